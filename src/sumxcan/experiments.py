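"""End-to-end experiments on synthetic cohorts.

These functions wire the generator, the per-SNP scan, the reference
covariance, and the gene-level tests together: concordance of the
summary-statistic gene Z-scores with the individual-level computation,
null calibration of the gene statistics, and the staged
association/colocalization pipeline on a cohort with known mediated and
LD-contaminated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import GeneAssociation, compute_zscore
from .coloc import ColocResult, PipelineConfig, PipelineResult, TraitRegion, coloc_abf, run_pipeline
from .covariance import compute_covariance
from .gwas import records_index
from .oracle import association, gwas_scan, predict_expression
from .simulate import SimScenario, SimulatedStudy, simulate_study


def summary_vs_oracle(study: SimulatedStudy) -> pd.DataFrame:
    """Gene Z-scores by both routes, with the study set as its own LD reference.

    Runs the per-SNP GWAS scan on the cohort, computes the summary gene
    statistic with covariances from the same individuals, and the
    individual-level statistic by regressing the phenotype on predicted
    expression.  Returns one row per gene with ``z_oracle``, ``z_summary``,
    and the summary p-value.
    """
    records = gwas_scan(study.dosages, study.phenotype, study.variants)
    gwas_idx = records_index(records)
    rows = []
    for model in study.models:
        cov = compute_covariance(study.dosages, model)
        summary = compute_zscore(model, gwas_idx, cov)
        t, _ = predict_expression(study.dosages, model)
        oracle = association(t, study.phenotype)
        rows.append(
            {
                "gene_id": model.gene_id,
                "z_oracle": oracle.zscore,
                "z_summary": summary.zscore,
                "pvalue_summary": summary.pvalue,
                "sigma_g2": summary.sigma_g2,
                "status": summary.status,
            }
        )
    return pd.DataFrame(rows)


def concordance_r2(comparison: pd.DataFrame) -> float:
    """Squared Pearson correlation between oracle and summary gene Z-scores."""
    ok = comparison[comparison["status"] == "ok"]
    return float(np.corrcoef(ok["z_oracle"], ok["z_summary"])[0, 1] ** 2)


def null_gene_zscores(scenario: SimScenario) -> np.ndarray:
    """Summary gene Z-scores for a null-phenotype scenario."""
    if scenario.architecture != "null":
        raise ValueError("null calibration needs a null-architecture scenario")
    comparison = summary_vs_oracle(simulate_study(scenario))
    ok = comparison[comparison["status"] == "ok"]
    return ok["z_summary"].to_numpy()


@dataclass
class PipelineExperiment:
    """Staged-pipeline run on a cohort with known gene roles."""

    result: PipelineResult
    associations: pd.DataFrame  # gene_id, pvalue, pred_perf_pval, zscore, role
    colocs: dict[str, ColocResult]
    labels: pd.DataFrame


def pipeline_experiment(
    scenario: SimScenario, config: PipelineConfig = PipelineConfig()
) -> PipelineExperiment:
    """Associations + colocalization + staged filtering on one cohort.

    For every gene the per-SNP GWAS and eQTL summaries over its LD block
    are computed from the same simulated individuals, colocalization
    posteriors are derived from them, and the four-step filter is applied
    to the gene-level associations.
    """
    study = simulate_study(scenario)
    records = gwas_scan(study.dosages, study.phenotype, study.variants)
    gwas_idx = records_index(records)

    by_gene = dict(tuple(study.variants.groupby("gene_id", sort=False)))
    rows = []
    colocs: dict[str, ColocResult] = {}
    for model in study.models:
        cov = compute_covariance(study.dosages, model)
        summary = compute_zscore(model, gwas_idx, cov)
        rows.append(
            {
                "gene_id": model.gene_id,
                "key": model.gene_id,
                "pvalue": summary.pvalue,
                "pred_perf_pval": model.perf_pvalue,
                "zscore": summary.zscore,
            }
        )
        block_ids = by_gene[model.gene_id]["variant_id"].tolist()
        gwas_records = [gwas_idx[v] for v in block_ids if v in gwas_idx]
        eqtl_records = gwas_scan(
            study.dosages[block_ids],
            study.expression[model.gene_id],
            study.variants[study.variants["gene_id"] == model.gene_id],
        )
        colocs[model.gene_id] = coloc_abf(
            TraitRegion.from_records(gwas_records),
            TraitRegion.from_records(eqtl_records),
            priors=config.priors,
            gene_id=model.gene_id,
        )

    associations = pd.DataFrame(rows).merge(study.labels, on="gene_id")
    result = run_pipeline(associations, colocs, config)
    return PipelineExperiment(
        result=result, associations=associations, colocs=colocs, labels=study.labels
    )
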