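"""Synthetic cohorts for exercising the summary-association machinery.

Everything downstream — GWAS summaries, expression models, LD reference
covariances, phenotypes mediated through expression — can be generated
from one :class:`SimScenario`, so the whole framework is testable without
external data.

Genotypes are drawn under Hardy-Weinberg equilibrium with block LD via a
Gaussian copula: each gene's SNPs share a latent equicorrelated normal
(correlation ``ld_rho``) per haplotype, thresholded at the allele
frequency, and the two haplotypes are summed into a dosage in {0, 1, 2}.
Expression is a sparse weighted dosage sum plus Gaussian noise scaled to a
target heritability; phenotypes are null, mediated through the genetic
component of expression, or LD-contaminated (driven by a block SNP that
carries no model weight).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelWeight, PredictionModel

ARCHITECTURES = ("null", "mediated", "ld_contaminated")

# Genome layout: genes are spaced far enough apart that cis windows of
# neighbouring genes never overlap (spacing > 2 * (window + block span)).
_GENE_SPACING = 3_000_000
_FIRST_TSS = 2_000_000
_GENE_LENGTH = 10_000
_SNP_SPACING = 1_000

# Causal eQTL SNPs are drawn from the head of each block; the reserved tail
# is where LD-contaminating phenotype SNPs live, guaranteeing zero weight.
_RESERVED_TAIL_FRACTION = 0.25


@dataclass
class SimScenario:
    """Full specification of one synthetic study; the seed is mandatory."""

    seed: int
    n_individuals: int = 500
    n_genes: int = 200
    snps_per_gene: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    n_causal_snps: int = 3
    h2_expr: float = 0.5
    gamma: float = 0.25  # phenotype effect per sd of genetic expression
    architecture: str = "null"
    n_mediated: int = 0  # 0 under 'mediated' means every gene mediates
    n_decoys: int = 0
    decoy_effect: float = 0.3  # phenotype effect per sd of the decoy SNP

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0.0 <= self.h2_expr <= 1.0):
            raise ValueError("h2_expr must be in [0, 1]")
        if self.n_causal_snps > self.snps_per_gene:
            raise ValueError("n_causal_snps exceeds snps_per_gene")
        if self.n_mediated + self.n_decoys > self.n_genes:
            raise ValueError("n_mediated + n_decoys exceeds n_genes")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimScenario":
        with open(path) as fh:
            raw = json.load(fh)
        raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)


def _gene_id(g: int) -> str:
    return f"GENE{g:04d}"


def _variant_id(g: int, k: int) -> str:
    return f"rs{g}_{k}"


def make_variant_map(scenario: SimScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene annotation and variant table implied by a scenario."""
    genes = pd.DataFrame(
        {
            "gene_id": [_gene_id(g) for g in range(scenario.n_genes)],
            "gene_name": [_gene_id(g) for g in range(scenario.n_genes)],
            "chrom": "1",
            "tss": [_FIRST_TSS + g * _GENE_SPACING for g in range(scenario.n_genes)],
            "tes": [
                _FIRST_TSS + g * _GENE_SPACING + _GENE_LENGTH for g in range(scenario.n_genes)
            ],
        }
    )
    rows = []
    for g in range(scenario.n_genes):
        tss = _FIRST_TSS + g * _GENE_SPACING
        for k in range(scenario.snps_per_gene):
            rows.append(
                {
                    "variant_id": _variant_id(g, k),
                    "chrom": "1",
                    "pos": tss - 500_000 + k * _SNP_SPACING,
                    "effect_allele": "A",
                    "other_allele": "G",
                    "gene_id": _gene_id(g),
                }
            )
    return genes, pd.DataFrame(rows)


def simulate_genotypes(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """HWE dosages with per-gene block LD.

    Returns ``(dosages, variants, genes)``; dosage columns follow the
    variant table order.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    genes, variants = make_variant_map(scenario)
    n, p = scenario.n_individuals, scenario.snps_per_gene
    rho = scenario.ld_rho
    blocks = []
    for _ in range(scenario.n_genes):
        maf = rng.uniform(*scenario.maf_range, size=p)
        cut = stats.norm.ppf(maf)
        dosage = np.zeros((n, p), dtype=float)
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((n, p))
            dosage += (latent < cut).astype(float)
        blocks.append(dosage)
    dosages = pd.DataFrame(
        np.hstack(blocks), columns=variants["variant_id"].tolist()
    )
    return dosages, variants, genes


def simulate_gene_models(
    scenario: SimScenario,
    dosages: pd.DataFrame,
    variants: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, float]], list[PredictionModel], pd.DataFrame, pd.DataFrame]:
    """Sparse truth weights, the matching models, and expression traits.

    Per gene, ``n_causal_snps`` weights are drawn nonzero (uniform
    magnitude in [0.2, 1.0], random sign) from the head of the block;
    expression is the genetic component X.w plus Gaussian noise scaled so
    the genetic share of variance equals ``h2_expr``.  Returns
    ``(truth, models, expression, genetic)`` where ``genetic`` holds the
    noiseless genetic component per gene.
    """
    rng = np.random.default_rng(scenario.seed + 1) if rng is None else rng
    n = len(dosages)
    head = max(
        scenario.n_causal_snps,
        int(round(scenario.snps_per_gene * (1.0 - _RESERVED_TAIL_FRACTION))),
    )
    truth: dict[str, dict[str, float]] = {}
    models: list[PredictionModel] = []
    expression = {}
    genetic = {}
    by_gene = dict(tuple(variants.groupby("gene_id", sort=False)))
    for gene_id, vtable in by_gene.items():
        ids = vtable["variant_id"].tolist()
        causal_idx = rng.choice(head, size=scenario.n_causal_snps, replace=False)
        weights = {}
        for j in causal_idx:
            w = rng.uniform(0.2, 1.0) * rng.choice([-1.0, 1.0])
            weights[ids[j]] = float(w)
        truth[gene_id] = weights
        X = dosages[list(weights)].to_numpy(dtype=float)
        w_vec = np.array(list(weights.values()))
        g = X @ w_vec
        sd_g = g.std(ddof=1)
        noise = rng.standard_normal(n)
        h2 = scenario.h2_expr
        if h2 == 0.0 or sd_g == 0.0:
            expr = noise
        elif h2 == 1.0:
            expr = g.copy()
        else:
            expr = g + sd_g * np.sqrt((1.0 - h2) / h2) * noise
        expression[gene_id] = expr
        genetic[gene_id] = g
        if np.std(expr) > 0 and sd_g > 0:
            res = stats.pearsonr(g, expr, alternative="greater")
            perf_r2, perf_p = float(res.statistic**2), float(res.pvalue)
        else:
            perf_r2, perf_p = 0.0, 1.0
        models.append(
            PredictionModel(
                gene_id=gene_id,
                gene_name=gene_id,
                weights={
                    vid: ModelWeight(weight=w, effect_allele="A", other_allele="G")
                    for vid, w in weights.items()
                },
                perf_r2=perf_r2,
                perf_pvalue=perf_p,
            )
        )
    return truth, models, pd.DataFrame(expression), pd.DataFrame(genetic)


def simulate_phenotype(
    scenario: SimScenario,
    genetic: pd.DataFrame,
    dosages: pd.DataFrame,
    truth: Mapping[str, Mapping[str, float]],
    variants: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Phenotype under the scenario's architecture, with per-gene truth labels.

    null: standard normal, independent of genotype.  mediated: a sum of
    ``gamma`` x standardized genetic expression over the mediated genes
    plus unit noise, standardized to unit variance.  ld_contaminated:
    additionally, decoy genes contribute through a reserved block SNP that
    carries no model weight.
    """
    rng = np.random.default_rng(scenario.seed + 2) if rng is None else rng
    n = len(dosages)
    gene_ids = list(genetic.columns)
    roles = {g: "null" for g in gene_ids}
    decoy_snp: dict[str, str] = {}

    y = rng.standard_normal(n)
    if scenario.architecture != "null":
        if scenario.architecture == "mediated" and scenario.n_mediated == 0:
            mediated = list(gene_ids)  # every gene mediates by default
        else:
            mediated = gene_ids[: scenario.n_mediated]
        for g in mediated:
            roles[g] = "mediated"
            comp = genetic[g].to_numpy()
            sd = comp.std(ddof=1)
            if sd > 0:
                y = y + scenario.gamma * (comp - comp.mean()) / sd
        if scenario.architecture == "ld_contaminated":
            by_gene = dict(tuple(variants.groupby("gene_id", sort=False)))
            start = scenario.n_mediated if scenario.n_mediated else 0
            decoys = gene_ids[start : start + scenario.n_decoys]
            for g in decoys:
                roles[g] = "decoy"
                ids = by_gene[g]["variant_id"].tolist()
                candidates = [v for v in ids if v not in truth[g]]
                vid = candidates[int(rng.integers(len(candidates)))]
                decoy_snp[g] = vid
                x = dosages[vid].to_numpy(dtype=float)
                sd = x.std(ddof=1)
                if sd > 0:
                    y = y + scenario.decoy_effect * (x - x.mean()) / sd
    y = (y - y.mean()) / y.std(ddof=1)

    labels = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "role": [roles[g] for g in gene_ids],
            "decoy_snp": [decoy_snp.get(g) for g in gene_ids],
        }
    )
    return y, labels


@dataclass
class SimulatedStudy:
    """Everything one scenario generates, bundled for downstream modules."""

    scenario: SimScenario
    dosages: pd.DataFrame
    variants: pd.DataFrame
    genes: pd.DataFrame
    truth: dict[str, dict[str, float]]
    models: list[PredictionModel]
    expression: pd.DataFrame
    genetic: pd.DataFrame
    phenotype: np.ndarray
    labels: pd.DataFrame


def simulate_study(scenario: SimScenario) -> SimulatedStudy:
    """Run the full generator: genotypes, models, expression, phenotype."""
    dosages, variants, genes = simulate_genotypes(scenario)
    truth, models, expression, genetic = simulate_gene_models(scenario, dosages, variants)
    phenotype, labels = simulate_phenotype(
        scenario, genetic, dosages, truth, variants
    )
    return SimulatedStudy(
        scenario=scenario,
        dosages=dosages,
        variants=variants,
        genes=genes,
        truth=truth,
        models=models,
        expression=expression,
        genetic=genetic,
        phenotype=phenotype,
        labels=labels,
    )
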