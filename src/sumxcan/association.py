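"""Gene-level association from GWAS summary statistics (S-PrediXcan).

The Wald Z-score of the association between a gene's predicted expression
and a phenotype can be assembled from per-SNP GWAS statistics without
individual-level data:

    Z_g ~= sum_{l in model} w_lg (sigma_l / sigma_g) Z_l

with sigma_g^2 = W' Gamma W from a reference LD panel.  The neglected
per-SNP correction factor sqrt((1 - R_l^2) / (1 - R_g^2)) is close to 1
for realistic effect sizes and is available through
:func:`compute_zscore_exact` when the phenotype variance and sample size
are known.  An equivalent matrix form on scaled weights,
Z_g = W~ . Z / sqrt(W~' Sigma W~), makes the link to summary TWAS explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .covariance import SnpCovariance, predicted_expression_variance
from .gwas import GwasRecord
from .models import PredictionModel

ZERO_VARIANCE_TOL = 1e-12


class AlleleFrameError(ValueError):
    """GWAS records were not harmonized to the model's allele frame."""


@dataclass
class GeneAssociation:
    """Gene-level summary association result."""

    gene_id: str
    zscore: float = float("nan")
    pvalue: float = float("nan")
    sigma_g2: float = float("nan")
    n_snps_used: int = 0
    n_snps_in_model: int = 0
    exact_factor_applied: bool = False
    effect_size: float | None = None
    status: str = "ok"  # ok | no_snps | zero_variance


@dataclass
class ScaledWeights:
    """Variance-scaled weights W~ = (sigma_1 w_1, ...) with SNP correlation Sigma."""

    gene_id: str
    variant_ids: list[str]
    scaled: np.ndarray
    correlation: np.ndarray

    @classmethod
    def from_model(cls, model: PredictionModel, cov: SnpCovariance) -> "ScaledWeights":
        sigma = np.sqrt(np.clip(cov.variances, 0.0, None))
        w = model.weight_vector(cov.variant_ids)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(sigma > 0, 1.0 / sigma, 0.0)
        corr = np.outer(inv, inv) * cov.matrix
        np.fill_diagonal(corr, np.where(sigma > 0, 1.0, 0.0))
        return cls(
            gene_id=model.gene_id,
            variant_ids=list(cov.variant_ids),
            scaled=sigma * w,
            correlation=corr,
        )


def _intersect(
    model: PredictionModel,
    gwas: Mapping[str, GwasRecord],
    cov: SnpCovariance,
) -> list[str]:
    """Model SNPs with a GWAS record and a covariance entry, checking frames."""
    used = []
    for vid in cov.variant_ids:
        if vid not in model.weights:
            continue
        record = gwas.get(vid)
        if record is None or record.zscore is None:
            continue
        w = model.weights[vid]
        if (record.effect_allele, record.other_allele) != (w.effect_allele, w.other_allele):
            raise AlleleFrameError(
                f"{vid}: GWAS alleles {record.effect_allele}/{record.other_allele} do not "
                f"match model {w.effect_allele}/{w.other_allele}; harmonize first"
            )
        used.append(vid)
    return used


def compute_zscore(
    model: PredictionModel,
    gwas: Mapping[str, GwasRecord],
    cov: SnpCovariance,
) -> GeneAssociation:
    """S-PrediXcan Z-score for one gene from harmonized GWAS records.

    The computation runs on the intersection of model SNPs, GWAS records,
    and covariance entries; sigma_g^2 is recomputed on that same subset so
    the numerator and denominator stay consistent.  ``n_snps_used`` /
    ``n_snps_in_model`` lets callers filter genes with poor coverage.
    """
    out = GeneAssociation(gene_id=model.gene_id, n_snps_in_model=model.n_snps_in_model)
    used = _intersect(model, gwas, cov)
    if not used:
        out.status = "no_snps"
        return out
    sub = cov.subset(used)
    sigma_g2 = predicted_expression_variance(model, sub)
    out.n_snps_used = len(used)
    out.sigma_g2 = sigma_g2
    if sigma_g2 <= ZERO_VARIANCE_TOL:
        out.status = "zero_variance"
        return out
    sigma_g = np.sqrt(sigma_g2)
    sigma_l = np.sqrt(np.clip(sub.variances, 0.0, None))
    w = model.weight_vector(used)
    z_snp = np.array([gwas[v].zscore for v in used], dtype=float)
    if len(used) == 1:
        # single predictor: w sigma_l / sqrt(w^2 sigma_l^2) cancels exactly
        # to sign(w), so the gene Z is the SNP's GWAS Z up to sign
        out.zscore = float(np.sign(w[0]) * z_snp[0])
    else:
        out.zscore = float(np.sum(w * sigma_l / sigma_g * z_snp))
    out.pvalue = float(2.0 * stats.norm.sf(abs(out.zscore)))
    return out


def effect_size(
    model: PredictionModel,
    gwas: Mapping[str, GwasRecord],
    cov: SnpCovariance,
) -> float:
    """Estimated effect of predicted expression on the phenotype.

    gamma_g = sum_l w_lg beta_l sigma_l^2 / sigma_g^2; requires per-SNP
    effect sizes (not just Z-scores).
    """
    used = _intersect(model, gwas, cov)
    if not used:
        raise ValueError(f"no usable SNPs for {model.gene_id}")
    for vid in used:
        if gwas[vid].beta is None:
            raise ValueError(f"effect size needs beta for {vid}")
    sub = cov.subset(used)
    sigma_g2 = predicted_expression_variance(model, sub)
    if sigma_g2 <= ZERO_VARIANCE_TOL:
        raise ValueError(f"zero predicted-expression variance for {model.gene_id}")
    w = model.weight_vector(used)
    beta = np.array([gwas[v].beta for v in used], dtype=float)
    return float(np.sum(w * beta * sub.variances) / sigma_g2)


def compute_zscore_exact(
    model: PredictionModel,
    gwas: Mapping[str, GwasRecord],
    cov: SnpCovariance,
    phenotype_variance: float,
    n: int,
) -> GeneAssociation:
    """Gene Z-score with the per-SNP sqrt((1-R_l^2)/(1-R_g^2)) factor restored.

    R_l^2 = beta_l^2 sigma_l^2 / sigma_Y^2 is each SNP's share of phenotype
    variance; R_g^2 = gamma_g^2 sigma_g^2 / sigma_Y^2 the gene's share.
    Requires per-SNP betas.  Raises when the implied R_g^2 reaches 1
    (inconsistent inputs).
    """
    out = GeneAssociation(
        gene_id=model.gene_id,
        n_snps_in_model=model.n_snps_in_model,
        exact_factor_applied=True,
    )
    used = _intersect(model, gwas, cov)
    if not used:
        out.status = "no_snps"
        return out
    sub = cov.subset(used)
    sigma_g2 = predicted_expression_variance(model, sub)
    out.n_snps_used = len(used)
    out.sigma_g2 = sigma_g2
    if sigma_g2 <= ZERO_VARIANCE_TOL:
        out.status = "zero_variance"
        return out

    w = model.weight_vector(used)
    beta = np.array([gwas[v].beta for v in used], dtype=float)
    if np.any(np.isnan(beta)):
        raise ValueError("exact factor needs beta for every SNP")
    z_snp = np.array([gwas[v].zscore for v in used], dtype=float)
    sigma_l2 = np.clip(sub.variances, 0.0, None)

    r2_l = beta**2 * sigma_l2 / phenotype_variance
    gamma_g = float(np.sum(w * beta * sigma_l2) / sigma_g2)
    r2_g = gamma_g**2 * sigma_g2 / phenotype_variance
    if r2_g >= 1.0 or np.any(r2_l >= 1.0):
        raise ValueError(
            f"{model.gene_id}: proportion of variance explained reaches 1; inconsistent inputs"
        )
    factor = np.sqrt((1.0 - r2_l) / (1.0 - r2_g))
    out.effect_size = gamma_g
    out.zscore = float(np.sum(w * np.sqrt(sigma_l2) / np.sqrt(sigma_g2) * z_snp * factor))
    out.pvalue = float(2.0 * stats.norm.sf(abs(out.zscore)))
    return out


def compute_zscore_matrix_form(scaled: ScaledWeights, snp_zscores: Sequence[float]) -> float:
    """Z_g = W~ . Z / sqrt(W~' Sigma W~); NaN when the denominator vanishes."""
    z = np.asarray(snp_zscores, dtype=float)
    if z.shape[0] != scaled.scaled.shape[0]:
        raise ValueError("dimension mismatch between scaled weights and SNP Z-scores")
    denom2 = float(scaled.scaled @ scaled.correlation @ scaled.scaled)
    if denom2 <= ZERO_VARIANCE_TOL:
        return float("nan")
    return float(scaled.scaled @ z / np.sqrt(denom2))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Significance threshold corrected for all gene-tissue pairs tested."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests
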