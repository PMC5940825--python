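"""Individual-level gene association (PrediXcan) used as ground truth.

With genotypes and phenotype in hand, the gene test is plain least
squares: impute expression T_g = sum_l w_lg X_l, then regress the
phenotype on T_g.  The summary-statistic route must reproduce these
Z-scores; this module provides the reference computation and the per-SNP
GWAS scan that feeds the summary route in end-to-end checks.

Sample moments use n-1; the slope's standard error follows
se^2 = sigma_Y^2 (1 - R^2) / (n sigma_x^2), matching the conventions of
the summary derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import GwasRecord
from .models import PredictionModel


@dataclass
class OracleAssociation:
    """Least-squares association of a phenotype with one predictor."""

    effect: float
    se: float
    zscore: float
    pvalue: float
    status: str = "ok"  # ok | zero_variance


def predict_expression(
    dosages: pd.DataFrame, model: PredictionModel
) -> tuple[np.ndarray, list[str]]:
    """Per-individual predicted expression; missing model SNPs contribute 0.

    Returns the prediction vector and the list of model SNPs absent from
    the dosage matrix.
    """
    t = np.zeros(len(dosages))
    missing = []
    for vid, w in model.weights.items():
        if vid in dosages.columns:
            t += w.weight * dosages[vid].to_numpy(dtype=float)
        else:
            missing.append(vid)
    return t, missing


def association(predictor, phenotype, n: int | None = None) -> OracleAssociation:
    """Simple regression of phenotype on one predictor (intercept implied).

    effect = Cov(x, Y)/Var(x); se^2 = sigma_Y^2 (1 - R^2)/(n sigma_x^2);
    Z = effect/se; p two-sided normal.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if n is None:
        n = len(y)
    var_x = x.var(ddof=1)
    if var_x <= 0:
        return OracleAssociation(float("nan"), float("nan"), float("nan"), float("nan"),
                                 status="zero_variance")
    var_y = y.var(ddof=1)
    cov_xy = np.cov(x, y, ddof=1)[0, 1]
    effect = cov_xy / var_x
    r2 = effect**2 * var_x / var_y if var_y > 0 else 0.0
    se2 = var_y * max(1.0 - r2, 0.0) / (n * var_x)
    if se2 <= 0:
        z = np.inf * np.sign(effect) if effect != 0 else 0.0
        return OracleAssociation(float(effect), 0.0, float(z), 0.0 if effect else 1.0)
    se = float(np.sqrt(se2))
    z = float(effect / se)
    return OracleAssociation(float(effect), se, z, float(2.0 * stats.norm.sf(abs(z))))


def gwas_scan(
    dosages: pd.DataFrame,
    phenotype,
    variants: pd.DataFrame | None = None,
) -> list[GwasRecord]:
    """Per-SNP association scan producing GWAS summary records.

    Constant SNPs are skipped.  When ``variants`` (columns variant_id,
    effect_allele, other_allele, optionally chrom/pos) is omitted, alleles
    default to A (effect, the counted dosage allele) / G.
    """
    y = np.asarray(phenotype, dtype=float)
    X = dosages.to_numpy(dtype=float)
    n = len(y)
    var_x = X.var(axis=0, ddof=1)
    var_y = y.var(ddof=1)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    cov_xy = xc.T @ yc / (n - 1)

    info = None
    if variants is not None:
        info = variants.set_index("variant_id")

    records = []
    for j, vid in enumerate(dosages.columns):
        if var_x[j] <= 0:
            continue
        beta = cov_xy[j] / var_x[j]
        r2 = beta**2 * var_x[j] / var_y if var_y > 0 else 0.0
        se2 = var_y * max(1.0 - r2, 0.0) / (n * var_x[j])
        if se2 <= 0:
            continue
        se = float(np.sqrt(se2))
        z = float(beta / se)
        if info is not None:
            row = info.loc[vid]
            ea, oa = row["effect_allele"], row["other_allele"]
            chrom = str(row["chrom"]) if "chrom" in info.columns else None
            pos = int(row["pos"]) if "pos" in info.columns else None
        else:
            ea, oa, chrom, pos = "A", "G", None, None
        records.append(
            GwasRecord(
                variant_id=vid,
                effect_allele=ea,
                other_allele=oa,
                chrom=chrom,
                pos=pos,
                beta=float(beta),
                se=se,
                zscore=z,
                pvalue=float(2.0 * stats.norm.sf(abs(z))),
                frequency=float(X[:, j].mean() / 2.0),
                n=n,
            )
        )
    return records
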