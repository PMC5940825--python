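"""Sparse gene expression prediction models: storage, filtering, training.

A prediction model for a gene is a sparse set of cis-SNP weights: the
genetically regulated component of expression is imputed as the weighted
sum of allele dosages, T_g = sum_l w_lg X_l.  Models are trained with an
elastic net (mixing parameter 0.5, penalty chosen by 10-fold cross
validation) on residualized expression, scored by the squared correlation
between cross-validated predictions and observed expression, and retained
when that performance clears an FDR threshold (q < 0.05).

Models are persisted in the field's conventional SQLite layout: a
``weights`` table with one row per (gene, SNP) and an ``extra`` table with
one row per gene holding the cross-validated performance.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold, cross_val_predict

from .fdr import qvalues
from .gwas import is_ambiguous

log = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000  # bases added upstream of TSS and downstream of TES
MAF_THRESHOLD = 0.01


class ModelFormatError(ValueError):
    """A model database does not have the expected schema or integrity."""


@dataclass(frozen=True)
class ModelWeight:
    """One SNP's contribution to a gene's predicted expression."""

    weight: float  # per copy of effect_allele
    effect_allele: str
    other_allele: str


@dataclass
class PredictionModel:
    """Per gene: SNP weights with their allele frame, and CV performance."""

    gene_id: str
    weights: dict[str, ModelWeight]
    gene_name: str | None = None
    perf_r2: float = float("nan")
    perf_pvalue: float = float("nan")

    @property
    def n_snps_in_model(self) -> int:
        return len(self.weights)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.weights)

    def weight_vector(self, variant_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.variant_ids if variant_ids is None else variant_ids
        return np.array([self.weights[v].weight for v in ids], dtype=float)

    def validate(self) -> None:
        if not self.weights:
            raise ValueError(f"model {self.gene_id} has no weights")
        for vid, w in self.weights.items():
            if not np.isfinite(w.weight) or w.weight == 0.0:
                raise ValueError(f"model {self.gene_id} has invalid weight for {vid}")


@dataclass
class ModelRejection:
    """Outcome of a training attempt that produced no usable model."""

    gene_id: str
    reason: str


@dataclass
class TrainingData:
    """Genotypes, residualizable expression, covariates, and gene annotation.

    ``dosages`` is individuals x variants with entries in [0, 2];
    ``variants`` has columns variant_id, chrom, pos, effect_allele,
    other_allele; ``genes`` has columns gene_id, chrom, tss, tes (1-based).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame
    expression: pd.DataFrame
    covariates: pd.DataFrame | None
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.dosages)
        if len(self.expression) != n:
            raise ValueError("dosage and expression row counts disagree")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("dosage and covariate row counts disagree")
        if (self.genes["tss"] > self.genes["tes"]).any():
            raise ValueError("gene annotation with tss > tes")


# ---------------------------------------------------------------------------
# SQLite persistence
# ---------------------------------------------------------------------------

_WEIGHTS_COLUMNS = ("gene", "rsid", "varID", "ref_allele", "eff_allele", "weight")
_EXTRA_COLUMNS = ("gene", "genename", "pred_perf_R2", "pred_perf_pval", "n_snps_in_model")


def write_model_db(models: Iterable[PredictionModel], path) -> None:
    """Write models to a SQLite database (tables ``weights`` and ``extra``)."""
    conn = sqlite3.connect(str(path))
    try:
        cur = conn.cursor()
        cur.execute("DROP TABLE IF EXISTS weights")
        cur.execute("DROP TABLE IF EXISTS extra")
        cur.execute(
            "CREATE TABLE weights (gene TEXT, rsid TEXT, varID TEXT,"
            " ref_allele TEXT, eff_allele TEXT, weight REAL)"
        )
        cur.execute(
            "CREATE TABLE extra (gene TEXT, genename TEXT, pred_perf_R2 REAL,"
            " pred_perf_pval REAL, n_snps_in_model INTEGER)"
        )
        for model in models:
            model.validate()
            cur.execute(
                "INSERT INTO extra VALUES (?,?,?,?,?)",
                (
                    model.gene_id,
                    model.gene_name,
                    model.perf_r2,
                    model.perf_pvalue,
                    model.n_snps_in_model,
                ),
            )
            for vid, w in model.weights.items():
                cur.execute(
                    "INSERT INTO weights VALUES (?,?,?,?,?,?)",
                    (model.gene_id, vid, vid, w.other_allele, w.effect_allele, w.weight),
                )
        conn.commit()
    finally:
        conn.close()


def read_model_db(path) -> list[PredictionModel]:
    """Read prediction models from a SQLite database.

    Raises :class:`ModelFormatError` naming the missing table/column for a
    malformed schema, or the offending gene when a weight row references a
    gene absent from the ``extra`` table.
    """
    conn = sqlite3.connect(str(path))
    try:
        tables = {
            row[0]
            for row in conn.execute("SELECT name FROM sqlite_master WHERE type='table'")
        }
        for table, columns in (("weights", _WEIGHTS_COLUMNS), ("extra", _EXTRA_COLUMNS)):
            if table not in tables:
                raise ModelFormatError(f"missing table {table!r}")
            present = {row[1] for row in conn.execute(f"PRAGMA table_info({table})")}
            for col in columns:
                if col not in present:
                    raise ModelFormatError(f"table {table!r} is missing column {col!r}")
        extra = pd.read_sql_query("SELECT * FROM extra", conn)
        weights = pd.read_sql_query("SELECT * FROM weights", conn)
    finally:
        conn.close()

    known = set(extra["gene"])
    orphans = set(weights["gene"]) - known
    if orphans:
        raise ModelFormatError(f"weight rows reference genes absent from extra: {sorted(orphans)}")

    models = []
    grouped = dict(tuple(weights.groupby("gene", sort=False)))
    for _, row in extra.iterrows():
        gene = row["gene"]
        gene_weights = {}
        if gene in grouped:
            for _, wrow in grouped[gene].iterrows():
                gene_weights[wrow["rsid"]] = ModelWeight(
                    weight=float(wrow["weight"]),
                    effect_allele=wrow["eff_allele"],
                    other_allele=wrow["ref_allele"],
                )
        models.append(
            PredictionModel(
                gene_id=gene,
                gene_name=row["genename"],
                weights=gene_weights,
                perf_r2=float(row["pred_perf_R2"]),
                perf_pvalue=float(row["pred_perf_pval"]),
            )
        )
    return models


def model_allele_frame(models: Iterable[PredictionModel]) -> dict[str, tuple[str, str]]:
    """Per-variant (effect_allele, other_allele) frame for harmonization."""
    frame: dict[str, tuple[str, str]] = {}
    for model in models:
        for vid, w in model.weights.items():
            frame[vid] = (w.effect_allele, w.other_allele)
    return frame


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def select_cis_snps(
    gene: Mapping[str, object],
    variants: pd.DataFrame,
    window: int = CIS_WINDOW,
) -> list[str]:
    """Variant ids within ``window`` of a gene's transcribed region.

    A variant is cis when it is on the gene's chromosome with
    tss - window <= pos <= tes + window (boundaries inclusive).
    """
    same_chrom = variants["chrom"].astype(str) == str(gene["chrom"])
    lo = int(gene["tss"]) - window
    hi = int(gene["tes"]) + window
    in_window = (variants["pos"] >= lo) & (variants["pos"] <= hi)
    return variants.loc[same_chrom & in_window, "variant_id"].tolist()


def dosage_maf(dosages: pd.DataFrame) -> pd.Series:
    """Minor-allele frequency per variant from dosages in [0, 2]."""
    freq = dosages.mean(axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def filter_training_variants(
    dosages: pd.DataFrame,
    variants: pd.DataFrame,
    maf_threshold: float = MAF_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep variants with MAF strictly above threshold and resolvable strand."""
    maf = dosage_maf(dosages)
    keep_maf = set(maf.index[maf > maf_threshold])
    keep = [
        vid
        for vid, ea, oa in zip(
            variants["variant_id"], variants["effect_allele"], variants["other_allele"]
        )
        if vid in keep_maf and not is_ambiguous(ea, oa)
    ]
    return dosages[keep], variants[variants["variant_id"].isin(keep)].reset_index(drop=True)


def residualize(expression, covariates) -> np.ndarray:
    """Least-squares residuals of expression on covariates (plus intercept).

    Raises for rank-deficient covariates, naming the collinear columns.
    """
    y = np.asarray(expression, dtype=float)
    if covariates is None:
        return y - y.mean()
    names = (
        list(covariates.columns)
        if isinstance(covariates, pd.DataFrame)
        else [f"cov{i}" for i in range(np.atleast_2d(covariates).shape[1])]
    )
    C = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # pivoted QR identifies which columns fail to add rank
        _, _, piv = linalg.qr(C, pivoting=True)
        dependent = sorted(piv[rank:])
        bad = [("intercept" if j == 0 else names[j - 1]) for j in dependent]
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


def train_elastic_net(
    training: TrainingData,
    gene_id: str,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    window: int = CIS_WINDOW,
    n_lambdas: int = 100,
    penalty_rule: str = "1se",
) -> PredictionModel | ModelRejection:
    """Fit a cis elastic-net expression model for one gene.

    ``alpha`` is the L1/L2 mixing parameter (0.5 = equal mix, the glmnet
    convention).  The penalty strength is chosen over ``folds`` CV folds by
    ``penalty_rule``: ``"1se"`` (default) takes the strongest penalty whose
    mean CV error is within one standard error of the minimum, which keeps
    the support sparse; ``"min"`` takes the error-minimizing penalty.
    Dosages are standardized internally and coefficients mapped back to
    the dosage scale.  Returns a :class:`ModelRejection` when no SNP
    survives the filters or every coefficient is zero at the selected
    penalty.

    Performance is the squared correlation between cross-validated
    predictions and observed (residualized) expression, with a one-sided
    p-value for positive correlation.
    """
    gene_rows = training.genes[training.genes["gene_id"] == gene_id]
    if gene_rows.empty:
        raise KeyError(f"gene {gene_id} not in annotation")
    gene = gene_rows.iloc[0]

    dosages, variants = filter_training_variants(training.dosages, training.variants)
    cis_ids = select_cis_snps(gene, variants, window=window)
    if not cis_ids:
        return ModelRejection(gene_id, "no cis SNPs after filters")

    X = dosages[cis_ids].to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=1)
    usable = sds > 0
    if not usable.any():
        return ModelRejection(gene_id, "no polymorphic cis SNPs")
    cis_ids = [v for v, u in zip(cis_ids, usable) if u]
    X = X[:, usable]
    sds = sds[usable]
    Xs = (X - X.mean(axis=0)) / sds

    y = residualize(training.expression[gene_id], training.covariates)
    if len(y) < folds:
        raise ValueError(f"need at least {folds} individuals for {folds}-fold CV")

    if penalty_rule not in ("1se", "min"):
        raise ValueError("penalty_rule must be '1se' or 'min'")
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    enet = ElasticNetCV(l1_ratio=alpha, alphas=n_lambdas, cv=cv, max_iter=5000)
    enet.fit(Xs, y)

    if penalty_rule == "min":
        lam = float(enet.alpha_)
        coef = enet.coef_
    else:
        mean_mse = enet.mse_path_.mean(axis=1)
        se_mse = enet.mse_path_.std(axis=1, ddof=1) / np.sqrt(folds)
        best = int(np.argmin(mean_mse))
        within = mean_mse <= mean_mse[best] + se_mse[best]
        lam = float(enet.alphas_[within].max())
        coef = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=5000).fit(Xs, y).coef_

    nonzero = np.flatnonzero(coef)
    if nonzero.size == 0:
        return ModelRejection(gene_id, "null model")

    cv_pred = cross_val_predict(
        ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=5000), Xs, y, cv=cv
    )
    if np.std(cv_pred) == 0 or np.std(y) == 0:
        perf_r2, perf_pvalue = 0.0, 1.0
    else:
        res = stats.pearsonr(cv_pred, y, alternative="greater")
        perf_r2 = float(res.statistic**2)
        perf_pvalue = float(res.pvalue)

    vinfo = variants.set_index("variant_id")
    weights = {}
    for j in nonzero:
        vid = cis_ids[j]
        weights[vid] = ModelWeight(
            weight=float(coef[j] / sds[j]),  # back to dosage scale
            effect_allele=vinfo.loc[vid, "effect_allele"],
            other_allele=vinfo.loc[vid, "other_allele"],
        )
    return PredictionModel(
        gene_id=gene_id,
        gene_name=str(gene.get("gene_name", gene_id)),
        weights=weights,
        perf_r2=perf_r2,
        perf_pvalue=perf_pvalue,
    )


def filter_models_by_qvalue(
    models: Sequence[PredictionModel], threshold: float = 0.05
) -> list[PredictionModel]:
    """Retain models whose performance q-value (over this set) is < threshold."""
    if not models:
        return []
    q = qvalues([m.perf_pvalue for m in models])
    return [m for m, qv in zip(models, q) if qv < threshold]
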