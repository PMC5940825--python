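"""Per-gene SNP variance/covariance from a reference genotype panel.

The gene-level Wald statistic needs the variance of predicted expression,
sigma_g^2 = W' Gamma W, where Gamma is the dosage covariance of the
model's SNPs.  When study genotypes are unavailable Gamma is estimated in
a reference panel (e.g., 1000 Genomes) or in the training set.  Sample
moments use the n-1 convention throughout.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import PredictionModel

log = logging.getLogger(__name__)


@dataclass
class SnpCovariance:
    """Symmetric dosage covariance over a gene's model SNPs.

    The diagonal is the per-SNP variance vector; ``effect_alleles`` records
    the allele each dosage counts (aligned to the model when built by
    :func:`compute_covariance`).
    """

    gene_id: str
    variant_ids: list[str]
    matrix: np.ndarray
    effect_alleles: list[str] | None = None
    status: str = "ok"  # ok | empty

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        p = len(self.variant_ids)
        if self.matrix.shape != (p, p):
            raise ValueError(f"covariance for {self.gene_id}: matrix shape != ({p},{p})")
        if p and not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError(f"covariance for {self.gene_id} is not symmetric")

    @property
    def variances(self) -> np.ndarray:
        """Per-SNP dosage variances (the diagonal)."""
        return np.diag(self.matrix).copy()

    def subset(self, variant_ids: Sequence[str]) -> "SnpCovariance":
        """Covariance restricted to ``variant_ids`` (in the given order)."""
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        idx = [pos[v] for v in variant_ids]
        return SnpCovariance(
            gene_id=self.gene_id,
            variant_ids=list(variant_ids),
            matrix=self.matrix[np.ix_(idx, idx)],
            effect_alleles=None
            if self.effect_alleles is None
            else [self.effect_alleles[i] for i in idx],
            status=self.status if variant_ids else "empty",
        )


def compute_covariance(
    panel_dosages: pd.DataFrame,
    model: PredictionModel,
    panel_alleles: Mapping[str, tuple[str, str]] | None = None,
) -> SnpCovariance:
    """Dosage covariance of a model's SNPs in a reference panel.

    Dosages are aligned to the model's effect alleles: when the panel
    counts the opposite allele the dosage is reflected (2 - d).  SNPs with
    mismatched allele sets are dropped.  Missing dosages are mean-imputed
    per SNP.  Returns an empty covariance (status ``"empty"``) when no
    model SNP intersects the panel.
    """
    if len(panel_dosages) < 2:
        raise ValueError("reference panel needs at least 2 individuals")
    ids: list[str] = []
    columns: list[np.ndarray] = []
    for vid, w in model.weights.items():
        if vid not in panel_dosages.columns:
            continue
        d = panel_dosages[vid].to_numpy(dtype=float)
        if panel_alleles is not None and vid in panel_alleles:
            ea, oa = panel_alleles[vid]
            if (ea, oa) == (w.effect_allele, w.other_allele):
                pass
            elif (ea, oa) == (w.other_allele, w.effect_allele):
                d = 2.0 - d
            else:
                log.warning(
                    "dropping %s for %s: panel alleles %s/%s do not match model %s/%s",
                    vid, model.gene_id, ea, oa, w.effect_allele, w.other_allele,
                )
                continue
        if np.isnan(d).any():
            d = np.where(np.isnan(d), np.nanmean(d), d)
        ids.append(vid)
        columns.append(d)
    if not ids:
        return SnpCovariance(model.gene_id, [], np.zeros((0, 0)), [], status="empty")
    X = np.column_stack(columns)
    matrix = np.cov(X, rowvar=False, ddof=1).reshape(len(ids), len(ids))
    return SnpCovariance(
        gene_id=model.gene_id,
        variant_ids=ids,
        matrix=matrix,
        effect_alleles=[model.weights[v].effect_allele for v in ids],
    )


def predicted_expression_variance(model: PredictionModel, cov: SnpCovariance) -> float:
    """sigma_g^2 = W' Gamma W over the covariance's SNP set."""
    missing = [v for v in cov.variant_ids if v not in model.weights]
    if missing:
        raise ValueError(f"covariance SNPs absent from model {model.gene_id}: {missing}")
    w = model.weight_vector(cov.variant_ids)
    value = float(w @ cov.matrix @ w)
    if value < -1e-12:
        raise ValueError(f"negative predicted-expression variance for {model.gene_id}: {value}")
    return max(value, 0.0)


# ---------------------------------------------------------------------------
# Serialization: gzipped TSV with GENE RSID1 RSID2 VALUE (upper triangle)
# ---------------------------------------------------------------------------


def write_covariance(covariances: Iterable[SnpCovariance], path) -> None:
    """Write covariances as gzipped TSV; ``repr`` keeps full float precision."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("GENE\tRSID1\tRSID2\tVALUE\n")
        for cov in covariances:
            for i, vi in enumerate(cov.variant_ids):
                for j in range(i, len(cov.variant_ids)):
                    fh.write(
                        f"{cov.gene_id}\t{vi}\t{cov.variant_ids[j]}\t{float(cov.matrix[i, j])!r}\n"
                    )


def read_covariance(path, gene_ids: Iterable[str] | None = None) -> dict[str, SnpCovariance]:
    """Read a covariance file back into per-gene matrices.

    When ``gene_ids`` is given, an entry for any other gene raises.  A
    malformed line raises with its line number.  Variant order is the order
    of first appearance per gene.
    """
    known = None if gene_ids is None else set(gene_ids)
    entries: dict[str, dict[tuple[str, str], float]] = {}
    order: dict[str, list[str]] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        header = fh.readline()
        if header.split() != ["GENE", "RSID1", "RSID2", "VALUE"]:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            gene, s1, s2, raw = parts
            if known is not None and gene not in known:
                raise ValueError(f"{path}:{lineno}: unknown gene {gene!r}")
            try:
                value = float(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad value {raw!r}") from None
            entries.setdefault(gene, {})[(s1, s2)] = value
            ordered = order.setdefault(gene, [])
            for s in (s1, s2):
                if s not in ordered:
                    ordered.append(s)

    out = {}
    for gene, pairs in entries.items():
        ids = order[gene]
        pos = {v: i for i, v in enumerate(ids)}
        matrix = np.zeros((len(ids), len(ids)))
        for (s1, s2), value in pairs.items():
            i, j = pos[s1], pos[s2]
            matrix[i, j] = value
            matrix[j, i] = value
        out[gene] = SnpCovariance(gene_id=gene, variant_ids=ids, matrix=matrix)
    return out
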