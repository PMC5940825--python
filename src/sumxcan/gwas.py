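"""Reading and allele harmonization of GWAS summary statistics.

A GWAS summary file reports, per variant, an effect size (or odds ratio)
with its standard error and/or a p-value, relative to a declared effect
allele.  Before gene-level association can be computed the records must be
expressed in the same allele frame as the prediction models: swapped
alleles flip the sign of the effect, strand-ambiguous variants (A/T, C/G)
are unresolvable from summary data and are removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: ref/alt pairs whose strand cannot be resolved from the alleles alone
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


class GwasConfigurationError(ValueError):
    """The column mapping does not match the file."""


def is_ambiguous(a1: str, a2: str) -> bool:
    """True for strand-ambiguous (complementary) allele pairs."""
    return (a1, a2) in AMBIGUOUS_PAIRS


@dataclass
class GwasRecord:
    """One variant's harmonized association summary.

    ``beta`` is the effect per copy of ``effect_allele``; ``zscore`` is the
    Wald statistic beta/se.  ``frequency`` is the effect-allele frequency.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    chrom: str | None = None
    pos: int | None = None
    beta: float | None = None
    se: float | None = None
    pvalue: float | None = None
    zscore: float | None = None
    frequency: float | None = None
    n: int | None = None

    def flipped(self) -> "GwasRecord":
        """The same record expressed with effect and other allele swapped."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=None if self.beta is None else -self.beta,
            zscore=None if self.zscore is None else -self.zscore,
            frequency=None if self.frequency is None else 1.0 - self.frequency,
        )


# Fields accepted in a column map.  variant_id and both alleles are mandatory.
_MANDATORY = ("variant_id", "effect_allele", "other_allele")
_OPTIONAL = ("chrom", "pos", "beta", "odds_ratio", "se", "pvalue", "zscore", "frequency", "n")


def _float_or_none(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"not a number: {value!r}")
    return None if math.isnan(out) else out


def _build_record(row: Mapping[str, object], column_map: Mapping[str, str]) -> GwasRecord | None:
    """Turn one parsed row into a record, or None (with a logged reason)."""

    def get(fieldname):
        col = column_map.get(fieldname)
        return None if col is None else row.get(col)

    variant_id = str(get("variant_id"))
    ea = str(get("effect_allele")).upper()
    oa = str(get("other_allele")).upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES or ea == oa:
        log.warning("skipping %s: invalid allele pair %s/%s", variant_id, ea, oa)
        return None

    beta = _float_or_none(get("beta"))
    odds_ratio = _float_or_none(get("odds_ratio"))
    if beta is None and odds_ratio is not None:
        if odds_ratio <= 0:
            raise ValueError(f"non-positive odds ratio {odds_ratio}")
        beta = math.log(odds_ratio)
    se = _float_or_none(get("se"))
    pvalue = _float_or_none(get("pvalue"))
    zscore = _float_or_none(get("zscore"))
    frequency = _float_or_none(get("frequency"))
    n_raw = _float_or_none(get("n"))
    n = None if n_raw is None else int(n_raw)
    pos_raw = _float_or_none(get("pos"))
    pos = None if pos_raw is None else int(pos_raw)
    chrom_raw = get("chrom")
    chrom = None if chrom_raw is None else str(chrom_raw)

    # Z-score precedence: beta/se, then a provided Z, then p-value plus an
    # effect-direction source.  p-value-only rows carry no sign and are dropped.
    if beta is not None and se is not None and se > 0:
        zscore = beta / se
    elif zscore is not None:
        pass
    elif pvalue is not None and beta is not None:
        sign = 1.0 if beta > 0 else (-1.0 if beta < 0 else 0.0)
        zscore = sign * stats.norm.isf(pvalue / 2.0)
    else:
        log.warning("skipping %s: no usable (beta,se), zscore, or signed p-value", variant_id)
        return None

    return GwasRecord(
        variant_id=variant_id,
        effect_allele=ea,
        other_allele=oa,
        chrom=chrom,
        pos=pos,
        beta=beta,
        se=se,
        pvalue=pvalue,
        zscore=zscore,
        frequency=frequency,
        n=n,
    )


def parse_gwas(path, column_map: Mapping[str, str], sep: str | None = None) -> list[GwasRecord]:
    """Parse a delimited GWAS summary file into records.

    Parameters
    ----------
    path:
        TSV/CSV file, optionally gzipped (inferred from the ``.gz`` suffix).
    column_map:
        Maps field names (``variant_id``, ``effect_allele``, ``other_allele``,
        and optionally ``chrom``, ``pos``, ``beta``, ``odds_ratio``, ``se``,
        ``pvalue``, ``zscore``, ``frequency``, ``n``) to column names in the
        file.
    sep:
        Field separator; sniffed by pandas when omitted.

    Rows that cannot be interpreted are skipped with a logged warning; row
    order is preserved.
    """
    for fieldname in _MANDATORY:
        if fieldname not in column_map:
            raise GwasConfigurationError(f"column_map is missing mandatory field {fieldname!r}")
    unknown = set(column_map) - set(_MANDATORY) - set(_OPTIONAL)
    if unknown:
        raise GwasConfigurationError(f"unknown column_map fields: {sorted(unknown)}")

    table = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    missing_cols = [c for c in column_map.values() if c not in table.columns]
    if missing_cols:
        raise GwasConfigurationError(f"columns not found in {path}: {missing_cols}")

    records: list[GwasRecord] = []
    for _, row in table.iterrows():
        try:
            record = _build_record(row, column_map)
        except ValueError as exc:
            log.warning("skipping row (%s)", exc)
            continue
        if record is not None:
            records.append(record)
    return records


@dataclass
class HarmonizationReport:
    """Per-category counts from allele harmonization."""

    n_input: int = 0
    n_matched: int = 0
    n_flipped: int = 0
    n_ambiguous: int = 0
    n_mismatched: int = 0
    n_absent: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_matched + self.n_flipped

    @property
    def is_empty(self) -> bool:
        """True when no record survived harmonization."""
        return self.n_kept == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": ["matched", "flipped", "ambiguous", "mismatched", "absent"],
                "count": [
                    self.n_matched,
                    self.n_flipped,
                    self.n_ambiguous,
                    self.n_mismatched,
                    self.n_absent,
                ],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def harmonize(
    records: Iterable[GwasRecord],
    frame: Mapping[str, tuple[str, str]],
) -> tuple[list[GwasRecord], HarmonizationReport]:
    """Align GWAS records to a model/reference allele frame.

    ``frame`` maps variant id to its (effect_allele, other_allele).  Records
    matching the frame pass through; swapped records have their effect sign
    flipped and frequency mapped f -> 1-f; strand-ambiguous pairs and
    mismatched allele sets are removed.  Ambiguity is checked first, so an
    A/T record is counted as ambiguous even when its alleles also fail to
    match the frame.
    """
    report = HarmonizationReport()
    kept: list[GwasRecord] = []
    for record in records:
        report.n_input += 1
        if is_ambiguous(record.effect_allele, record.other_allele):
            report.n_ambiguous += 1
            continue
        entry = frame.get(record.variant_id)
        if entry is None:
            report.n_absent += 1
            continue
        frame_ea, frame_oa = entry[0].upper(), entry[1].upper()
        if (record.effect_allele, record.other_allele) == (frame_ea, frame_oa):
            report.n_matched += 1
            kept.append(record)
        elif (record.effect_allele, record.other_allele) == (frame_oa, frame_ea):
            report.n_flipped += 1
            kept.append(record.flipped())
        else:
            report.n_mismatched += 1
    if report.is_empty:
        log.warning("harmonization produced an empty record set (%d inputs)", report.n_input)
    return kept, report


def records_index(records: Iterable[GwasRecord]) -> dict[str, GwasRecord]:
    """Index records by variant id (last occurrence wins)."""
    return {r.variant_id: r for r in records}


def records_to_frame(records: Sequence[GwasRecord]) -> pd.DataFrame:
    """Tabular view of a record collection."""
    return pd.DataFrame([vars(r) for r in records])


def fill_frequency_from_reference(
    records: Iterable[GwasRecord],
    reference_frequency: Mapping[str, float],
) -> list[GwasRecord]:
    """Fill missing effect-allele frequencies from a reference panel.

    Frequencies in ``reference_frequency`` must refer to the same effect
    allele as the (already harmonized) records.
    """
    out = []
    for record in records:
        if record.frequency is None and record.variant_id in reference_frequency:
            record = replace(record, frequency=float(reference_frequency[record.variant_id]))
        out.append(record)
    return out
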