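"""Colocalization of eQTL and GWAS signals, and the staged gene filter.

A significant gene-level association can be LD contamination: the SNPs
predicting expression and the SNPs causal for the phenotype are distinct
but correlated.  Under a single-causal-variant assumption per trait, the
approximate-Bayes-factor colocalization model assigns posterior
probabilities to five region configurations:

    H0 no signal; H1 eQTL only; H2 GWAS only;
    H3 both, independent signals; H4 both, one shared signal.

Genes are classified from (P3, P4): colocalized when P4 > 0.5,
independent (LD-contaminated) when P3 > 0.5, otherwise undetermined;
1 - P3 - P4 aggregates the three limited-power hypotheses.

The suggested analysis pipeline stacks four nested filters: Bonferroni on
the gene associations, Bonferroni on prediction performance among the
survivors, removal of likely LD contamination (P3 < 0.5), and optionally
explicit colocalization evidence (P4 > 0.5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .gwas import GwasRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of carrying each kind of signal."""

    p1: float = 1e-4  # eQTL association only
    p2: float = 1e-4  # GWAS association only
    p12: float = 1e-5  # shared causal variant

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be positive")
        if self.p12 > min(self.p1, self.p2):
            log.warning("p12=%g exceeds min(p1, p2); unusual prior choice", self.p12)


@dataclass
class TraitRegion:
    """Per-SNP association summaries for one trait over a region.

    Bayes factors are computed from beta/se when available; otherwise from
    Z-scores with the variance of beta approximated from allele frequency
    and sample size.  ``sd_prior`` overrides the prior effect-size scale
    (default 0.15 x sdY for quantitative traits, 0.2 for case-control).
    """

    variant_ids: list[str]
    beta: np.ndarray | None = None
    se: np.ndarray | None = None
    zscore: np.ndarray | None = None
    frequency: np.ndarray | None = None
    n: int | None = None
    trait_type: str = "quantitative"  # quantitative | case_control
    case_fraction: float | None = None
    sd_prior: float | None = None

    def __post_init__(self) -> None:
        for name in ("beta", "se", "zscore", "frequency"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, np.asarray(value, dtype=float))
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "case_control" and self.case_fraction is None:
            raise ValueError("case_control regions need a case_fraction")

    @classmethod
    def from_records(
        cls, records: Sequence[GwasRecord], trait_type: str = "quantitative",
        case_fraction: float | None = None,
    ) -> "TraitRegion":
        if any(r.frequency is None for r in records):
            raise ValueError(
                "records are missing allele frequencies; fill from a reference panel first"
            )
        ns = [r.n for r in records if r.n is not None]
        return cls(
            variant_ids=[r.variant_id for r in records],
            beta=None if any(r.beta is None for r in records) else [r.beta for r in records],
            se=None if any(r.se is None for r in records) else [r.se for r in records],
            zscore=[r.zscore for r in records],
            frequency=[r.frequency for r in records],
            n=min(ns) if ns else None,
            trait_type=trait_type,
            case_fraction=case_fraction,
        )

    def _estimate_sdy2(self) -> float:
        """Phenotype variance from var(beta), frequency, and sample size.

        Regression through the origin of 2 n f (1-f) on 1/var(beta); the
        slope is sdY^2.  Falls back to 1.0 when the inputs are unavailable.
        """
        if self.se is None or self.frequency is None or self.n is None:
            return 1.0
        oneover = 1.0 / self.se**2
        nvx = 2.0 * self.n * self.frequency * (1.0 - self.frequency)
        denom = float(np.sum(oneover**2))
        if denom <= 0:
            return 1.0
        slope = float(np.sum(nvx * oneover) / denom)
        return slope if slope > 0 else 1.0

    def log_abf(self, index: Mapping[str, int] | None = None) -> np.ndarray:
        """Wakefield log approximate Bayes factors, one per SNP."""
        if self.beta is not None and self.se is not None:
            z = self.beta / self.se
            v = self.se**2
        elif self.zscore is not None:
            if self.frequency is None or self.n is None:
                raise ValueError("Z-score regions need frequency and sample size")
            z = self.zscore
            denom = 2.0 * self.n * self.frequency * (1.0 - self.frequency)
            if self.trait_type == "case_control":
                denom = denom * self.case_fraction * (1.0 - self.case_fraction)
            v = 1.0 / denom
        else:
            raise ValueError("region has neither beta/se nor zscore")
        if self.sd_prior is not None:
            w = self.sd_prior**2
        elif self.trait_type == "case_control":
            w = 0.2**2
        else:
            w = (0.15**2) * self._estimate_sdy2()
        r = w / (w + v)
        return 0.5 * (np.log1p(-r) + r * z**2)


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization configurations."""

    gene_id: str
    p0: float
    p1: float
    p2: float
    p3: float
    p4: float
    degenerate: bool = False  # single shared SNP: H3 impossible

    @property
    def limited_power(self) -> float:
        """Aggregate probability of H0+H1+H2 (no usable signal)."""
        return self.p0 + self.p1 + self.p2

    @property
    def ternary_class(self) -> str:
        return classify_ternary(self)

    def posteriors(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2, self.p3, self.p4])


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference vanishes."""
    if b >= a:
        return -math.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(
    gwas_region: TraitRegion,
    eqtl_region: TraitRegion,
    priors: ColocPriors = ColocPriors(),
    gene_id: str = "",
) -> ColocResult:
    """Posterior colocalization probabilities for one gene region.

    Both regions are intersected on variant id; with a single shared SNP
    the independent-signals configuration is impossible and the result is
    flagged degenerate.
    """
    shared = [v for v in gwas_region.variant_ids if v in set(eqtl_region.variant_ids)]
    if not shared:
        raise ValueError("no shared SNPs between GWAS and eQTL regions")
    gpos = {v: i for i, v in enumerate(gwas_region.variant_ids)}
    epos = {v: i for i, v in enumerate(eqtl_region.variant_ids)}
    l_gwas = gwas_region.log_abf()[[gpos[v] for v in shared]]
    l_eqtl = eqtl_region.log_abf()[[epos[v] for v in shared]]

    ls_eqtl = float(logsumexp(l_eqtl))
    ls_gwas = float(logsumexp(l_gwas))
    ls_both = float(logsumexp(l_eqtl + l_gwas))

    lh = np.array(
        [
            0.0,
            math.log(priors.p1) + ls_eqtl,
            math.log(priors.p2) + ls_gwas,
            math.log(priors.p1) + math.log(priors.p2)
            + _log_diff_exp(ls_eqtl + ls_gwas, ls_both),
            math.log(priors.p12) + ls_both,
        ]
    )
    post = np.exp(lh - logsumexp(lh))
    post = post / post.sum()
    return ColocResult(
        gene_id=gene_id,
        p0=float(post[0]),
        p1=float(post[1]),
        p2=float(post[2]),
        p3=float(post[3]),
        p4=float(post[4]),
        degenerate=len(shared) == 1,
    )


def classify_ternary(result: ColocResult, threshold: float = 0.5) -> str:
    """colocalized (P4 > t), independent (P3 > t), else undetermined.

    Inequalities are strict: boundary mass goes to undetermined.
    """
    if result.p4 > threshold:
        return "colocalized"
    if result.p3 > threshold:
        return "independent"
    return "undetermined"


def ternary_coordinates(results: Sequence[ColocResult]) -> pd.DataFrame:
    """(P3, P4, 1-P3-P4) per gene, for ternary plotting."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "p3": [r.p3 for r in results],
            "p4": [r.p4 for r in results],
            "limited_power": [r.limited_power for r in results],
            "class": [r.ternary_class for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Staged association pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    priors: ColocPriors = field(default_factory=ColocPriors)
    class_threshold: float = 0.5
    keep_missing_coloc: bool = False  # drop step-3 survivors without a coloc result


@dataclass
class PipelineResult:
    """Nested gene-tissue sets surviving each filter, with realized thresholds."""

    stages: dict[int, list[str]]
    counts: dict[int, int]
    step1_threshold: float
    step2_threshold: float | None
    n_missing_coloc: int


def run_pipeline(
    associations: pd.DataFrame,
    colocs: Mapping[str, ColocResult],
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Apply the four-step gene filter.

    ``associations`` needs columns ``key`` (gene or gene-tissue identifier;
    ``gene_id`` is accepted as an alias), ``pvalue`` (gene association) and
    ``pred_perf_pval`` (model performance).  Thresholds are computed from
    the realized set sizes: step 1 keeps p < alpha / n_tested, step 2 keeps
    pred_perf_pval < alpha / n_step1, step 3 keeps P3 < 0.5, step 4 keeps
    P4 > 0.5.
    """
    table = associations.copy()
    if "key" not in table.columns:
        table["key"] = table["gene_id"]
    n_tested = int(table["pvalue"].notna().sum())
    step1_threshold = config.alpha / n_tested if n_tested else float("nan")
    step1 = table[table["pvalue"] < step1_threshold] if n_tested else table.iloc[0:0]

    if len(step1):
        step2_threshold = config.alpha / len(step1)
        step2 = step1[step1["pred_perf_pval"] < step2_threshold]
    else:
        step2_threshold = None
        step2 = step1

    n_missing = 0
    step3_keys, step4_keys = [], []
    for key in step2["key"]:
        coloc = colocs.get(key)
        if coloc is None:
            n_missing += 1
            if config.keep_missing_coloc:
                step3_keys.append(key)
            continue
        if coloc.p3 < config.class_threshold:
            step3_keys.append(key)
            if coloc.p4 > config.class_threshold:
                step4_keys.append(key)
    if n_missing:
        log.warning("%d step-2 survivors had no colocalization result", n_missing)

    stages = {
        1: step1["key"].tolist(),
        2: step2["key"].tolist(),
        3: step3_keys,
        4: step4_keys,
    }
    return PipelineResult(
        stages=stages,
        counts={k: len(v) for k, v in stages.items()},
        step1_threshold=step1_threshold,
        step2_threshold=step2_threshold,
        n_missing_coloc=n_missing,
    )


def enrichment_mean_z2(zscores_by_group: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Simple mean of Z^2 per group (phenotype or tissue); empty groups omitted."""
    out = {}
    for group, zs in zscores_by_group.items():
        z = np.asarray(list(zs), dtype=float)
        if z.size:
            out[group] = float(np.mean(z**2))
    return out
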