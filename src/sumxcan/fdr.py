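"""False-discovery-rate estimation for model retention.

Prediction models are kept only when their cross-validated performance
p-value survives an FDR threshold.  The q-value of a p-value is the
minimum FDR at which it would be called significant; Storey's estimator
scales the Benjamini-Hochberg adjustment by an estimate of pi0, the
proportion of true nulls.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

# pi0 is estimated on this grid and smoothed, following Storey & Tibshirani.
_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)
_MIN_P_FOR_STOREY = 20


def estimate_pi0(pvalues: np.ndarray) -> float:
    """Smoothed-grid estimate of the proportion of true null hypotheses.

    Returns 1.0 (the Benjamini-Hochberg fallback) when there are too few
    p-values for the grid to be stable or when the estimate leaves (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < _MIN_P_FOR_STOREY:
        return 1.0
    pi0_grid = np.array([np.mean(p > lam) / (1.0 - lam) for lam in _LAMBDA_GRID])
    try:
        spline = UnivariateSpline(_LAMBDA_GRID, pi0_grid, k=3)
        pi0 = float(spline(_LAMBDA_GRID[-1]))
    except Exception:  # degenerate grids (e.g., all identical p-values)
        return 1.0
    if not np.isfinite(pi0) or pi0 > 1.0 or pi0 <= 0.0:
        return 1.0
    return pi0


def qvalues(pvalues) -> np.ndarray:
    """q-values for a set of p-values (Storey pi0 x Benjamini-Hochberg)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    pi0 = estimate_pi0(p)
    _, p_bh, _, _ = multipletests(p, method="fdr_bh")
    return np.minimum(pi0 * p_bh, 1.0)
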