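"""Summary statistics used in the recovery analyses.

Accuracy is mean absolute error (MAE); precision is the sample standard
deviation across measurements; method comparisons use a paired t test on
per-lesion differences; bias-vs-truth scatter gets a least-squares line with
its coefficient of determination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["SummaryStats", "mae", "sample_sd", "paired_t", "linear_fit_r2"]


@dataclass(frozen=True)
class SummaryStats:
    slope: float
    intercept: float
    r2: float
    n: int


def mae(values, truth: float) -> float:
    """Mean absolute deviation from ``truth``.

    When aggregating recovery coefficients the reference is RC = 100 %.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mae needs at least one value")
    return float(np.abs(arr - truth).mean())


def sample_sd(values) -> float:
    """√(Σ(aᵢ − ā)²/(n−1)); requires n ≥ 2."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("sample SD needs at least two values")
    return float(arr.std(ddof=1))


def paired_t(values_a, values_b) -> tuple[float, float, int]:
    """Paired t test on d = a − b: t = |mean d| / (sd(d)/√n), two-sided p.

    Returns (t, p, n).  Raises on unequal lengths, n < 2, or zero-variance
    differences (the statistic is undefined there).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t needs n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0, n  # identical samples: no evidence of difference
        raise ValueError("zero-variance differences: paired t undefined")
    t = abs(mean) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(t, df=n - 1)
    return float(t), float(p), n


def linear_fit_r2(x, y) -> SummaryStats:
    """Least-squares line with r² = 1 − SS_res/SS_tot.

    Raises on constant x (no line) and on constant y (SS_tot = 0, r²
    undefined by the formula).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("linear fit needs matched x, y with n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("y is constant: r² undefined (SS_tot = 0)")
    res = sps.linregress(x, y)
    y_hat = res.intercept + res.slope * x
    ss_res = float(((y - y_hat) ** 2).sum())
    return SummaryStats(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=1.0 - ss_res / ss_tot,
        n=x.size,
    )
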