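"""Nonparametric two-sample and paired comparisons.

Two-sided Mann-Whitney U for independent groups and the Wilcoxon
signed-rank test for paired differences, with the exact null distribution
used for small samples and the tie-corrected normal approximation
otherwise.  The method actually used is reported alongside the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "mann_whitney_u", "wilcoxon_signed_rank"]


@dataclass
class ComparisonResult:
    test: str
    n1: int
    n2: int
    statistic: float
    p_value: float
    method: str  # "exact" or "approximate"
    mean1: float | None = None
    sem1: float | None = None
    mean2: float | None = None
    sem2: float | None = None
    n_zeros_dropped: int = 0


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return m, s


def mann_whitney_u(a, b) -> ComparisonResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Exact p-value when the combined sample size is at most 16 and there
    are no ties; tie-corrected normal approximation (without continuity
    correction, which the exact path does not use either) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    use_exact = (len(a) + len(b)) <= 16 and no_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    m1, s1 = _mean_sem(a)
    m2, s2 = _mean_sem(b)
    return ComparisonResult(
        test="mann_whitney_u",
        n1=len(a),
        n2=len(b),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if use_exact else "approximate",
        mean1=m1,
        sem1=s1,
        mean2=m2,
        sem2=s2,
    )


def wilcoxon_signed_rank(diffs) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (and counted in the result).  Exact
    p-value for up to 12 nonzero differences with untied magnitudes;
    normal approximation otherwise.
    """
    diffs = np.asarray(diffs, dtype=float)
    nz = diffs[diffs != 0]
    dropped = len(diffs) - len(nz)
    if len(nz) == 0:
        raise ValueError("all paired differences are zero")
    mags = np.abs(nz)
    no_ties = len(np.unique(mags)) == len(mags)
    use_exact = len(nz) <= 12 and no_ties
    res = sps.wilcoxon(
        nz, alternative="two-sided", method="exact" if use_exact else "approx"
    )
    m1, s1 = _mean_sem(nz)
    return ComparisonResult(
        test="wilcoxon_signed_rank",
        n1=len(nz),
        n2=len(nz),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if use_exact else "approximate",
        mean1=m1,
        sem1=s1,
        n_zeros_dropped=dropped,
    )
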