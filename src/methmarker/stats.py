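"""Shared two-sample and paired tests used across pipeline stages.

Three tests cover every inferential step in the pipeline: Fisher's exact
test for marker x outcome 2x2 tables, the Mann-Whitney U test for
continuous levels (expression, pyrosequencing methylation) between pCR and
non-pCR groups, and the Wilcoxon signed-rank test for paired
baseline/on-treatment comparisons.

Fisher and Mann-Whitney delegate to scipy.stats.  The Mann-Whitney exact
p-value (enumeration of group assignments) is used when both groups have
<= 10 observations and there are no ties; otherwise the tie-corrected
normal approximation with continuity correction applies.

The Wilcoxon exact path is implemented here by direct enumeration of all
2^n sign assignments (n <= 15 after dropping zero differences) using
midranks of |d|, so tied absolute differences are handled exactly; for
larger n the normal approximation with tie correction is used.  Zero
differences are dropped before ranking (standard practice); if all
differences are zero the test is degenerate and p = 1 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import ValidationError

__all__ = [
    "fisher_exact_2x2",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "MannWhitneyResult",
    "WilcoxonResult",
]

_EXACT_MW_MAX_N = 10
_EXACT_WILCOXON_MAX_N = 15


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table ``[[a, b], [c, d]]``.

    Two-sided by summing hypergeometric probabilities of tables at least
    as extreme as the observed one (the standard definition).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("Fisher test requires a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValidationError("Fisher test on an empty table")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float  # U statistic of the first group
    p: float
    exact: bool


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of ``x`` versus ``y``.

    ``U`` is reported for the first group (number of (x, y) pairs with
    x > y, ties counting 1/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("Mann-Whitney test requires at least one observation per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and x.size <= _EXACT_MW_MAX_N and y.size <= _EXACT_MW_MAX_N
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(U=float(res.statistic), p=min(1.0, float(res.pvalue)), exact=exact)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-) over nonzero differences
    p: float
    n_nonzero: int
    exact: bool


def _wilcoxon_exact(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Uses midranks of |d| so tied magnitudes are exact.  p = P(W+ <= w_min)
    + P(W+ >= w_max) under uniform random signs, capped at 1.
    """
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w_min, w_max = min(w_pos, w_neg), max(w_pos, w_neg)
    # all 2^n subsets: bit j of k says rank j carries a positive sign
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w_all = masks @ ranks
    eps = 1e-9
    p = (np.count_nonzero(w_all <= w_min + eps) + np.count_nonzero(w_all >= w_max - eps)) / 2.0**n
    return w_min, min(1.0, p)


def wilcoxon_signed_rank(baseline, on_treatment=None) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Call with two paired arrays, or with a single array of differences.
    Zero differences are dropped; if none remain the result is the
    degenerate p = 1 (with a warning).
    """
    if on_treatment is None:
        d = np.asarray(baseline, dtype=float)
    else:
        b = np.asarray(baseline, dtype=float)
        t = np.asarray(on_treatment, dtype=float)
        if b.size != t.size:
            raise ValidationError("paired arrays must have equal length")
        d = b - t
    if d.size == 0:
        raise ValidationError("signed-rank test requires at least one pair")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; signed-rank test is degenerate (p = 1)")
        return WilcoxonResult(statistic=0.0, p=1.0, n_nonzero=0, exact=True)
    if d.size <= _EXACT_WILCOXON_MAX_N:
        stat, p = _wilcoxon_exact(d)
        return WilcoxonResult(statistic=stat, p=p, n_nonzero=int(d.size), exact=True)
    res = sps.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
    return WilcoxonResult(
        statistic=float(res.statistic), p=min(1.0, float(res.pvalue)),
        n_nonzero=int(d.size), exact=False,
    )
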