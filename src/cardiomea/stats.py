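"""Rank-based hypothesis tests with exact small-sample p values.

Both tests report two-sided p values.  At small sample sizes the exact
null distribution is enumerated (all group labelings for Mann-Whitney,
all sign assignments for Wilcoxon); beyond the enumeration thresholds, or
in the presence of ties, a tie-corrected normal approximation with
continuity correction is used.  The two-sided exact p is
``min(1, 2 * min(P(T <= t), P(T >= t)))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

#: Largest combined n for exact Mann-Whitney enumeration (C(12,6) = 924).
MWU_EXACT_MAX_N = 12
#: Largest n for exact Wilcoxon sign enumeration (2^15 = 32768).
WILCOXON_EXACT_MAX_N = 15


@dataclass(frozen=True)
class TestResult:
    statistic: float
    n: tuple[int, ...]
    p_value: float
    method: str  # "exact" | "normal"
    tie_corrected: bool = False
    degenerate: bool = False


def _two_sided_exact(dist: np.ndarray, observed: float) -> float:
    lo = np.mean(dist <= observed + 1e-9)
    hi = np.mean(dist >= observed - 1e-9)
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney_u(x, y) -> TestResult:
    """Independent-samples Mann-Whitney U test (two-sided).

    The statistic is U of the first group with midrank ties.  Exact p by
    enumeration of all ``C(n_x + n_y, n_x)`` labelings when the combined n
    is <= 12 and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    n = nx + ny

    if n <= MWU_EXACT_MAX_N and not has_ties:
        # ranks are a permutation of 1..n; enumerate which go to group x
        dist = np.asarray(
            [sum(c) - nx * (nx + 1) / 2.0 for c in combinations(range(1, n + 1), nx)],
            dtype=float,
        )
        p = _two_sided_exact(dist, u_x)
        return TestResult(u_x, (nx, ny), p, "exact")

    mean_u = nx * ny / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return TestResult(u_x, (nx, ny), 1.0, "normal", tie_corrected=has_ties, degenerate=True)
    diff = u_x - mean_u
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var_u)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return TestResult(u_x, (nx, ny), p, "normal", tie_corrected=has_ties)


def wilcoxon_signed_rank(before, after) -> TestResult:
    """Related-samples Wilcoxon signed-rank test (two-sided).

    Differences ``after - before``; zero differences are dropped (the
    documented convention).  The statistic is W+, the sum of ranks of
    positive differences.  Exact p by enumeration of all 2^n sign
    assignments when n <= 15 and the absolute differences are untied;
    otherwise the tie-corrected normal approximation.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    d = after - before
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(0.0, (0,), 1.0, "exact", degenerate=True)
    abs_ranks = rankdata(np.abs(d))
    w_plus = float(abs_ranks[d > 0].sum())
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n <= WILCOXON_EXACT_MAX_N and not has_ties:
        ranks = np.arange(1, n + 1)
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
        dist = signs @ ranks
        p = _two_sided_exact(dist, w_plus)
        return TestResult(w_plus, (n,), p, "exact")

    mean_w = n * (n + 1) / 4.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - float((tie_counts**3 - tie_counts).sum()) / 48.0
    if var_w <= 0:
        return TestResult(w_plus, (n,), 1.0, "normal", tie_corrected=has_ties, degenerate=True)
    diff = w_plus - mean_w
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var_w)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return TestResult(w_plus, (n,), p, "normal", tie_corrected=has_ties)
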