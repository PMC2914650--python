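"""Nonparametric statistics shared by all analyses.

Conventions (pinned so results are reproducible across environments):

* Spearman rho uses mid-ranks for ties.  The two-sided p-value comes from the
  exact permutation distribution for n <= 10 and from the t approximation
  ``t = rho * sqrt((n-2)/(1-rho^2))`` otherwise.
* The Wilcoxon rank-sum (Mann–Whitney) p is exact (enumeration over rank
  assignments, two-sided as ``2 * min(P(U<=u), P(U>=u))`` capped at 1) when
  ``n_a + n_b <= 12`` and there are no ties, and a tie-corrected normal
  approximation with continuity correction otherwise.
* Fisher's exact two-sided p uses the probability-mass definition: the sum of
  hypergeometric probabilities of all tables with the same margins whose
  probability does not exceed that of the observed table.  The odds ratio is
  the sample odds ratio (a*d)/(b*c), infinite when b*c = 0 and a*d > 0.

These are the defaults of the standard statistical environments for these
tests; rho/U/p computation delegates to scipy where scipy implements the
pinned convention, with the exact small-sample Spearman p implemented here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with a two-sided p-value over n pairs."""

    rho: float
    p_value: float
    n: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.rho)


@dataclass(frozen=True)
class GroupComparisonResult:
    median_a: float
    median_b: float
    p_value: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = group 1 / group 2, columns = outcome yes / no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if int(v) != v or v < 0:
                raise StatError(f"table entry {name}={v} must be a count >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise StatError("contingency table is all zeros")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class ContingencyResult:
    odds_ratio: float  # may be math.inf; nan when both cross products are 0
    p_value: float
    table: ContingencyTable2x2


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

_EXACT_SPEARMAN_MAX_N = 10
_PERM_CHUNK = 200_000


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with the two-sided p convention above.

    Constant input leaves rho undefined; the result carries NaN and
    ``defined`` is False.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise StatError("x and y must be 1-D sequences of equal length")
    n = len(x)
    if n < 3:
        raise StatError(f"need at least 3 pairs, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatError("non-finite values in input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(rho=math.nan, p_value=math.nan, n=n)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if n <= _EXACT_SPEARMAN_MAX_N:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        p = _spearman_t_approx_p(rho, n)
    return CorrelationResult(rho=rho, p_value=p, n=n)


def _spearman_t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p: share of permutations of y-ranks with |rho| as or
    more extreme than observed (ties handled because mid-ranks are permuted)."""
    n = len(rx)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
    thresh = abs(rho_obs) * denom - 1e-9 * denom
    count = 0
    total = 0
    perms = itertools.permutations(cy)
    while True:
        chunk = list(itertools.islice(perms, _PERM_CHUNK))
        if not chunk:
            break
        arr = np.asarray(chunk)
        stats = np.abs(arr @ cx)
        count += int(np.count_nonzero(stats >= thresh))
        total += len(chunk)
    return count / total


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

_EXACT_RANKSUM_MAX_N = 12


def wilcoxon_rank_sum(a, b) -> GroupComparisonResult:
    """Two-sided Wilcoxon rank-sum comparison of two samples.

    Reports both group medians alongside the p-value.  Identical constant
    groups carry no evidence and yield p = 1 under the tie-corrected
    approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise StatError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(pooled) <= _EXACT_RANKSUM_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    if np.ptp(pooled) == 0:
        p = 1.0  # all observations tied: zero-variance normal approximation
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        p = float(res.pvalue)
        if not math.isfinite(p):
            p = 1.0
    return GroupComparisonResult(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        p_value=p,
        n_a=len(a),
        n_b=len(b),
    )


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table: ContingencyTable2x2) -> ContingencyResult:
    """Fisher's exact test on a 2x2 table, probability-mass two-sided p.

    The odds ratio is the sample odds ratio (a*d)/(b*c); a zero denominator
    with a positive numerator gives +inf, and 0/0 gives NaN.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    num = a * d
    den = b * c
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = math.inf
    else:
        odds = math.nan
    p = float(sps.fisher_exact(table.as_array(), alternative="two-sided").pvalue)
    return ContingencyResult(odds_ratio=odds, p_value=min(p, 1.0), table=table)
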