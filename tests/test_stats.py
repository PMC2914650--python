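"""Oracle-backed tests for the nonparametric statistics.

Each test compares the implementation against an independent brute-force
computation: hypergeometric enumeration for Fisher's exact test, enumeration
of rank assignments for the rank-sum test, and permutation enumeration for
Spearman's exact p.
"""

import itertools
import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirnetevo.stats import (
    ContingencyTable2x2,
    StatError,
    fisher_exact_2x2,
    spearman,
    wilcoxon_rank_sum,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def fisher_oracle_p(a, b, c, d):
    """Two-sided probability-mass Fisher p by hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(k):
        if k < max(0, c1 - r2) or k > min(r1, c1):
            return 0.0
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = pmf(a)
    return sum(
        pk for k in range(min(r1, c1) + 1) if (pk := pmf(k)) <= p_obs * (1 + 1e-12)
    )


def ranksum_oracle_p(x, y):
    """Exact two-sided rank-sum p: enumerate all C(n, n_x) rank assignments."""
    pooled = sorted(x + y)
    n, nx = len(pooled), len(x)
    rank = {v: i + 1 for i, v in enumerate(pooled)}  # no ties by construction
    w_obs = sum(rank[v] for v in x)
    ws = [sum(c) for c in itertools.combinations(range(1, n + 1), nx)]
    total = len(ws)
    p_le = sum(w <= w_obs for w in ws) / total
    p_ge = sum(w >= w_obs for w in ws) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def _rho_from_ranks(rx, ry):
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def spearman_oracle(x, y):
    """(rho, exact permutation p) computed from first principles."""
    rx, ry = _midranks(list(x)), _midranks(list(y))
    rho_obs = _rho_from_ranks(rx, ry)
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_rho_from_ranks(rx, list(perm))) >= abs(rho_obs) - 1e-9:
            count += 1
    return rho_obs, count / total


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, expected_rho",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (6, 4, 2), -1.0),
            ((1, 2, 3, 4), (2, 1, 4, 3), 0.6),  # sum d^2 = 4, 1 - 24/60
        ],
    )
    def test_known_rho(self, x, y, expected_rho):
        assert spearman(x, y).rho == pytest.approx(expected_rho)

    def test_exact_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        for n in (4, 5, 6):
            for _ in range(3):
                x = rng.normal(size=n)
                y = rng.normal(size=n)
                rho_o, p_o = spearman_oracle(x, y)
                got = spearman(x, y)
                assert got.rho == pytest.approx(rho_o, abs=1e-12)
                assert got.p_value == pytest.approx(p_o, abs=1e-12)

    def test_exact_p_with_ties_matches_oracle(self):
        x = [1.0, 1.0, 2.0, 3.0, 3.0]
        y = [2.0, 1.0, 1.0, 3.0, 2.0]
        rho_o, p_o = spearman_oracle(x, y)
        got = spearman(x, y)
        assert got.rho == pytest.approx(rho_o, abs=1e-12)
        assert got.p_value == pytest.approx(p_o, abs=1e-12)

    def test_constant_input_is_undefined(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined and math.isnan(res.p_value)

    def test_length_mismatch_and_small_n_rejected(self):
        with pytest.raises(StatError):
            spearman([1, 2], [1, 2, 3])
        with pytest.raises(StatError):
            spearman([1, 2], [3, 4])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.integers(-100, 100), min_size=4, max_size=9).filter(
            lambda v: len(set(v)) > 1
        )
    )
    def test_symmetry_and_monotone_invariance(self, x):
        x = [float(v) for v in x]
        rng = np.random.default_rng(0)
        y = list(rng.normal(size=len(x)))
        a = spearman(x, y)
        b = spearman(y, x)
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        # strictly monotone transform of x leaves the result unchanged
        c = spearman([3.0 * v + 10.0 for v in x], y)
        assert c.rho == pytest.approx(a.rho, abs=1e-12)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


class TestWilcoxonRankSum:
    def test_separated_groups_exact_p(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 as extreme
        assert (res.median_a, res.median_b) == (2.0, 5.0)

    def test_interleaved_groups_exact_p(self):
        res = wilcoxon_rank_sum([1, 3], [2, 4])
        assert res.p_value == pytest.approx(2 / 3)  # P(W<=4)=2/6, doubled

    def test_identical_constant_groups(self):
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5, 5]).p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(StatError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for n_a, n_b in [(2, 3), (3, 3), (4, 5), (5, 6), (6, 6)]:
            vals = rng.permutation(100)[: n_a + n_b].astype(float)
            a, b = list(vals[:n_a]), list(vals[n_a:])
            assert wilcoxon_rank_sum(a, b).p_value == pytest.approx(
                ranksum_oracle_p(a, b), abs=1e-12
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=8),
        st.lists(st.integers(0, 50), min_size=1, max_size=8),
    )
    def test_symmetric_in_group_order(self, a, b):
        pa = wilcoxon_rank_sum(a, b).p_value
        pb = wilcoxon_rank_sum(b, a).p_value
        assert pa == pytest.approx(pb, abs=1e-12)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


class TestFisherExact:
    def test_printed_table_odds_ratio(self):
        res = fisher_exact_2x2(ContingencyTable2x2(349, 1327, 121, 893))
        assert round(res.odds_ratio, 2) == 1.94

    def test_balanced_table(self):
        res = fisher_exact_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.odds_ratio == 1.0 and res.p_value == pytest.approx(1.0)

    def test_small_table_exact_value(self):
        res = fisher_exact_2x2(ContingencyTable2x2(3, 1, 1, 3))
        assert res.odds_ratio == 9.0
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)

    def test_infinite_and_nan_odds_ratio(self):
        assert math.isinf(fisher_exact_2x2(ContingencyTable2x2(3, 0, 1, 3)).odds_ratio)
        assert math.isnan(fisher_exact_2x2(ContingencyTable2x2(0, 2, 0, 3)).odds_ratio)

    def test_negative_entry_rejected(self):
        with pytest.raises(StatError):
            ContingencyTable2x2(-1, 2, 3, 4)

    def test_matches_hypergeometric_oracle_randomized(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 11, size=4))
            if a + b + c + d == 0:
                continue
            got = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
            assert got == pytest.approx(fisher_oracle_p(a, b, c, d), abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4).filter(lambda t: sum(t) > 0))
    def test_invariant_under_row_and_column_swap(self, t):
        a, b, c, d = t
        p1 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
        p2 = fisher_exact_2x2(ContingencyTable2x2(d, c, b, a)).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)
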