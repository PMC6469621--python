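import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given
from hypothesis import strategies as st

from pcbrisk import kruskal_wallis, mann_whitney_u, spearman_rs
from pcbrisk.concentrations import DomainError
from pcbrisk.ranktests import _mw_z, _u_statistic, holm_adjust


def brute_force_mw_p(x, y):
    """Two-sided permutation p by explicit pair counting over every
    assignment of the pooled values to the two labels."""
    pooled = list(x) + list(y)
    nx, n = len(x), len(x) + len(y)
    centre = nx * len(y)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys
        )

    dev = abs(2 * u_of(tuple(range(nx))) - centre)
    hits = total = 0
    for idx in itertools.combinations(range(n), nx):
        total += 1
        if abs(2 * u_of(idx) - centre) >= dev - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_separated_groups(self):
        result = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_multisets_give_p_one(self):
        result = mann_whitney_u([1, 2, 2], [1, 2, 2], mode="exact")
        assert result.p_value == 1.0

    def test_exact_equals_brute_force_for_all_small_sizes(self):
        rng = np.random.default_rng(42)
        for nx in range(1, 10):
            for ny in range(1, 11 - nx):
                x = rng.integers(0, 4, nx).astype(float)
                y = rng.integers(0, 4, ny).astype(float)
                exact = mann_whitney_u(x, y, mode="exact").p_value
                assert exact == pytest.approx(
                    brute_force_mw_p(list(x), list(y)), abs=1e-12
                ), (nx, ny)

    def test_exact_matches_scipy_without_ties(self):
        x, y = [1.0, 4.0, 6.0, 9.0], [2.0, 3.0, 5.0]
        ours = mann_whitney_u(x, y, mode="exact")
        ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        assert ours.statistic == ref.statistic
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_approx_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 25).astype(float)
        ours = mann_whitney_u(x, y, mode="normal_approx")
        ref = sps.mannwhitneyu(
            x, y, method="asymptotic", alternative="two-sided"
        )
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_type_i_error_bounded_at_5_5(self):
        # exact test on untied data: enumerate every outcome and its
        # probability; attained size must not exceed the nominal level
        values = list(range(1, 11))
        reject_prob = 0.0
        total = math.comb(10, 5)
        for idx in itertools.combinations(range(10), 5):
            x = [values[i] for i in idx]
            y = [values[i] for i in range(10) if i not in idx]
            if mann_whitney_u(x, y, mode="exact").p_value < 0.05:
                reject_prob += 1 / total
        assert reject_prob <= 0.05

    def test_monotone_transform_invariance(self):
        x = [0.1, 2.0, 2.0, 7.0]
        y = [1.5, 2.0, 9.0]
        base = mann_whitney_u(x, y, mode="exact")
        for f in (math.exp, lambda v: v**3, lambda v: 5 * v - 2):
            t = mann_whitney_u([f(v) for v in x], [f(v) for v in y], "exact")
            assert t.statistic == base.statistic
            assert t.p_value == base.p_value

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney_u([], [1.0])

    def test_exact_size_limit(self):
        with pytest.raises(DomainError):
            mann_whitney_u(list(range(15)), list(range(15)), mode="exact")


class TestKruskalWallis:
    def test_constant_data_h_zero(self):
        result = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_matches_scipy_with_ties(self):
        groups = [[1, 2, 5, 5], [3, 4, 4], [7, 1, 2]]
        ours = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_two_groups_equal_squared_mw_deviate(self):
        x = [1.0, 2.0, 2.0, 5.0, 8.0]
        y = [3.0, 4.0, 4.0, 9.0]
        h = kruskal_wallis([x, y]).statistic
        u = _u_statistic(np.asarray(x), np.asarray(y))
        z = _mw_z(u, np.asarray(x + y), len(x), len(y), continuity=False)
        assert h == pytest.approx(z * z, abs=1e-9)

    def test_group_order_invariance(self):
        groups = [[1, 5, 3], [2, 2], [9, 4, 4, 7]]
        base = kruskal_wallis(groups)
        for perm in itertools.permutations(groups):
            assert kruskal_wallis(list(perm)).statistic == pytest.approx(
                base.statistic
            )

    def test_exact_matches_brute_force_permutations(self):
        groups = [[0.0, 0.0, 1.0], [2.0, 3.0, 3.0], [4.0, 5.0, 6.0]]
        ours = kruskal_wallis(groups, mode="exact")
        # oracle: distinct permutations of the pooled midranks, H from
        # the plain rank-sum formula
        pooled = np.concatenate([np.asarray(g) for g in groups])
        n = len(pooled)
        ranks = sps.rankdata(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        correction = 1 - float(np.sum(counts**3 - counts)) / (n**3 - n)
        sizes = [len(g) for g in groups]

        def h_of(perm):
            h, start = 0.0, 0
            for size in sizes:
                h += sum(perm[start : start + size]) ** 2 / size
                start += size
            return (12.0 / (n * (n + 1)) * h - 3 * (n + 1)) / correction

        seen = set()
        hits = total = 0
        for perm in itertools.permutations(ranks):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if h_of(perm) >= ours.statistic - 1e-9:
                hits += 1
        assert ours.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(DomainError):
            kruskal_wallis([[1.0, 2.0]])


class TestSpearman:
    def test_monotone_identity(self):
        assert spearman_rs([1, 2, 3, 4], [10, 20, 25, 90]).statistic == 1.0

    def test_perfect_inversion(self):
        result = spearman_rs([1, 2, 3, 4], [8, 6, 4, 2])
        assert result.statistic == -1.0
        assert result.p_value == 0.0

    def test_tied_data_midrank_oracle(self):
        # hand-assigned midranks: x -> [1.5, 1.5, 3, 4.5, 4.5, 6],
        # y -> [2, 1, 3.5, 3.5, 5, 6]
        x = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
        y = [5.0, 2.0, 7.0, 7.0, 8.0, 9.0]
        rx = [1.5, 1.5, 3.0, 4.5, 4.5, 6.0]
        ry = [2.0, 1.0, 3.5, 3.5, 5.0, 6.0]
        expected = float(np.corrcoef(rx, ry)[0, 1])
        assert spearman_rs(x, y).statistic == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 6, 20).astype(float)
        y = x + rng.normal(0, 2, 20)
        ours = spearman_rs(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    @given(
        st.lists(st.integers(-500, 500), min_size=4, max_size=12, unique=True)
    )
    def test_monotone_transform_invariance(self, grid):
        # well-separated x values so the monotone transform cannot
        # collapse distinct inputs by floating underflow
        x = [v / 10 for v in grid]
        y = [math.sin(v) for v in x]
        base = spearman_rs(x, y)
        transformed = spearman_rs([math.exp(v / 10) for v in x], y)
        assert transformed.statistic == pytest.approx(base.statistic)

    @pytest.mark.parametrize(
        "x,y,err",
        [
            ([1, 2], [3, 4], "n >= 3"),
            ([1, 2, 3], [3, 4], "equal length"),
            ([1, 1, 1], [3, 4, 5], "zero rank variance"),
        ],
    )
    def test_domain_errors(self, x, y, err):
        with pytest.raises(DomainError, match=err):
            spearman_rs(x, y)


def test_holm_adjustment_monotone_and_bounded():
    p = [0.01, 0.04, 0.03, 0.50]
    adjusted = holm_adjust(p)
    assert adjusted == [0.04, 0.09, 0.09, 0.50]
    assert all(a >= raw for a, raw in zip(adjusted, p))
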