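"""Rank-based tests for organ and species contrasts.

Residue data from small bird cohorts are skewed and, after substitution
of below-LOQ values, heavily tied at zero, so the battery is
non-parametric throughout: Mann–Whitney U for two groups,
Kruskal–Wallis for several, and Spearman rank correlation for
concentration–lipid relationships.  Ties receive midranks everywhere and
tie-corrected variances in the large-sample approximations.  For small
samples the exact null distributions are computed over all group-label
assignments conditional on the observed (tied) values, which keeps the
tests exact in the presence of ties — the textbook no-tie tables do not
apply to these data.

All p values are two-sided; the conventional significance threshold for
reporting is 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .concentrations import DomainError

#: Largest pooled sample for which exact enumeration is attempted.
EXACT_MW_LIMIT = 20
EXACT_KW_LIMIT = 10

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return _sps.rankdata(pooled, method="average")


def _tie_term(pooled: np.ndarray) -> float:
    """Σ (t³ − t) over groups of tied values."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


# ---------------------------------------------------------------------------
# Mann–Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{x_i > y_j} + ½·#{x_i = y_j} (direct pair counting)."""
    gt = np.sum(x[:, None] > y[None, :])
    eq = np.sum(x[:, None] == y[None, :])
    return float(gt) + 0.5 * float(eq)


def _exact_u_distribution(pooled: np.ndarray, nx: int):
    """Null distribution of the doubled x-midrank sum over all subsets.

    Returns (sums, counts): for every achievable value s of twice the
    rank sum of an nx-subset, the number of subsets attaining it.  A
    dynamic programme over items avoids enumerating subsets explicitly.
    """
    doubled = np.rint(2.0 * _midranks(pooled)).astype(np.int64)
    total = int(doubled.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((nx + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for e in doubled:
        kmax = nx
        dp[1:kmax + 1, e:] += dp[0:kmax, : total + 1 - e]
    sums = np.nonzero(dp[nx])[0]
    return sums, dp[nx, sums]


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    continuity: bool = True,
) -> TestResult:
    """Two-sided Mann–Whitney U test with midrank tie handling.

    ``mode="exact"`` enumerates the conditional permutation null (all
    assignments of the pooled values to the two group labels) and is
    available for pooled samples of at most 20; ``"normal_approx"`` uses
    the tie-corrected normal approximation with an optional continuity
    correction.  ``"auto"`` picks exact when feasible.

    The statistic is U for the first sample: the number of (xᵢ, yⱼ)
    pairs with xᵢ > yⱼ plus half the tied pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both groups must be non-empty")
    nx, ny = int(x.size), int(y.size)
    pooled = np.concatenate([x, y])
    u = _u_statistic(x, y)

    if mode == "auto":
        mode = "exact" if nx + ny <= EXACT_MW_LIMIT else "normal_approx"
    if mode == "exact":
        if nx + ny > EXACT_MW_LIMIT:
            raise DomainError(
                f"exact mode limited to pooled n <= {EXACT_MW_LIMIT}"
            )
        sums, counts = _exact_u_distribution(pooled, nx)
        # doubled U values: 2U = s - nx(nx+1); null centre is nx*ny
        t_vals = sums - nx * (nx + 1)
        centre = nx * ny
        dev = abs(2.0 * u - centre)
        mask = np.abs(t_vals - centre) >= dev - 1e-9
        p = float(counts[mask].sum() / counts.sum())
        return TestResult(u, min(p, 1.0), "exact", (nx, ny))
    if mode == "normal_approx":
        z = _mw_z(u, pooled, nx, ny, continuity=continuity)
        p = 2.0 * float(_sps.norm.sf(abs(z)))
        return TestResult(u, min(p, 1.0), "approximation", (nx, ny))
    raise DomainError(f"unknown mode {mode!r}")


def _mw_z(
    u: float, pooled: np.ndarray, nx: int, ny: int, continuity: bool
) -> float:
    """Tie-corrected normal deviate of U (signed)."""
    n = nx + ny
    mu = nx * ny / 2.0
    tie = _tie_term(pooled)
    var = nx * ny / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 0.0
    diff = u - mu
    if continuity:
        diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff) if diff else 0.0
    return diff / math.sqrt(var)


# ---------------------------------------------------------------------------
# Kruskal–Wallis


def _h_statistic(rank_sums: np.ndarray, sizes: np.ndarray, n: int,
                 tie_correction: float) -> float:
    h = 12.0 / (n * (n + 1)) * float(np.sum(rank_sums**2 / sizes)) - 3.0 * (n + 1)
    return h / tie_correction


def kruskal_wallis(
    groups: Sequence[Sequence[float]], mode: str = "chi2"
) -> TestResult:
    """Kruskal–Wallis H test on midranks with tie correction.

    ``mode="chi2"`` refers H to the χ² distribution with k−1 degrees of
    freedom; ``mode="exact"`` enumerates all assignments of the pooled
    values into groups of the observed sizes (total n ≤ 10).  When every
    pooled value is identical, H = 0 and p = 1 by convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DomainError("at least two groups required")
    if any(a.size == 0 for a in arrays):
        raise DomainError("all groups must be non-empty")
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    n = int(pooled.size)
    df = len(arrays) - 1

    tie = _tie_term(pooled)
    correction = 1.0 - tie / (n**3 - n)
    if correction <= 0:  # every pooled value identical
        return TestResult(0.0, 1.0, "degenerate", tuple(sizes))

    ranks = _midranks(pooled)
    bounds = np.cumsum(sizes)[:-1]
    rank_sums = np.array([g.sum() for g in np.split(ranks, bounds)])
    h_obs = _h_statistic(rank_sums, sizes.astype(float), n, correction)

    if mode == "chi2":
        p = float(_sps.chi2.sf(h_obs, df))
        return TestResult(h_obs, p, "approximation", tuple(sizes))
    if mode == "exact":
        if n > EXACT_KW_LIMIT:
            raise DomainError(
                f"exact mode limited to total n <= {EXACT_KW_LIMIT}"
            )
        ge = 0
        total = 0
        for assignment_sums in _group_rank_sums(ranks, list(sizes)):
            h = _h_statistic(
                np.asarray(assignment_sums), sizes.astype(float), n, correction
            )
            total += 1
            if h >= h_obs - 1e-9:
                ge += 1
        return TestResult(h_obs, ge / total, "exact", tuple(sizes))
    raise DomainError(f"unknown mode {mode!r}")


def _group_rank_sums(ranks: np.ndarray, sizes: list[int]):
    """Yield tuples of per-group rank sums over all distinct assignments."""
    idx = tuple(range(len(ranks)))

    def rec(remaining: tuple[int, ...], sizes_left: list[int], acc: tuple):
        if len(sizes_left) == 1:
            yield acc + (float(ranks[list(remaining)].sum()),)
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            yield from rec(
                rest, sizes_left[1:], acc + (float(ranks[list(combo)].sum()),)
            )

    yield from rec(idx, sizes, ())


# ---------------------------------------------------------------------------
# Spearman rank correlation


def spearman_rs(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman's rs: product-moment correlation of midranks.

    Two-sided p from the t approximation with n−2 degrees of freedom;
    perfectly monotone data give rs = ±1 with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    n = int(x.size)
    if n < 3:
        raise DomainError("spearman_rs requires n >= 3")
    rx = _midranks(x)
    ry = _midranks(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise DomainError("zero rank variance (all values tied)")
    rs = float(np.corrcoef(rx, ry)[0, 1])
    rs = max(-1.0, min(1.0, rs))
    if abs(rs) == 1.0:
        p = 0.0
    else:
        t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
        p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return TestResult(rs, min(p, 1.0), "approximation", (n, n))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (optional; contrasts are reported
    unadjusted by default, matching single-survey practice)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adjusted[i] = min(1.0, running)
    return adjusted
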