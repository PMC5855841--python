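"""Nonparametric and parametric group comparisons, implemented from formulas.

The battery mirrors what a patch-clamp/clinical study typically applies:
Mann-Whitney U (exact by enumeration at small tie-free n, otherwise a
tie-corrected normal approximation), Kruskal-Wallis with Dunn's post hoc test,
pooled-variance Student's t, and Fisher's exact test on 2x2 tables.  All test
statistics are computed here from first principles; only distribution
functions (normal, chi-square, t) come from :mod:`scipy.special`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy.special import chdtrc, gammaln, ndtr, stdtr

from .errors import InvalidInputError

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "rank_with_ties",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "students_t",
    "fisher_exact",
]

#: Total-sample-size cutoff below which (tie-free) Mann-Whitney p-values are
#: computed by full enumeration.
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SEM summary of one group, the study's reporting convention."""

    name: str
    n: int
    mean: float
    sd: float
    sem: float


def summarize(name: str, data: Sequence[float]) -> GroupSummary:
    arr = np.asarray(list(data), dtype=float)
    if arr.size < 1:
        raise InvalidInputError("cannot summarize an empty group")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(
        name=name,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        sem=sd / math.sqrt(arr.size),
    )


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    adjusted: bool = False
    pairwise: tuple[dict, ...] = field(default_factory=tuple)
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidInputError(f"p-value {self.p_value} outside [0, 1]")


def rank_with_ties(values: Sequence[float]) -> tuple[np.ndarray, list[int]]:
    """Midranks (1-based) and the list of tie-group sizes > 1."""
    arr = np.asarray(values, dtype=float)
    order = np.argsort(arr, kind="mergesort")
    ranks = np.empty(arr.size, dtype=float)
    ties: list[int] = []
    i = 0
    while i < arr.size:
        j = i
        while j + 1 < arr.size and arr[order[j + 1]] == arr[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        ranks[order[i : j + 1]] = midrank
        if j > i:
            ties.append(j - i + 1)
        i = j + 1
    return ranks, ties


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """(U_x, U_y) from midranks; U_x + U_y = n_x n_y always."""
    nx, ny = len(x), len(y)
    ranks, _ = rank_with_ties(list(x) + list(y))
    r_x = float(ranks[:nx].sum())
    u_x = r_x - nx * (nx + 1) / 2.0
    return u_x, nx * ny - u_x


def _exact_mw_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided p by enumerating all C(N, n_x) rank assignments."""
    nx = len(x)
    pooled = sorted(list(x) + list(y))
    n = len(pooled)
    u_obs, _ = _u_statistic(x, y)
    count_le = 0
    count_ge = 0
    total = 0
    for idx in combinations(range(n), nx):
        r_x = sum(idx) + nx  # 0-based indices -> 1-based ranks
        u = r_x - nx * (nx + 1) / 2.0
        total += 1
        if u <= u_obs + 1e-9:
            count_le += 1
        if u >= u_obs - 1e-9:
            count_ge += 1
    p = 2.0 * min(count_le, count_ge) / total
    return u_obs, min(p, 1.0)


def _asymptotic_mw_p(
    x: Sequence[float], y: Sequence[float], continuity: bool
) -> tuple[float, float]:
    nx, ny = len(x), len(y)
    n = nx + ny
    u_x, _ = _u_statistic(x, y)
    _, ties = rank_with_ties(list(x) + list(y))
    mu = nx * ny / 2.0
    tie_term = sum(t**3 - t for t in ties)
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_x, 1.0
    dev = abs(u_x - mu)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    z = dev / math.sqrt(var)
    return u_x, float(2.0 * ndtr(-z))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "asymptotic", "auto"] = "auto",
    continuity: bool = True,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``auto`` uses exact enumeration when n_x + n_y <= 12 and the pooled data
    is tie-free, otherwise the tie-corrected normal approximation (with
    continuity correction unless ``continuity=False``).
    """
    if len(x) == 0 or len(y) == 0:
        raise InvalidInputError("both samples must be non-empty")
    _, ties = rank_with_ties(list(x) + list(y))
    flags: list[str] = []
    if mode == "exact" or (
        mode == "auto" and len(x) + len(y) <= EXACT_MW_MAX_N and not ties
    ):
        if ties:
            raise InvalidInputError("exact mode requires tie-free data")
        u, p = _exact_mw_p(x, y)
        flags.append("exact")
    else:
        u, p = _asymptotic_mw_p(x, y, continuity)
        flags.append("asymptotic")
    return TestResult(
        method="mann_whitney_u", statistic=u, p_value=p, flags=tuple(flags)
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square, k-1 df.

    ``H = 12/(N(N+1)) * sum R_j^2/n_j - 3(N+1)``, divided by
    ``1 - sum(t^3 - t)/(N^3 - N)`` when ties are present.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InvalidInputError("need >= 2 non-empty groups")
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    pooled = [v for g in groups for v in g]
    ranks, ties = rank_with_ties(pooled)
    h = 0.0
    start = 0
    for sz in sizes:
        r_j = float(ranks[start : start + sz].sum())
        h += r_j * r_j / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    flags: list[str] = []
    if ties:
        denom = 1.0 - sum(t**3 - t for t in ties) / (n**3 - n)
        if denom <= 0:  # all observations identical
            return TestResult(
                method="kruskal_wallis", statistic=0.0, p_value=1.0,
                flags=("degenerate_all_tied",),
            )
        h /= denom
        flags.append("tie_corrected")
    h = max(h, 0.0)
    p = float(chdtrc(len(groups) - 1, h))
    return TestResult(
        method="kruskal_wallis", statistic=h, p_value=min(p, 1.0),
        flags=tuple(flags),
    )


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjustment: Literal["bonferroni", "none"] = "bonferroni",
) -> TestResult:
    """Dunn's pairwise rank comparison after Kruskal-Wallis.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - sum(t^3-t)/(12(N-1)))
    * (1/n_i + 1/n_j)]`` with two-sided normal p-values, Bonferroni-multiplied
    by the number of pairs when requested.
    """
    if len(groups) < 3:
        raise InvalidInputError(
            "Dunn post hoc needs >= 3 groups; use mann_whitney_u for two"
        )
    if any(len(g) == 0 for g in groups):
        raise InvalidInputError("all groups must be non-empty")
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    pooled = [v for g in groups for v in g]
    ranks, ties = rank_with_ties(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(float(ranks[start : start + sz].mean()))
        start += sz
    tie_term = sum(t**3 - t for t in ties)
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise = []
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = float(2.0 * ndtr(-abs(z)))
        p_adj = min(p * n_pairs, 1.0) if adjustment == "bonferroni" else p
        pairwise.append(
            {"i": i, "j": j, "z": z, "p_unadjusted": p, "p_value": p_adj}
        )
    p_min = min(entry["p_value"] for entry in pairwise)
    z_max = max(abs(entry["z"]) for entry in pairwise)
    return TestResult(
        method="dunn_posthoc",
        statistic=z_max,
        p_value=p_min,
        adjusted=adjustment == "bonferroni",
        pairwise=tuple(pairwise),
    )


def students_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Classic pooled-variance two-sided Student's t with n_x + n_y - 2 df."""
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise InvalidInputError("Student's t needs n >= 2 per group")
    ax, ay = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    df = nx + ny - 2
    sp2 = ((nx - 1) * ax.var(ddof=1) + (ny - 1) * ay.var(ddof=1)) / df
    diff = float(ax.mean() - ay.mean())
    if sp2 == 0:
        if diff == 0:
            return TestResult(
                method="students_t", statistic=0.0, p_value=1.0,
                flags=("degenerate_zero_variance",),
            )
        return TestResult(
            method="students_t", statistic=math.inf * np.sign(diff), p_value=0.0,
            flags=("degenerate_zero_variance",),
        )
    t = diff / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = float(2.0 * stdtr(df, -abs(t)))
    return TestResult(method="students_t", statistic=t, p_value=min(p, 1.0))


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    n = r1 + r2
    return float(
        gammaln(r1 + 1) - gammaln(a + 1) - gammaln(r1 - a + 1)
        + gammaln(r2 + 1) - gammaln(c1 - a + 1) - gammaln(r2 - (c1 - a) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    Sums hypergeometric probabilities (margins fixed) of every table whose
    point probability does not exceed the observed one (with 1e-7 relative
    slack).  A zero margin makes every table equally likely: p = 1, flagged.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in cells):
        raise InvalidInputError("table entries must be non-negative integers")
    a, b, c, d = (int(v) for v in cells)
    r1, r2, c1 = a + b, c + d, a + c
    if 0 in (r1, r2, c1, b + d):
        return TestResult(
            method="fisher_exact", statistic=float("nan"), p_value=1.0,
            flags=("degenerate_zero_margin",),
        )
    lp_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p = 0.0
    for k in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(k, r1, r2, c1)
        if lp <= lp_obs + 1e-7:
            p += math.exp(lp)
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return TestResult(method="fisher_exact", statistic=odds, p_value=min(p, 1.0))
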