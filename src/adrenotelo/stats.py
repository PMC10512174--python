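"""Nonparametric tests with GraphPad-Prism-5 semantics.

The two-group comparisons in the source cohort were run in Prism 5, whose
Mann–Whitney test switches between two branches:

* **exact** — when the pooled sample has no tied values, the permutation
  distribution of the U statistic is computed exactly and the two-sided
  p doubles the smaller tail (capped at 1);
* **approx_cc** — when ties are present, a Gaussian approximation is used
  with a continuity correction of 0.5 and the pooled tie-corrected
  variance

  .. math::

     \\sigma^2 = \\frac{n_1 n_2}{12}\\Bigl[(N+1) -
         \\frac{\\sum_g (t_g^3 - t_g)}{N(N-1)}\\Bigr]

  over tie groups of size :math:`t_g` in the pooled sample of size
  :math:`N = n_1 + n_2`.

This pairing is what reproduces the cohort's printed p-values from the
printed per-patient tables.  A forced-exact mode is also provided for
tied data (full enumeration with midrank U): printed values rounded to
2 decimals can carry spurious ties that the underlying continuous
measurements did not have.

Wilcoxon signed-rank, Kruskal–Wallis with Dunn's multiple-comparison
z tests, and Spearman correlation round out the battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "WilcoxonResult",
    "KruskalDunnResult",
    "CorrelationResult",
    "mann_whitney_u",
    "mw_exact_p",
    "mw_exact_p_enumerate",
    "mw_approx_p",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "kruskal_wallis_dunn",
    "spearman",
]

# Full enumeration of C(n1+n2, n1) group assignments is refused above this.
_MAX_ENUMERATION = 500_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group Mann–Whitney comparison."""

    u_raw: float
    u_small: float
    n1: int
    n2: int
    method: str  # "exact" | "approx_cc"
    p_two_sided: float
    tie_present: bool


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    n_nonzero: int
    n_zero: int
    method: str  # "exact" | "approx_cc" | "degenerate"
    p_two_sided: float


@dataclass(frozen=True)
class KruskalDunnResult:
    h: float
    df: int
    p_two_sided: float
    dunn_z: dict[tuple[int, int], float]
    dunn_p_adjusted: dict[tuple[int, int], float]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_two_sided: float | None
    n: int


def _validate_group(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"group {name} must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"group {name} contains non-finite values")
    return arr


def mann_whitney_u(x, y) -> tuple[float, bool]:
    """U statistic for group ``x``: wins over ``y`` plus half the ties.

    Returns ``(u_raw, tie_present)`` where ``tie_present`` flags any tie in
    the *pooled* sample (within- or cross-group).
    """
    xa = _validate_group(x, "x")
    ya = _validate_group(y, "y")
    gt = np.sum(xa[:, None] > ya[None, :])
    eq = np.sum(xa[:, None] == ya[None, :])
    pooled = np.concatenate([xa, ya])
    tie_present = np.unique(pooled).size < pooled.size
    return float(gt + 0.5 * eq), bool(tie_present)


@lru_cache(maxsize=256)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of assignments with each U value, for tie-free data.

    Recurrence: N(n1, n2; u) = N(n1-1, n2; u-n2) + N(n1, n2-1; u).
    Returned tuple has length n1*n2 + 1 and sums to C(n1+n2, n1).
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = np.array(_u_counts(n1 - 1, n2), dtype=object)  # shift by n2
    b = np.array(_u_counts(n1, n2 - 1), dtype=object)
    out = np.zeros(n1 * n2 + 1, dtype=object)
    out[n2 : n2 + a.size] += a
    out[: b.size] += b
    return tuple(int(c) for c in out)


def mw_exact_p(u_raw: float, n1: int, n2: int) -> float:
    """Exact two-sided p for a tie-free Mann–Whitney U.

    The permutation distribution of U over all C(n1+n2, n1) group
    assignments is built by a count recurrence; p doubles the smaller
    tail, capped at 1.  Half-integral U (from cross-group ties) is
    rejected — use :func:`mw_exact_p_enumerate` or the approximation.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both group sizes must be >= 1")
    if abs(u_raw - round(u_raw)) > 1e-9:
        raise ValueError(
            "non-integral U implies cross-group ties; use mw_approx_p or "
            "mw_exact_p_enumerate (forced exact with midranks)"
        )
    u = int(round(u_raw))
    if not 0 <= u <= n1 * n2:
        raise ValueError(f"U={u_raw} outside [0, {n1 * n2}]")
    counts = _u_counts(n1, n2)
    total = sum(counts)
    u_small = min(u, n1 * n2 - u)
    tail = sum(counts[: u_small + 1])
    return min(1.0, 2.0 * tail / total)


def mw_exact_p_enumerate(x, y) -> float:
    """Exact two-sided p by full enumeration, valid with tied values.

    U is recomputed (with midrank ties) for every group assignment of the
    pooled values; p doubles the smaller of P(U <= u_obs) and
    P(U >= u_obs), capped at 1.  Equals :func:`mw_exact_p` on tie-free
    data.
    """
    xa = _validate_group(x, "x")
    ya = _validate_group(y, "y")
    n1, n = xa.size, xa.size + ya.size
    if math.comb(n, n1) > _MAX_ENUMERATION:
        raise ValueError(f"enumeration over C({n},{n1}) assignments is too large")
    pooled = np.concatenate([xa, ya])
    u_obs, _ = mann_whitney_u(xa, ya)
    # U = (sum of pooled midranks of group 1) - n1(n1+1)/2, so ranks suffice.
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    lo = hi = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        lo += u <= u_obs + 1e-12
        hi += u >= u_obs - 1e-12
    return min(1.0, 2.0 * min(lo, hi) / total)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mw_approx_p(u_raw: float, x, y) -> float:
    """Gaussian two-sided p with continuity and pooled tie correction."""
    xa = _validate_group(x, "x")
    ya = _validate_group(y, "y")
    n1, n2 = xa.size, ya.size
    n = n1 + n2
    pooled = np.concatenate([xa, ya])
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 1.0  # every pooled value identical
    z = (abs(u_raw - n1 * n2 / 2.0) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, float(2.0 * sps.norm.sf(z)))


def mann_whitney(x, y, method: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney test.

    ``method='auto'`` selects the exact permutation branch iff the pooled
    sample has no ties, otherwise the continuity/tie-corrected Gaussian
    branch.  ``method='exact'`` forces the exact branch (full midrank
    enumeration when ties are present); ``method='approx'`` forces the
    Gaussian branch.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    xa = _validate_group(x, "x")
    ya = _validate_group(y, "y")
    u_raw, tie_present = mann_whitney_u(xa, ya)
    n1, n2 = xa.size, ya.size
    if method == "approx" or (method == "auto" and tie_present):
        p = mw_approx_p(u_raw, xa, ya)
        used = "approx_cc"
    else:
        if tie_present:  # forced exact on tied data
            p = mw_exact_p_enumerate(xa, ya)
        else:
            p = mw_exact_p(u_raw, n1, n2)
        used = "exact"
    return TestResult(
        u_raw=u_raw,
        u_small=min(u_raw, n1 * n2 - u_raw),
        n1=n1,
        n2=n2,
        method=used,
        p_two_sided=p,
        tie_present=tie_present,
    )


@lru_cache(maxsize=64)
def _signed_rank_counts(n: int) -> tuple[int, ...]:
    """Counts of sign patterns by positive-rank sum W+, ranks 1..n."""
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in range(1, n + 1):
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return tuple(int(c) for c in counts)


def wilcoxon_signed_rank(differences, max_enum_n: int = 14) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  Tie-free data with n <= 25 use the
    exact distribution of W+ (count recurrence); tied absolute values
    with n <= ``max_enum_n`` use exact enumeration of all sign patterns
    with midranks; larger samples use a Gaussian approximation with
    continuity correction and the usual tie variance deduction.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("differences must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences contain non-finite values")
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 0, n_zero, "degenerate", 1.0)
    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    tied = np.unique(absd).size < n
    if not tied and n <= 25:
        counts = _signed_rank_counts(n)
        total = 2**n
        w = int(round(w_plus))
        lo = sum(counts[: w + 1])
        hi = sum(counts[w:])
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return WilcoxonResult(w_plus, n, n_zero, "exact", p)
    if tied and n <= max_enum_n:
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        lo = np.sum(sums <= w_plus + 1e-12)
        hi = np.sum(sums >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(lo, hi) / sums.size)
        return WilcoxonResult(w_plus, n, n_zero, "exact", p)
    mean = n * (n + 1) / 4.0
    _, cnt = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(cnt.astype(float) ** 3 - cnt) / 48.0
    if var <= 0:
        return WilcoxonResult(w_plus, n, n_zero, "degenerate", 1.0)
    z = max((abs(w_plus - mean) - 0.5) / math.sqrt(var), 0.0)
    p = min(1.0, float(2.0 * sps.norm.sf(z)))
    return WilcoxonResult(w_plus, n, n_zero, "approx_cc", p)


def kruskal_wallis_dunn(groups, alpha: float = 0.05) -> KruskalDunnResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn's pairwise z tests.

    Dunn p-values are Bonferroni-adjusted by the number of pairwise
    comparisons and capped at 1.
    """
    arrs = [_validate_group(g, f"group {i}") for i, g in enumerate(groups)]
    k = len(arrs)
    if k < 3:
        raise ValueError("kruskal_wallis_dunn requires >= 3 groups; use mann_whitney for two")
    h, p = sps.kruskal(*arrs)
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrs:
        mean_ranks.append(float(ranks[start : start + a.size].mean()))
        start += a.size
    tie = _tie_term(pooled)
    var_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    m = k * (k - 1) // 2
    dunn_z: dict[tuple[int, int], float] = {}
    dunn_p: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(var_base * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
            z = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            dunn_z[(i, j)] = z
            dunn_p[(i, j)] = min(1.0, float(2.0 * sps.norm.sf(z) * m))
    return KruskalDunnResult(
        h=float(h), df=k - 1, p_two_sided=float(p), dunn_z=dunn_z, dunn_p_adjusted=dunn_p
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (Pearson of midranks) with t-based p."""
    xa = _validate_group(x, "x")
    ya = _validate_group(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must be paired (equal length)")
    n = xa.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        return CorrelationResult(rho=float("nan"), p_two_sided=None, n=n)
    rho, p = sps.spearmanr(xa, ya)
    return CorrelationResult(rho=float(rho), p_two_sided=float(p), n=n)
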