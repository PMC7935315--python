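"""Statistical primitives used throughout the screen.

Every test here is implemented in-package so that each can be verified
against a brute-force oracle (full enumeration of labelings or outcomes) in
the test suite.  Conventions:

* Mann-Whitney is exact (full U-distribution) when ``min(n, m) <= 25`` and
  the pooled data have no ties; otherwise a tie-corrected normal
  approximation with a 0.5 continuity correction is used.  Two-sided p is
  ``min(1, 2 * min(tail p))``.
* Fisher's exact test and the binomial test at p0 = 0.5 are computed with
  integer arithmetic, so printed-precision cases are exact.
* The hypergeometric overrepresentation test reduces to Fisher's test on the
  induced 2x2 table and agrees with it bit-for-bit on the one-sided path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "mann_whitney",
    "bh_adjust",
    "spearman_rho",
    "fisher_exact",
    "binomial_test",
    "hypergeom_ora",
    "holm_adjust",
]

TWO = "two"
GREATER = "greater"
LESS = "less"

_EXACT_MAX_MIN_N = 25


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    sided: str
    method: str  # "exact" | "approx"


# ---------------------------------------------------------------------------
# Mann-Whitney


_u_dist_cache: dict[tuple[int, int], np.ndarray] = {}


def _u_counts(n: int, m: int) -> np.ndarray:
    """Counts of labelings by U value for group sizes (n, m).

    ``counts[u]`` is the number of ways to choose which n of the n+m pooled
    ranks belong to group x such that the Mann-Whitney U statistic equals u.
    Built by the Gaussian-binomial recurrence
    ``G(i, j) = G(i, j-1) + q^j * G(i-1, j)``.
    """
    key = (min(n, m), max(n, m))
    cached = _u_dist_cache.get(key)
    if cached is not None:
        return cached
    a, b = key
    dp = [np.ones(1)] + [None] * a
    for i in range(1, a + 1):
        dp[i] = np.ones(1)  # (i, 0)
    for j in range(1, b + 1):
        for i in range(1, a + 1):
            out = np.zeros(i * j + 1)
            prev = dp[i]  # (i, j-1)
            out[: prev.size] += prev
            lower = dp[i - 1]  # (i-1, j), already advanced to column j
            out[j : j + lower.size] += lower
            dp[i] = out
    _u_dist_cache[key] = dp[a]
    return dp[a]


def mann_whitney(x, y, sided: str = TWO, method: str = "auto") -> TestResult:
    """Unpaired Wilcoxon-Mann-Whitney test of two samples.

    ``sided=greater`` tests whether x tends to exceed y.  Missing values
    must be removed by the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN in input; remove missing values first")
    n, m = x.size, y.size
    diff = x[:, None] - y[None, :]
    u1 = float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    use_exact = method == "exact" or (
        method == "auto" and min(n, m) <= _EXACT_MAX_MIN_N and not has_ties
    )
    if use_exact and has_ties:
        raise ValueError("exact method is not defined with ties")

    if use_exact:
        counts = _u_counts(n, m)
        total = counts.sum()
        u = int(round(u1))
        p_greater = counts[u:].sum() / total
        p_less = counts[: u + 1].sum() / total
        how = "exact"
    else:
        mu = n * m / 2.0
        big_n = n + m
        tie_term = float(((tie_counts**3) - tie_counts).sum())
        var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
        if var <= 0:
            p_greater = p_less = 1.0
        else:
            sd = math.sqrt(var)
            z_greater = (u1 - mu - 0.5) / sd
            z_less = (u1 - mu + 0.5) / sd
            p_greater = 0.5 * math.erfc(z_greater / math.sqrt(2))
            p_less = 0.5 * math.erfc(-z_less / math.sqrt(2))
        how = "approx"

    if sided == GREATER:
        p = p_greater
    elif sided == LESS:
        p = p_less
    elif sided == TWO:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return TestResult(statistic=u1, p=float(min(p, 1.0)), sided=sided, method=how)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def holm_adjust(pvalues) -> np.ndarray:
    """Holm (Bonferroni step-down) adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Spearman correlation


def spearman_rho(x, y) -> float | None:
    """Rank correlation with average ranks for ties, pairwise-complete.

    Pairs with a missing member are dropped first.  Returns ``None`` when
    fewer than 3 complete pairs remain or when either side is constant —
    an undefined correlation is signalled distinctly, never reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        return None
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return None
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return max(-1.0, min(1.0, rho))


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact(table, sided: str = GREATER) -> float:
    """Exact hypergeometric p for a 2x2 table ``[[a, b], [c, d]]``.

    ``sided=greater`` tests enrichment of the (1,1) cell.  Two-sided sums
    the probabilities of all tables no more likely than the observed one.
    Computed with integer arithmetic (no rounding in the tail sums).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in contingency table")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    total = math.comb(n, c1)
    if sided == GREATER:
        num = sum(w for k, w in weights.items() if k >= a)
    elif sided == LESS:
        num = sum(w for k, w in weights.items() if k <= a)
    elif sided == TWO:
        w_obs = weights[a]
        num = sum(w for w in weights.values() if w <= w_obs)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return min(1.0, num / total)


# ---------------------------------------------------------------------------
# Binomial test


def binomial_test(k: int, n: int, p0: float = 0.5, sided: str = TWO) -> float:
    """Exact binomial test of k successes in n trials at success rate p0.

    The two-sided p sums the probabilities of all outcomes no more likely
    than the observed one.  At p0 = 0.5 integer arithmetic makes the result
    exact to the last bit.
    """
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    if p0 == 0.5:
        weights = [math.comb(n, i) for i in range(n + 1)]
        total = 1 << n
        if sided == GREATER:
            num = sum(weights[k:])
        elif sided == LESS:
            num = sum(weights[: k + 1])
        else:
            w_obs = weights[k]
            num = sum(w for w in weights if w <= w_obs)
        return min(1.0, num / total)

    i = np.arange(n + 1)
    logpmf = (
        np.array([math.lgamma(n + 1) - math.lgamma(j + 1) - math.lgamma(n - j + 1) for j in i])
        + i * math.log(p0)
        + (n - i) * math.log1p(-p0)
    )
    pmf = np.exp(logpmf)
    if sided == GREATER:
        p = pmf[k:].sum()
    elif sided == LESS:
        p = pmf[: k + 1].sum()
    elif sided == TWO:
        p = pmf[pmf <= pmf[k] * (1 + 1e-9)].sum()
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# Hypergeometric overrepresentation


def hypergeom_ora(query, annotated, universe, sided: str = GREATER) -> float:
    """Overrepresentation p for ``|query & annotated|`` against a universe.

    Reduces to Fisher's exact test on the induced 2x2 table, so the
    one-sided "greater" path is identical to :func:`fisher_exact`.
    """
    query, annotated, universe = set(query), set(annotated), set(universe)
    if not query <= universe:
        raise ValueError("query is not contained in the universe")
    annotated = annotated & universe
    k = len(query & annotated)
    table = [
        [k, len(query) - k],
        [len(annotated) - k, len(universe) - len(query) - len(annotated) + k],
    ]
    return fisher_exact(table, sided=sided)


def ora_scan(query, annotated_sets: dict, universe, sided: str = GREATER) -> dict:
    """ORA over several annotated sets with Bonferroni step-down correction.

    Returns ``{name: (raw_p, adjusted_p)}`` using Holm adjustment across the
    scanned sets.
    """
    names = list(annotated_sets)
    raw = [hypergeom_ora(query, annotated_sets[name], universe, sided) for name in names]
    adj = holm_adjust(raw)
    return {name: (raw[i], float(adj[i])) for i, name in enumerate(names)}
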