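"""Exact two-group Mann-Whitney rank-sum statistics for very small samples.

With 3 or 4 replicates per group, asymptotic rank tests are meaningless and
the exact null distribution is tiny: C(6,3)=20 or C(8,4)=70 equally likely
assignments of the observed values to the two groups. This module enumerates
that distribution directly, which makes the granularity of achievable
p-values explicit — e.g. the smallest two-tailed p for a 3 vs 3 design is
2/20 = 0.1 (complete separation), and for 4 vs 4 the two most extreme levels
are 2/70 = 0.0286 and 4/70 = 0.0571.

Definitions used throughout:

* ``U`` counts pairwise wins of group B over group A, each within-pair tie
  contributing 1/2 (equivalently, mid-rank sum of B minus n(n+1)/2).
* The two-tailed p-value is the null probability of an assignment at least
  as extreme as observed, extremity measured by the symmetric distance
  ``|U - mn/2|``. For tie-free data this coincides with doubling the
  one-sided tail; with ties it stays well defined.
* Ties are handled permutation-exactly: the null enumerates assignments of
  the observed multiset itself, so tied values are exchangeable under the
  null rather than being broken arbitrarily.

Above an enumeration cap (default 14 total samples, i.e. at most
C(14,7)=3432 assignments) a tie-corrected normal approximation is used and
flagged via ``exact=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

__all__ = [
    "RankTestResult",
    "exact_rank_sum",
    "exact_rank_sum_matrix",
    "min_achievable_p",
    "kth_smallest_p",
    "fold_difference",
    "rounded",
    "DEFAULT_ENUMERATION_CAP",
]

DEFAULT_ENUMERATION_CAP = 14

# distances |U - mn/2| live on a half-integer grid; compare with this slack
_GRID_EPS = 1e-9


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a two-group rank-sum test.

    U is the number of pairwise wins of group B over group A (ties count
    1/2); m and n are the larger and smaller group size; ``exact`` is True
    when p was obtained by full enumeration.
    """

    U: float
    p_two_tailed: float
    m: int
    n: int
    exact: bool


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _u_from_ranks(ranks_b: np.ndarray) -> float:
    nb = ranks_b.size
    return float(ranks_b.sum() - nb * (nb + 1) / 2)


def exact_rank_sum(values_a, values_b, enumeration_cap: int = DEFAULT_ENUMERATION_CAP) -> RankTestResult:
    """Two-tailed exact Mann-Whitney test of ``values_b`` vs ``values_a``.

    Enumerates all C(m+n, n) assignments of the observed (possibly tied)
    values when the combined size is within *enumeration_cap*; otherwise
    falls back to the tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    u_obs = _u_from_ranks(ranks[na:])
    mn = na * nb
    center = mn / 2.0

    if na + nb <= enumeration_cap:
        d_obs = abs(u_obs - center)
        total = hits = 0
        for idx in combinations(range(na + nb), nb):
            u = _u_from_ranks(ranks[list(idx)])
            if abs(u - center) >= d_obs - _GRID_EPS:
                hits += 1
            total += 1
        p = hits / total
        exact = True
    else:
        p = _normal_approx_p(ranks, na, nb, u_obs)
        exact = False

    return RankTestResult(
        U=u_obs,
        p_two_tailed=min(1.0, p),
        m=max(na, nb),
        n=min(na, nb),
        exact=exact,
    )


def _normal_approx_p(ranks: np.ndarray, na: int, nb: int, u_obs: float) -> float:
    """Two-tailed normal approximation with the standard tie correction."""
    k = na + nb
    mn = na * nb
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = mn / 12.0 * ((k + 1) - tie_term / (k * (k - 1)))
    if var <= 0:  # all values identical
        return 1.0
    z = (u_obs - mn / 2.0) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def exact_rank_sum_matrix(values_a: np.ndarray, values_b: np.ndarray,
                          enumeration_cap: int = DEFAULT_ENUMERATION_CAP):
    """Vectorized exact test over many genes at once.

    values_a, values_b : arrays of shape (genes, na) and (genes, nb)

    Returns ``(U, p)`` arrays of length *genes*. All genes share the same
    design, so the C(na+nb, nb) assignment index set is built once and the
    per-assignment U statistics are computed by a single gather-and-sum.
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValueError("group arrays must have the same number of genes")
    na, nb = A.shape[1], B.shape[1]
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    if na + nb > enumeration_cap:
        res = [exact_rank_sum(A[i], B[i], enumeration_cap) for i in range(A.shape[0])]
        return (np.array([r.U for r in res]), np.array([r.p_two_tailed for r in res]))

    combined = np.hstack([A, B])
    ranks = stats.rankdata(combined, method="average", axis=1)
    mn = na * nb
    center = mn / 2.0
    u_obs = ranks[:, na:].sum(axis=1) - nb * (nb + 1) / 2
    combos = np.array(list(combinations(range(na + nb), nb)))  # (C, nb)
    u_all = ranks[:, combos].sum(axis=2) - nb * (nb + 1) / 2   # (genes, C)
    d_obs = np.abs(u_obs - center)
    p = (np.abs(u_all - center) >= d_obs[:, None] - _GRID_EPS).mean(axis=1)
    return u_obs, np.minimum(p, 1.0)


def min_achievable_p(m: int, n: int) -> float:
    """Smallest two-tailed p attainable for group sizes m and n.

    Complete separation of the two groups is the most extreme of the
    C(m+n, n) assignments and occurs in 2 of them (either group on top),
    so the minimum is 2 / C(m+n, n), capped at 1. For 3 vs 3 this is
    2/20 = 0.1 — the smallest p the design can ever produce.
    """
    if m < 1 or n < 1:
        raise ValueError("group sizes must be >= 1")
    return min(1.0, 2.0 / comb(m + n, n))


def kth_smallest_p(m: int, n: int, k: int) -> float:
    """Two-tailed p of the k-th most extreme achievable outcome.

    Enumerates the null distribution of U for tie-free data, groups
    assignments by distinct extremity level |U - mn/2| (descending), and
    returns the cumulative two-tailed probability of the k-th level.
    k=1 reproduces :func:`min_achievable_p`; for a 4 vs 4 design k=2 gives
    4/70 = 0.0571, the usual origin of a printed 0.057 cutoff.
    """
    if m < 1 or n < 1:
        raise ValueError("group sizes must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    total = m + n
    center = m * n / 2.0
    devs = []
    for idx in combinations(range(total), n):
        ranks_b = np.asarray(idx, dtype=float) + 1.0  # distinct data: ranks 1..m+n
        u = _u_from_ranks(ranks_b)
        devs.append(round(2 * abs(u - center)))  # half-integer grid -> ints
    devs = np.asarray(devs)
    levels = np.unique(devs)[::-1]  # most extreme first
    if k > levels.size:
        raise ValueError(f"k={k} exceeds the {levels.size} distinct extremity levels")
    return float((devs >= levels[k - 1]).mean())


def fold_difference(mean_log2_ref: float, mean_log2_test: float) -> float:
    """Linear fold of test over reference from mean log2 intensities.

    ``2 ** (mean_log2_test - mean_log2_ref)``; values < 1 denote decreases.
    """
    return float(2.0 ** (float(mean_log2_test) - float(mean_log2_ref)))


def rounded(value: float, ndigits: int = 2) -> float:
    """Half-away-from-zero rounding, matching printed result tables."""
    q = 10.0**ndigits
    return float(np.floor(abs(value) * q + 0.5) / q * np.sign(value)) if value else 0.0
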