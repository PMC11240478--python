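"""Wilcoxon signed-rank test for paired series, implemented from scratch.

The test takes paired observations (here: two spectra sampled on the same
frequency grid), forms the differences d_i = x_i - y_i, discards exact
zeros, ranks |d_i| (midranks on ties), and sums the ranks of positive and
negative differences separately.  The statistic is the smaller of the two
rank sums; under the null hypothesis that the differences are symmetric
about zero every sign assignment of the ranks is equally likely, which
yields an exact, discrete reference distribution.

Three computational paths are used:

* ``EXACT`` — tie-free samples with n <= 25: the exact null distribution of
  the one-sided rank sum over all 2^n sign assignments, computed by a
  dynamic program over achievable rank sums (polynomial, not 2^n).
* ``NORMAL_APPROX`` — larger samples, or tied samples with n >= 10: normal
  approximation with the standard tie correction and a continuity
  correction of 1/2.
* tied samples with n < 10 fall back to exact enumeration over the observed
  midranks (the classical tables assume distinct ranks, so the generic DP
  table does not apply; with doubled midranks the sum lattice is integral
  and small).

Zero differences are dropped (Wilcoxon's original convention, not Pratt's).
All p-values are two-sided: twice the lower-tail probability of the min-sum
statistic, capped at 1.

``oracle_p`` is a deliberately independent brute-force implementation
(explicit iteration over all sign vectors) kept for cross-checking the main
path in tests; it is exponential and limited to n <= 14.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Method",
    "Alternative",
    "SignedRankResult",
    "signed_rank_test",
    "exact_null_distribution",
    "normal_approx_p",
    "oracle_p",
]

#: Largest n for which the exact DP null distribution is used.
EXACT_N_MAX = 25
#: Smallest n at which the normal approximation is considered usable.
NORMAL_N_MIN = 10
#: Brute-force oracle bound (2^n enumerations).
ORACLE_N_MAX = 14


class Method(enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"
    DEGENERATE = "degenerate"


class Alternative(enum.Enum):
    TWO_SIDED = "two-sided"


@dataclass(frozen=True)
class SignedRankResult:
    """Outcome of a paired signed-rank comparison.

    ``w_plus`` and ``w_minus`` are the rank sums of positive and negative
    differences; ``statistic`` is their minimum.  ``n_input`` counts the
    pairs supplied, ``n_effective`` the pairs remaining after zero
    differences are removed.
    """

    n_input: int
    n_effective: int
    w_plus: float
    w_minus: float
    statistic: float
    p_value: float
    method: Method
    alternative: Alternative = Alternative.TWO_SIDED

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _null_counts(n: int) -> np.ndarray:
    """Counts of sign assignments of ranks 1..n achieving each rank sum.

    ``counts[w]`` is the number of subsets of {1, ..., n} summing to w, for
    w = 0 .. n(n+1)/2.  Dynamic program: each rank is either in the positive
    set or not.
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for rank in range(1, n + 1):
        counts[rank:] = counts[rank:] + counts[: total + 1 - rank]
    return counts


def exact_null_distribution(n: int) -> dict[int, float]:
    """Exact null distribution of the one-sided rank sum W for sample size n.

    Returns a mapping rank-sum value -> probability over all 2^n equiprobable
    sign assignments of the distinct ranks 1..n.  The distribution is
    symmetric about n(n+1)/4 and its probabilities sum to 1.
    """
    if not (1 <= n <= EXACT_N_MAX):
        raise ValueError(f"n must be in [1, {EXACT_N_MAX}], got {n}")
    counts = _null_counts(n)
    denom = float(2**n)
    return {w: counts[w] / denom for w in range(counts.size)}


def _tied_null_counts(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Null distribution of the rank sum over observed midranks.

    Midranks may be half-integers, so the lattice is built on doubled ranks:
    returns (counts over doubled sums 0..2*total, scale=2).  Used only for
    small tied samples where the generic 1..n table does not apply.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total2 = int(doubled.sum())
    counts = np.zeros(total2 + 1, dtype=np.int64)
    counts[0] = 1
    for r2 in doubled:
        counts[r2:] = counts[r2:] + counts[: total2 + 1 - r2]
    return counts, 2


def _two_sided_from_counts(counts: np.ndarray, stat_scaled: int, n: int) -> float:
    """Two-sided p = min(1, 2 * P(W <= statistic)) from integer counts."""
    lower = int(counts[: stat_scaled + 1].sum())
    p = 2.0 * lower / float(2**n)
    return min(1.0, p)


def normal_approx_p(
    w_plus: float, n_effective: int, tie_sizes: Sequence[int] = ()
) -> float:
    """Two-sided normal-approximation p-value for the signed-rank statistic.

    Standardizes W+ against the null mean n(n+1)/4 and variance
    n(n+1)(2n+1)/24 - sum(t^3 - t)/48 (tie correction over tied groups of
    sizes t), with a continuity correction of 1/2.  Requires n >= 10; below
    that the approximation is too coarse to report.
    """
    if n_effective < NORMAL_N_MIN:
        raise ValueError(
            f"normal approximation needs n >= {NORMAL_N_MIN}, got {n_effective}"
        )
    n = n_effective
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    for t in tie_sizes:
        var -= (t**3 - t) / 48.0
    if var <= 0:  # all differences tied at one magnitude and n small enough
        return 1.0
    z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
    if z <= 0:
        return 1.0
    return min(1.0, 2.0 * float(stats.norm.sf(z)))


def signed_rank_test(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> SignedRankResult:
    """Paired two-sided Wilcoxon signed-rank test of ``x`` against ``y``.

    Pairs with zero difference are removed; if none remain the result is
    ``DEGENERATE`` with p = 1.  Tie-free samples with n_effective <= 25 use
    the exact enumeration null; otherwise the tie-corrected normal
    approximation (or, for tied samples too small for it, exact enumeration
    over the observed midranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"paired series must be 1-D of equal length, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")

    d = x - y
    n_input = int(d.size)
    nonzero = d != 0.0
    d_nz = d[nonzero]
    n_eff = int(d_nz.size)
    if n_eff == 0:
        return SignedRankResult(
            n_input=n_input,
            n_effective=0,
            w_plus=0.0,
            w_minus=0.0,
            statistic=0.0,
            p_value=1.0,
            method=Method.DEGENERATE,
        )

    abs_d = np.abs(d_nz)
    ranks = stats.rankdata(abs_d)  # midranks on ties
    w_plus = float(ranks[d_nz > 0].sum())
    w_minus = float(ranks[d_nz < 0].sum())
    statistic = min(w_plus, w_minus)

    _, tie_counts = np.unique(abs_d, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and n_eff <= EXACT_N_MAX:
        counts = _null_counts(n_eff)
        p = _two_sided_from_counts(counts, int(round(statistic)), n_eff)
        method = Method.EXACT
    elif n_eff >= NORMAL_N_MIN:
        p = normal_approx_p(w_plus, n_eff, tie_sizes=tie_counts[tie_counts > 1])
        method = Method.NORMAL_APPROX
    else:
        # small tied sample: enumerate over the observed midranks
        counts, scale = _tied_null_counts(ranks)
        p = _two_sided_from_counts(counts, int(round(scale * statistic)), n_eff)
        method = Method.EXACT

    return SignedRankResult(
        n_input=n_input,
        n_effective=n_eff,
        w_plus=w_plus,
        w_minus=w_minus,
        statistic=statistic,
        p_value=p,
        method=method,
    )


def oracle_p(differences: Sequence[float] | np.ndarray) -> float:
    """Brute-force two-sided signed-rank p-value by full sign enumeration.

    Independent of :func:`signed_rank_test`: iterates explicitly over every
    sign vector of the nonzero differences, computes min(W+, W-) for each,
    and reports the tail probability P(min(W+, W-) <= observed).  Ties keep
    their observed midranks.  Exponential — capped at 14 nonzero pairs.
    """
    d = np.asarray(differences, dtype=float)
    d_nz = d[d != 0.0]
    n = int(d_nz.size)
    if n < 1:
        return 1.0
    if n > ORACLE_N_MAX:
        raise ValueError(f"oracle limited to {ORACLE_N_MAX} nonzero differences, got {n}")
    ranks = stats.rankdata(np.abs(d_nz))
    total = float(ranks.sum())
    obs_w_plus = float(ranks[d_nz > 0].sum())
    obs_min = min(obs_w_plus, total - obs_w_plus)

    count = 0
    for signs in itertools.product((1.0, -1.0), repeat=n):
        w_plus = float(sum(r for r, s in zip(ranks, signs) if s > 0))
        if min(w_plus, total - w_plus) <= obs_min:
            count += 1
    return count / float(2**n)
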