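"""Rank-based test statistics for intron score comparisons.

The enrichment procedure compares the functional scores of the variants in
one intron against the pooled scores of the variants in all other introns.
Because functional scores are heavily tied at gene scale (many variants share
the same precomputed score), every statistic here carries the standard tie
correction; the one-sided Mann-Whitney/Wilcoxon test additionally applies a
continuity correction in its normal approximation and switches to exact
enumeration of rank assignments for small, cross-tie-free inputs.

All p-values are floored at ``P_FLOOR`` so that downstream ranking by p-value
is always a strict ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankTestResult",
    "mid_ranks",
    "mwu_one_sided_greater",
    "kruskal_wallis",
    "chi_square_upper_tail",
    "bonferroni_threshold",
    "P_FLOOR",
    "EXACT_MAX_N",
]

#: smallest reported p-value; keeps log-scale ranking well defined
P_FLOOR = 1e-300

#: pooled-sample-size bound below which the one-sided U test enumerates
#: all choose(n1+n2, n1) group assignments exactly
EXACT_MAX_N = 12


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a rank test, with method provenance.

    ``statistic`` is U for the Mann-Whitney test and H for Kruskal-Wallis.
    ``tie_correction`` is the multiplicative variance deflation factor
    ``1 - sum(t^3 - t) / (n^3 - n)`` computed over pooled tie groups
    (1.0 when there are no ties).
    """

    statistic: float
    p: float
    method: str  # "exact" | "normal_approx" | "chi_square"
    z: Optional[float] = None
    df: Optional[int] = None
    tie_correction: float = 1.0
    warnings_: tuple = field(default=())

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p": self.p,
            "method": self.method,
            "z": self.z,
            "df": self.df,
            "tie_correction": self.tie_correction,
        }


def _as_finite_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mid_ranks(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks of ``values``: tied values share the mean of their ranks.

    The ranks sum to ``n(n+1)/2`` regardless of ties.
    """
    arr = _as_finite_array(values, "values")
    return sps.rankdata(arr, method="average")


def _tie_term(pooled: np.ndarray) -> tuple[float, float]:
    """Return (sum(t^3 - t), tie_correction factor) for the pooled sample."""
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    s = float(np.sum(t**3 - t))
    if n < 2:
        return s, 1.0
    return s, 1.0 - s / (n**3 - n)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U counting pairs with x > y plus half of the tied pairs."""
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled, method="average")
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mwu_one_sided_greater(
    x: Sequence[float], y: Sequence[float]
) -> RankTestResult:
    """One-sided Mann-Whitney U test of the hypothesis that ``x`` tends to
    exceed ``y`` (upper tail).

    The asymptotic path uses the tie-corrected variance and a 0.5 continuity
    correction. When the pooled size is at most ``EXACT_MAX_N`` and no value
    occurs in both groups, the p-value is instead the exact proportion of the
    ``choose(n1+n2, n1)`` equally likely group assignments whose U statistic
    is at least the observed one.
    """
    xa = _as_finite_array(x, "x")
    ya = _as_finite_array(y, "y")
    n1, n2 = xa.size, ya.size
    n = n1 + n2
    pooled = np.concatenate([xa, ya])
    u = _u_statistic(xa, ya)

    tie_sum, tie_corr = _tie_term(pooled)

    if np.all(pooled == pooled[0]):
        # every pairwise comparison is a tie; no evidence in either direction
        msg = "all pooled values identical; degenerate variance, p set to 1"
        warnings.warn(msg)
        return RankTestResult(
            statistic=u, p=1.0, method="exact", tie_correction=0.0,
            warnings_=(msg,),
        )

    cross_ties = bool(np.intersect1d(np.unique(xa), np.unique(ya)).size)
    if n <= EXACT_MAX_N and not cross_ties:
        # conditional permutation null: enumerate group assignments
        hits = 0
        total = 0
        for idx in combinations(range(n), n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            u_perm = _u_statistic(pooled[sel], pooled[~sel])
            if u_perm >= u - 1e-12:
                hits += 1
            total += 1
        p = max(hits / total, P_FLOOR)
        return RankTestResult(
            statistic=u, p=p, method="exact", tie_correction=tie_corr
        )

    mean = n1 * n2 / 2.0
    var = (n1 * n2 / 12.0) * ((n + 1) - tie_sum / (n * (n - 1)))
    if var <= 0:
        msg = "zero variance after tie correction; p set to 1"
        warnings.warn(msg)
        return RankTestResult(
            statistic=u, p=1.0, method="exact", tie_correction=tie_corr,
            warnings_=(msg,),
        )
    z = (u - mean - 0.5) / np.sqrt(var)
    p = float(np.clip(sps.norm.sf(z), P_FLOOR, 1.0))
    return RankTestResult(
        statistic=u, p=p, method="normal_approx", z=float(z),
        tie_correction=tie_corr,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H test over ``groups``.

    Empty groups must be removed by the caller; ``df = k - 1`` for the k
    groups actually tested.
    """
    arrays = [_as_finite_array(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis requires at least 2 non-empty groups")
    k = len(arrays)
    pooled = np.concatenate(arrays)
    n = pooled.size
    _, tie_corr = _tie_term(pooled)
    df = k - 1
    if np.all(pooled == pooled[0]):
        return RankTestResult(
            statistic=0.0, p=1.0, method="chi_square", df=df,
            tie_correction=0.0,
        )
    ranks = sps.rankdata(pooled, method="average")
    h = 0.0
    offset = 0
    for arr in arrays:
        r = ranks[offset : offset + arr.size]
        h += r.sum() ** 2 / arr.size
        offset += arr.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    h /= tie_corr
    p = chi_square_upper_tail(h, df)
    return RankTestResult(
        statistic=float(h), p=p, method="chi_square", df=df,
        tie_correction=tie_corr,
    )


def chi_square_upper_tail(x: float, df: int) -> float:
    """Survival function of the chi-square law with ``df`` degrees of freedom."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("x must be >= 0")
    return float(np.clip(sps.chi2.sf(x, df), P_FLOOR, 1.0))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold ``alpha / m`` for ``m`` tests."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m
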