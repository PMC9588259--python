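"""Comparison statistics for paired motion amplitudes.

Two tumor-motion measurement methods (e.g. projection radiography vs
respiratory-gated 4D-CT) yield paired per-case amplitudes; agreement is
assessed with Spearman's rank correlation and the exact Wilcoxon
signed-rank test, plus median / interquartile-range summaries.

Exact p-values are computed by full enumeration — all n! rank
permutations for Spearman at small n, all 2^m sign assignments for
Wilcoxon — with large-sample approximations beyond the enumeration
thresholds.  Ties receive average ranks throughout; zero differences are
dropped (and counted) before the signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import norm, rankdata, t as t_dist

__all__ = [
    "PairedAmplitudes",
    "spearman",
    "wilcoxon_signed_rank",
    "summarize",
]

SPEARMAN_EXACT_MAX_N = 9
WILCOXON_EXACT_MAX_M = 20


@dataclass
class PairedAmplitudes:
    """Paired per-case measurements from two methods.

    Pairs with a missing member (NaN/None) are excluded from the tests;
    ``n_excluded`` reports how many were dropped.
    """

    labels: list[str]
    a_mm: np.ndarray
    b_mm: np.ndarray
    axis: str = "SI"

    def __post_init__(self) -> None:
        self.a_mm = np.asarray(
            [np.nan if v is None else v for v in np.atleast_1d(self.a_mm)], dtype=float
        )
        self.b_mm = np.asarray(
            [np.nan if v is None else v for v in np.atleast_1d(self.b_mm)], dtype=float
        )
        if not len(self.labels) == len(self.a_mm) == len(self.b_mm):
            raise ValueError("labels, a_mm and b_mm must have equal lengths")

    def complete(self) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(self.a_mm) & np.isfinite(self.b_mm)
        return self.a_mm[ok], self.b_mm[ok]

    @property
    def n_excluded(self) -> int:
        return int((~(np.isfinite(self.a_mm) & np.isfinite(self.b_mm))).sum())


def _rank_corr(ra: np.ndarray, rb: np.ndarray) -> float:
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra * ra).sum() * (rb * rb).sum())
    return float((ra * rb).sum() / denom)


def spearman(pairs: PairedAmplitudes) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of the average-ranked values.  For
    n <= 9 complete pairs the p-value is exact: the proportion of all n!
    permutations of one ranking whose |rho| matches or exceeds the
    observed value.  For larger n the usual t-approximation with
    n - 2 degrees of freedom is used.
    """
    a, b = pairs.complete()
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    ra, rb = rankdata(a), rankdata(b)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise ValueError("zero variance in a ranking; correlation undefined")
    rho = _rank_corr(ra, rb)
    if n <= SPEARMAN_EXACT_MAX_N:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(range(n)):
            r = _rank_corr(ra, rb[list(perm)])
            count += abs(r) >= target
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t_stat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * t_dist.sf(abs(t_stat), df=n - 2)
    return rho, float(min(p, 1.0))


def wilcoxon_signed_rank(pairs: PairedAmplitudes) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank test on the paired differences.

    Zero differences are dropped; the absolute differences are
    average-ranked and W is the smaller of the positive- and
    negative-difference rank sums.  For m <= 20 nonzero differences the
    two-sided p-value is exact, enumerating all 2^m sign assignments;
    beyond that a normal approximation with continuity and tie
    correction is used.
    """
    a, b = pairs.complete()
    d = a - b
    d = d[d != 0]
    m = len(d)
    if m == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    total = ranks.sum()
    if m <= WILCOXON_EXACT_MAX_M:
        # exact null distribution of the positive rank sum over all 2^m
        # sign assignments; doubled ranks are integers even under ties,
        # so the distribution is built by subset-sum counting
        ranks2 = np.round(2 * ranks).astype(np.int64)
        counts = np.zeros(int(ranks2.sum()) + 1)
        counts[0] = 1.0
        for r in ranks2:
            counts[r:] += counts[:-r].copy()
        sums2 = np.arange(len(counts))
        eps = 1e-9
        w2, total2 = 2 * w, 2 * total
        tail = (sums2 <= w2 + eps) | (sums2 >= total2 - w2 - eps)
        p = min(1.0, float(counts[tail].sum() / 2.0 ** m))
    else:
        mean = total / 2.0
        var = float((ranks * ranks).sum()) / 4.0
        z = (w - mean + 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.cdf(z)))
    return w, p


def summarize(values) -> tuple[float, float, float]:
    """Median and quartiles (linear-interpolation convention).

    Quartiles follow numpy's default ``linear`` interpolation between
    order statistics (the same convention as R's ``quantile`` type 7).
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)
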