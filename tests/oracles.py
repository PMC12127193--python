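"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity from first principles (exhaustive
enumeration, exact rational arithmetic, direct formulas) without touching the
package's implementation paths.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def pairwise_auroc(levels, flags) -> float:
    """AUROC by exhaustive comparison of every (positive, negative) pair."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(flags).astype(bool)
    pos = x[y]
    neg = x[~y]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_youden(levels, flags) -> float:
    """Max J over every achievable split (all between-value thresholds plus
    the degenerate all-or-none splits), both directions."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(flags).astype(bool)
    n1, n0 = y.sum(), (~y).sum()
    u = np.unique(x)
    thresholds = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    best = -np.inf
    for t in thresholds:
        for pred in (x >= t, x <= t):
            sens = (pred & y).sum() / n1
            spec = (~pred & ~y).sum() / n0
            best = max(best, sens + spec - 1.0)
    return float(best)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration with exact
    integer arithmetic (no floating-point tie ambiguity)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # numerators share the denominator comb(n, c1); compare integers
    num_obs = comb(r1, a) * comb(r2, c1 - a)
    total = Fraction(0)
    denom = comb(n, c1)
    for k in range(lo, hi + 1):
        num_k = comb(r1, k) * comb(r2, c1 - k)
        if num_k <= num_obs:
            total += Fraction(num_k, denom)
    return float(total)


def complete_linkage_heights(points: np.ndarray, metric) -> list[float]:
    """Merge heights of naive agglomerative complete linkage on raw points.

    ``metric(u, v)`` is a pairwise distance callable.  Clusters merge at the
    smallest maximum inter-point distance; returns the sorted merge heights.
    """
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dmax = max(
                    metric(points[a], points[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if dmax < best[0]:
                    best = (dmax, i, j)
        h, i, j = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


def running_sum_es(ordered_hits: list[bool], weights: list[float]) -> float:
    """Hand arithmetic for the weighted enrichment running sum."""
    total_hit = sum(w for h, w in zip(ordered_hits, weights) if h)
    n_miss = sum(1 for h in ordered_hits if not h)
    acc = 0.0
    best = 0.0
    for h, w in zip(ordered_hits, weights):
        acc += (w / total_hit) if h else (-1.0 / n_miss)
        if abs(acc) > abs(best):
            best = acc
    return best


def pooled_t_p(a, b) -> float:
    """Textbook pooled-variance two-sample t, two-sided p via scipy's t sf."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    tstat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return float(2 * tdist.sf(abs(tstat), na + nb - 2))


def anova_f_p(groups) -> tuple[float, float]:
    """One-way ANOVA by explicit sum-of-squares arithmetic."""
    from scipy.stats import f as fdist

    groups = [np.asarray(g, float) for g in groups]
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = sum(len(g) for g in groups) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(f), float(fdist.sf(f, df_b, df_w))
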