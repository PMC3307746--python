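"""Independent brute-force oracles the implementation is tested against.

These deliberately recompute everything from first principles (per-peak rule
scans, from-scratch error-sum-of-squares agglomeration, textbook balanced
ANOVA sums of squares) and share no code with the package internals.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_filter(peaks, group, min_rfu=70.0, bp_tolerance=1.0, spacing_bp=3.0):
    """Peak-by-peak scan of the two QC rules against the explicit size grid."""
    grid = list(group.grid(spacing_bp))
    lo, hi = group.range_bp
    kept = []
    for p in peaks:
        if p.height_rfu < min_rfu:
            continue
        if p.size_bp < lo or p.size_bp > hi:
            continue
        if min(abs(p.size_bp - g) for g in grid) > bp_tolerance:
            continue
        kept.append(p)
    return kept


def brute_force_ward(X):
    """Exhaustive greedy Ward agglomeration, recomputing ESS from raw points.

    Returns (merges, heights): at each step every cluster pair's merge cost is
    the increase in total within-cluster sum of squared Euclidean distances to
    the centroid, recomputed from scratch; the minimum-cost pair merges.
    ``merges`` holds frozensets of leaf indices for each fused pair.
    """
    X = np.asarray(X, dtype=float)

    def ess(members):
        pts = X[sorted(members)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(X.shape[0])]
    merges, heights = [], []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            cost = ess(clusters[a] | clusters[b]) - ess(clusters[a]) - ess(clusters[b])
            if best is None or cost < best[0]:
                best = (cost, a, b)
        cost, a, b = best
        merges.append((clusters[a], clusters[b]))
        heights.append(cost)
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges, heights


def linkage_to_merges(Z, n):
    """Convert a scipy-layout linkage into per-step frozenset merge pairs."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for m, (a, b, _h, _s) in enumerate(Z):
        fa, fb = members[int(a)], members[int(b)]
        merges.append((fa, fb))
        members[n + m] = fa | fb
    return merges


def balanced_two_way_anova(y, a, b):
    """Textbook sums-of-squares decomposition for a balanced two-way design.

    Returns dict of (F, p) for factors A, B and the interaction, computed from
    cell/marginal means and the chi-square/F distributions only.
    """
    from scipy import stats

    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    b = np.asarray(b)
    a_levels = sorted(set(a.tolist()))
    b_levels = sorted(set(b.tolist()))
    I, J = len(a_levels), len(b_levels)
    n = len(y) // (I * J)
    grand = y.mean()
    ss_a = sum(
        n * J * (y[a == al].mean() - grand) ** 2 for al in a_levels
    )
    ss_b = sum(
        n * I * (y[b == bl].mean() - grand) ** 2 for bl in b_levels
    )
    ss_ab = 0.0
    ss_err = 0.0
    for al in a_levels:
        for bl in b_levels:
            cell = y[(a == al) & (b == bl)]
            ss_ab += n * (
                cell.mean() - y[a == al].mean() - y[b == bl].mean() + grand
            ) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    df_a, df_b = I - 1, J - 1
    df_ab = df_a * df_b
    df_err = I * J * (n - 1)
    out = {}
    for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b), ("AB", ss_ab, df_ab)):
        F = (ss / df) / (ss_err / df_err)
        out[name] = (F, float(stats.f.sf(F, df, df_err)))
    return out
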