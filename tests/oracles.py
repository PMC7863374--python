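"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, closed forms) and shares
no code with the package paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def emd_bruteforce(a_units, b_units, gd, denom: int) -> float:
    """Exact EMD by exhaustive enumeration of integer transport plans.

    ``a_units``/``b_units`` are integer masses summing to ``denom`` (so the
    histograms are a/denom, b/denom); every feasible integer flow matrix with
    those margins is enumerated and the cheapest plan's cost returned.
    """
    a = list(a_units)
    b = list(b_units)
    assert sum(a) == sum(b) == denom
    n = len(a)
    best = [None]

    def rec(i, remaining_cols, cost):
        if best[0] is not None and cost >= best[0]:
            return
        if i == n:
            if all(c == 0 for c in remaining_cols):
                best[0] = cost
            return
        # enumerate row i allocations over columns
        def fill(j, left, cols, c):
            if best[0] is not None and c >= best[0]:
                return
            if j == n - 1:
                if left <= cols[j]:
                    cols2 = list(cols)
                    cols2[j] -= left
                    rec(i + 1, cols2, c + left * gd[i][j])
                return
            for f in range(min(left, cols[j]), -1, -1):
                cols2 = list(cols)
                cols2[j] -= f
                fill(j + 1, left - f, cols2, c + f * gd[i][j])

        fill(0, a[i], remaining_cols, cost)

    rec(0, b, 0.0)
    return best[0] / denom


def anosim_r(values_condensed, groups) -> float:
    """Rank-based ANOSIM R computed from first principles with midranks."""
    vals = np.asarray(values_condensed, float)
    order = np.argsort(vals, kind="stable")
    ranks = np.empty(len(vals))
    i = 0
    sorted_vals = vals[order]
    while i < len(vals):
        j = i
        while j + 1 < len(vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    n = len(groups)
    within, between = [], []
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            (within if groups[i] == groups[j] else between).append(ranks[k])
            k += 1
    m = n * (n - 1) / 2
    return (np.mean(between) - np.mean(within)) / (m / 2)


def anosim_exhaustive_p(values_condensed, groups) -> float:
    """Exact one-sided p over every distinct relabeling of the groups."""
    groups = list(groups)
    n = len(groups)
    r_obs = anosim_r(values_condensed, groups)
    label_a = groups[0]
    size_a = groups.count(label_a)
    label_b = next(g for g in groups if g != label_a)
    hits = 0
    total = 0
    for idx in combinations(range(n), size_a):
        perm = [label_b] * n
        for i in idx:
            perm[i] = label_a
        total += 1
        if anosim_r(values_condensed, perm) >= r_obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of arrangements."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n1 = len(x)
    ranks = _midranks(pooled)
    mu = n1 * (len(pooled) - n1) / 2
    offset = n1 * (n1 + 1) / 2
    u_obs = ranks[:n1].sum() - offset
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in idx) - offset
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def _midranks(vals):
    vals = np.asarray(vals, float)
    order = np.argsort(vals, kind="stable")
    ranks = np.empty(len(vals))
    i = 0
    sv = vals[order]
    while i < len(vals):
        j = i
        while j + 1 < len(vals) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def rational_mass_splits(n_bins: int, denom: int):
    """All histograms over ``n_bins`` bins with masses k/denom (compositions)."""
    out = []

    def rec(prefix, left, slots):
        if slots == 1:
            out.append(tuple(prefix + [left]))
            return
        for k in range(left + 1):
            rec(prefix + [k], left - k, slots - 1)

    rec([], denom, n_bins)
    return out
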