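"""Independent brute-force oracles used to validate the implementations.

Everything here is written for clarity at tiny n, not speed, and shares
no code with the package: naive O(n^3) UPGMA, pairwise-loop silhouette,
hand product-limit and per-event-time log-rank, enumeration-based
Mann-Whitney, pairwise-concordance AUC, and rank-then-Pearson Spearman.
"""

from __future__ import annotations

import itertools

import numpy as np


def upgma_merge_heights(d: np.ndarray):
    """Naive UPGMA: returns (merge heights, final partitions by level).

    Clusters are frozensets of leaf indices; at each step the pair with
    the smallest average inter-cluster distance merges (ties by the
    lexicographically smallest pair of sorted member tuples).
    """
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    partitions = [list(clusters)]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            avg = np.mean([d[i, j] for i in ca for j in cb])
            key = (avg, tuple(sorted(ca)), tuple(sorted(cb)))
            if best is None or key < best[0]:
                best = (key, a, b)
        (avg, _, _), a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)] + [merged]
        heights.append(avg)
        partitions.append(list(clusters))
    return heights, partitions


def upgma_labels(d: np.ndarray, k: int) -> np.ndarray:
    """Cluster labels from the naive UPGMA cut at k clusters."""
    _, partitions = upgma_merge_heights(d)
    part = next(p for p in partitions if len(p) == k)
    labels = np.empty(d.shape[0], dtype=int)
    for lab, cluster in enumerate(part, start=1):
        for i in cluster:
            labels[i] = lab
    return labels


def silhouette_brute(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rousseeuw silhouette by explicit pairwise loops; singletons get 0."""
    n = d.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([d[i, j] for j in own])
        b = np.inf
        for g in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == g]
            b = min(b, np.mean([d[i, j] for j in other]))
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


def km_brute(times, events):
    """Product-limit estimator by explicit per-time computation."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    grid = np.unique(times)
    surv = []
    s = 1.0
    for t in grid:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        surv.append(s)
    return grid, np.array(surv)


def logrank_brute(times, events, groups):
    """Multi-group log-rank chi2 by per-event-time O−E with hypergeometric variance."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    g = levels.size
    obs = np.zeros(g)
    exp = np.zeros(g)
    var = np.zeros((g, g))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = np.sum((times == t) & (events == 1))
        n_i = np.array([np.sum(at_risk & (groups == lv)) for lv in levels])
        d_i = np.array([np.sum((times == t) & (events == 1) & (groups == lv)) for lv in levels])
        obs += d_i
        exp += d_t * n_i / n_t
        if n_t > 1:
            for a in range(g):
                for b in range(g):
                    if a == b:
                        var[a, b] += (
                            d_t * (n_i[a] / n_t) * (1 - n_i[a] / n_t) * (n_t - d_t) / (n_t - 1)
                        )
                    else:
                        var[a, b] += -d_t * n_i[a] * n_i[b] / n_t**2 * (n_t - d_t) / (n_t - 1)
    z = (obs - exp)[:-1]
    v = var[:-1, :-1]
    chi2 = float(z @ np.linalg.solve(v, z))
    return chi2


def mann_whitney_exact_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = x.size

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    mean_u = n1 * y.size / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(pooled.size), n1):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


def auc_pairwise(scores, labels):
    """AUC as the fraction of concordant positive/negative pairs (ties = 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += (p > q) + 0.5 * (p == q)
    return total / (pos.size * neg.size)


def spearman_brute(x, y):
    """Spearman as Pearson on midranks."""
    def midrank(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(v.size)
        i = 0
        sv = v[order]
        while i < v.size:
            j = i
            while j < v.size and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    rx, ry = midrank(x), midrank(y)
    return float(np.corrcoef(rx, ry)[0, 1])
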