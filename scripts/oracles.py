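"""Naive reference implementations used as oracles by the acceptance script.

Everything here is deliberately written as plain double loops, independent
of the package's vectorised code paths.
"""

from __future__ import annotations

import itertools

import numpy as np

import mihc
from mihc.selection import NonNoiseSystem


def naive_bag_distance(a, b, mode="avg_hausdorff"):
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))

    def d(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return 2.0
        return 1.0 - np.corrcoef(x, y)[0, 1]

    row_mins = [min(d(x, y) for y in b) for x in a]
    col_mins = [min(d(x, y) for x in a) for y in b]
    if mode == "avg_hausdorff":
        return (sum(row_mins) + sum(col_mins)) / (len(a) + len(b))
    if mode == "max_hausdorff":
        return max(max(row_mins), max(col_mins))
    return min(col_mins)


def naive_mihc_merges(bags, stop_tau, mode="avg_hausdorff"):
    """Agglomeration that recomputes all pairwise bag distances each step."""
    clusters = {i: np.array(b) for i, b in enumerate(bags)}
    merges = []
    next_id = len(bags)
    while len(clusters) > 1:
        keys = sorted(clusters)
        h, a, b = min(
            (naive_bag_distance(clusters[i], clusters[j], mode), i, j)
            for i, j in itertools.combinations(keys, 2)
        )
        if h > stop_tau:
            break
        merged = np.vstack([clusters.pop(a), clusters.pop(b)])
        clusters[next_id] = merged
        merges.append((a, b, h, next_id))
        next_id += 1
    return merges


def nns_from_bags(bags):
    """Wrap raw profile bags as a NonNoiseSystem (one term per bag)."""
    genes, rows, cliques, pairs = [], [], {}, []
    for t, bag in enumerate(bags):
        term = f"T{t}"
        members = []
        for i, prof in enumerate(bag):
            gid = f"T{t}_g{i}"
            genes.append(gid)
            rows.append(prof)
            members.append(gid)
            pairs.append((gid, term))
        cliques[term] = frozenset(members)
    expr = mihc.TimeCourseMatrix(genes, np.arange(len(rows[0]), dtype=float),
                                 np.array(rows))
    return NonNoiseSystem(cliques, expr, mihc.AnnotationMap.from_pairs(pairs))


def brute_knn(x, X, Y, k):
    """Exhaustive multi-label KNN: neighbours, similarity scores, labels."""
    def sim(u, v):
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            return 0.0
        return (1.0 + np.corrcoef(u, v)[0, 1]) / 2.0

    sims = np.array([sim(x, row) for row in X])
    order = sorted(range(len(X)), key=lambda i: (1 - (2 * sims[i] - 1), i))
    nbrs = order[:k]
    candidates = {c for i in nbrs for c in np.nonzero(Y[i])[0]}
    scores = {c: sum(sims[i] for i in nbrs if Y[i, c]) for c in candidates}
    total = sum(sims[i] for i in nbrs)
    labels = {c for c, s in scores.items() if s > total / 2}
    return nbrs, scores, labels


def brute_auc(scores, y):
    """Pairwise Mann-Whitney AUC with ties counted 1/2."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))
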