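"""Independent reference implementations used to cross-check the package.

Everything here deliberately avoids the code paths under test: graphs are
hand-rolled edge sets, distances come from scipy's Floyd–Warshall, and the
ranking metrics are literal double loops over their definitions.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall


def random_connected_graph(
    n: int, n_extra: int, seed: int
) -> tuple[list[str], list[tuple[str, str]]]:
    """A connected graph: a random spanning path plus ``n_extra`` random edges."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:03d}" for i in range(n)]
    order = rng.permutation(n)
    edges = {(min(a, b), max(a, b)) for a, b in zip(order[:-1], order[1:])}
    while len(edges) < n - 1 + n_extra:
        a, b = (int(v) for v in rng.integers(n, size=2))
        if a != b:
            edges.add((min(a, b), max(a, b)))
    return nodes, [(nodes[a], nodes[b]) for a, b in sorted(edges)]


def allpairs_matrix(
    nodes: list[str], edges: list[tuple[str, str]]
) -> tuple[np.ndarray, dict[str, int]]:
    """Dense all-pairs shortest-path matrix via scipy Floyd–Warshall."""
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for a, b in edges:
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = floyd_warshall(adj, directed=False, unweighted=True)
    return dist, index


def brute_asp(dist, index, H, D) -> float:
    total = 0.0
    for h in H:
        for d in D:
            total += dist[index[h], index[d]]
    return total / (len(H) * len(D))


def brute_acp(dist, index, H, D) -> float:
    total = 0.0
    for h in H:
        total += min(dist[index[h], index[d]] for d in D)
    return total / len(H)


def brute_wacp(dist, index, weights, D) -> float:
    total = 0.0
    for h, w in weights.items():
        total += min(dist[index[h], index[d]] for d in D) / w
    return total / len(weights)


def pairwise_auroc(scores, labels) -> float:
    """P(random positive outranks random negative); smaller score = stronger."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p < q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def step_auprc(scores, labels) -> float:
    """Mean precision at each positive in the ranking (ties not supported)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(scores, kind="stable")  # strongest (smallest) first
    hits = 0
    total = 0.0
    for rank, lab in enumerate(labels[order], start=1):
        if lab:
            hits += 1
            total += hits / rank
    return total / labels.sum()


def scan_threshold(scores, labels, target_fpr) -> tuple[float, float]:
    """Linear scan over all candidate thresholds; returns (threshold, recall)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    neg = scores[labels == 0]
    pos = scores[labels == 1]
    best = (-np.inf, 0.0)
    for t in np.unique(scores):
        fpr = float(np.mean(neg <= t))
        if fpr <= target_fpr and t > best[0]:
            best = (float(t), float(np.mean(pos <= t)))
    return best
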