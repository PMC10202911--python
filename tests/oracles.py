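"""Independent brute-force implementations used to cross-check the metric
code.  Everything here works from first principles on explicit path / clique
/ tree enumerations and deliberately avoids the library's own shortest-path
or clique routines.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _scipy_components


def adjacency(graph) -> dict:
    adj: dict = {v: set() for v in graph.nodes}
    for a, b in graph.edges():
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def all_shortest_paths(adj: dict, s, t) -> list[tuple]:
    """Every shortest s-t path, by backtracking over the BFS distance table."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def extend(node, acc):
        if node == s:
            paths.append(tuple(reversed(acc)))
            return
        for u in adj[node]:
            if dist.get(u, -1) == dist[node] - 1:
                extend(u, acc + [u])

    extend(t, [t])
    return paths


def degree_oracle(graph) -> dict:
    adj = adjacency(graph)
    return {v: float(len(adj[v])) for v in adj}


def clustering_oracle(graph) -> dict:
    adj = adjacency(graph)
    out = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        e = sum(1 for a, b in combinations(sorted(nbrs, key=str), 2) if b in adj[a])
        out[v] = 2.0 * e / (k * (k - 1))
    return out


def _neighborhood_components(adj: dict, v) -> list[set]:
    nbrs = adj[v]
    sub = {u: adj[u] & nbrs for u in nbrs}
    seen: set = set()
    comps = []
    for u in nbrs:
        if u in seen:
            continue
        comp = set(bfs_distances(sub, u))
        comps.append(comp)
        seen |= comp
    return comps


def mnc_oracle(graph) -> dict:
    adj = adjacency(graph)
    out = {}
    for v in adj:
        comps = _neighborhood_components(adj, v)
        out[v] = float(max((len(c) for c in comps), default=0))
    return out


def dmnc_oracle(graph, epsilon: float = 1.7) -> dict:
    adj = adjacency(graph)
    out = {}
    for v in adj:
        comps = _neighborhood_components(adj, v)
        if not comps:
            out[v] = 0.0
            continue
        best = max(
            comps,
            key=lambda c: (
                len(c),
                sum(1 for a, b in combinations(sorted(c, key=str), 2) if b in adj[a]),
                tuple(sorted(map(str, c))),
            ),
        )
        n = len(best)
        e = sum(1 for a, b in combinations(sorted(best, key=str), 2) if b in adj[a])
        out[v] = e / n**epsilon if n > 1 else 0.0
    return out


def maximal_cliques(adj: dict) -> list[frozenset]:
    """Plain Bron-Kerbosch without pivoting."""
    cliques: list[frozenset] = []

    def bk(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        for v in sorted(p, key=str):
            bk(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bk(set(), set(adj), set())
    return cliques


def mcc_oracle(graph) -> dict:
    adj = adjacency(graph)
    out = {v: 0.0 for v in adj}
    for clique in maximal_cliques(adj):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += w
    for v in adj:
        nbrs = adj[v]
        if not any(b in adj[a] for a, b in combinations(sorted(nbrs, key=str), 2)):
            out[v] = float(len(nbrs))
    return out


def betweenness_oracle(graph) -> dict:
    adj = adjacency(graph)
    nodes = sorted(adj, key=str)
    out = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out


def stress_oracle(graph) -> dict:
    adj = adjacency(graph)
    nodes = sorted(adj, key=str)
    out = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        for p in all_shortest_paths(adj, s, t):
            for v in p[1:-1]:
                out[v] += 1.0
    return out


def closeness_oracle(graph) -> dict:
    adj = adjacency(graph)
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        out[v] = sum(1.0 / d for w, d in dist.items() if w != v)
    return out


def eccentricity_oracle(graph) -> dict:
    adj = adjacency(graph)
    return {v: float(max(bfs_distances(adj, v).values())) for v in adj}


def radiality_oracle(graph) -> dict:
    adj = adjacency(graph)
    out = {}
    # group into components first
    seen: set = set()
    for v in sorted(adj, key=str):
        if v in seen:
            continue
        comp = sorted(bfs_distances(adj, v), key=str)
        seen |= set(comp)
        tables = {u: bfs_distances(adj, u) for u in comp}
        diam = max(max(t.values()) for t in tables.values())
        for u in comp:
            if len(comp) == 1:
                out[u] = 0.0
            else:
                out[u] = sum(
                    diam + 1 - d for w, d in tables[u].items() if w != u
                ) / (len(comp) - 1)
    return out


def bottleneck_oracle(graph, fraction: float = 0.25) -> dict:
    """Explicit tree-descendant count: build the same deterministic BFS tree
    (parent = lowest-sorting closer neighbour), then walk every node's path
    to the root, crediting each node passed (itself included)."""
    adj = adjacency(graph)
    out = {v: 0.0 for v in adj}
    for s in adj:
        dist = bfs_distances(adj, s)
        parent = {}
        for v, d in dist.items():
            if v == s:
                continue
            parent[v] = min(
                (u for u in adj[v] if dist.get(u, -1) == d - 1), key=str
            )
        tree_size = len(dist)
        passes = {v: 0 for v in dist}
        for w in parent:
            node = w
            while node != s:
                passes[node] += 1
                node = parent[node]
        for v in parent:
            if passes[v] > fraction * tree_size:
                out[v] += 1.0
    return out


def epc_oracle(graph, retention: float, realizations: int, seed: int):
    """Independent Monte-Carlo percolation using scipy's sparse component
    labelling.  Returns (means, standard errors of those means).

    Edges are put in the same canonical order as the implementation so
    that, run with the same seed, both draw identical survival masks and
    the comparison checks the component counting exactly (common random
    numbers); with different seeds the streams are independent."""
    nodes = sorted(graph.nodes, key=str)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.array(
        sorted(tuple(sorted((idx[a], idx[b]))) for a, b in graph.edges()), dtype=int
    ).reshape(-1, 2)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    sizes = np.zeros((realizations, n))
    for r in range(realizations):
        keep = rng.random(len(edges)) < retention if len(edges) else np.zeros(0, bool)
        kept = edges[keep]
        data = np.ones(len(kept))
        mat = csr_matrix((data, (kept[:, 0], kept[:, 1])), shape=(n, n))
        _, labels = _scipy_components(mat, directed=False)
        _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
        sizes[r] = counts[inverse] - 1
    means = sizes.mean(axis=0)
    se = sizes.std(axis=0, ddof=1) / np.sqrt(realizations)
    return (
        {v: float(means[idx[v]]) for v in nodes},
        {v: float(se[idx[v]]) for v in nodes},
    )


def trapezoid_auc(scores, labels) -> float:
    """ROC area by explicit trapezoid over score thresholds (ties form
    blocks), independent of the rank-sum identity."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    n_pos, n_neg = labels.sum(), (~labels).sum()
    tps, fps = [0.0], [0.0]
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tps.append(tps[-1] + labels[i:j].sum())
        fps.append(fps[-1] + (~labels[i:j]).sum())
        i = j
    area = 0.0
    for k in range(1, len(tps)):
        area += (fps[k] - fps[k - 1]) * (tps[k] + tps[k - 1]) / 2.0
    return area / (n_pos * n_neg)
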