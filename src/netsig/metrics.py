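"""The twelve node-scoring metrics for gene-interaction networks.

Local metrics score a node from its immediate neighbourhood: Degree,
Maximal Clique Centrality (MCC), Density of Maximum Neighborhood Component
(DMNC), Maximum Neighborhood Component (MNC) and Clustering Coefficient.
Global metrics score a node against the whole network: Betweenness,
Bottleneck, Eccentricity, Closeness (reciprocal-distance form), Radiality,
Stress and Edge Percolated Component (EPC).

Operator conventions (pinned so that scores are reproducible and testable
against brute-force oracles):

* Betweenness and Stress sum over unordered source-target pairs with
  endpoints excluded.
* Closeness is the reciprocal-distance (harmonic) form, so unreachable
  pairs contribute 0 and disconnected graphs need no special casing.
* Radiality and Eccentricity are computed per connected component;
  singleton components score 0.
* Bottleneck grows one BFS shortest-path tree per source with a
  deterministic parent rule (lowest-sorting neighbour); a node scores +1
  for a source when its subtree holds more than ``bottleneck_fraction`` of
  the tree's nodes.
* EPC is a seeded Monte-Carlo estimate of the expected number of *other*
  nodes reachable after independent edge percolation.

All functions accept a :class:`~netsig.types.GeneGraph` or a bare
:class:`networkx.Graph`, allow disconnected graphs, and return a
``{gene: score}`` dict over all nodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import networkx as nx
import numpy as np

from .types import GeneGraph, as_nx

logger = logging.getLogger(__name__)

__all__ = [
    "METRIC_NAMES",
    "LOCAL_METRICS",
    "GLOBAL_METRICS",
    "MetricParams",
    "MetricScores",
    "RankedGeneSet",
    "degree_scores",
    "clustering_coefficient_scores",
    "mnc_scores",
    "dmnc_scores",
    "mcc_scores",
    "betweenness_scores",
    "stress_scores",
    "closeness_scores",
    "radiality_scores",
    "eccentricity_scores",
    "bottleneck_scores",
    "epc_scores",
    "score_all",
    "top_k",
]

LOCAL_METRICS = ("degree", "mcc", "dmnc", "mnc", "clustering_coefficient")
GLOBAL_METRICS = (
    "betweenness",
    "bottleneck",
    "eccentricity",
    "closeness",
    "radiality",
    "stress",
    "epc",
)
METRIC_NAMES: tuple[str, ...] = LOCAL_METRICS + GLOBAL_METRICS


@dataclass(frozen=True)
class MetricParams:
    """Tunable operator constants.

    dmnc_epsilon
        Exponent in the DMNC density E/N**epsilon (default 1.7).
    bottleneck_fraction
        A node is a bottleneck for a source when its shortest-path-tree
        subtree exceeds this fraction of the tree (default 0.25, the
        "n/4" rule).
    epc_realizations, epc_retention
        Monte-Carlo sample count and per-edge retention probability for
        edge percolation.
    seed
        Seed for the EPC percolation stream.
    """

    dmnc_epsilon: float = 1.7
    bottleneck_fraction: float = 0.25
    epc_realizations: int = 1000
    epc_retention: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dmnc_epsilon <= 0:
            raise ValueError("dmnc_epsilon must be > 0")
        if not 0 < self.bottleneck_fraction < 1:
            raise ValueError("bottleneck_fraction must lie in (0, 1)")
        if self.epc_realizations < 1:
            raise ValueError("epc_realizations must be >= 1")
        if not 0 <= self.epc_retention <= 1:
            raise ValueError("epc_retention must lie in [0, 1]")


@dataclass
class MetricScores:
    """Per-metric score maps plus the parameters that produced them."""

    scores: dict[str, dict[str, float]]
    params: MetricParams

    def __getitem__(self, metric: str) -> dict[str, float]:
        return self.scores[metric]

    def metrics(self) -> list[str]:
        return list(self.scores)


@dataclass
class RankedGeneSet:
    """Tie-aware ranked top-k selection from one score map.

    ``entries`` is ordered by score descending (symbol-alphabetical within
    ties); equal scores share a rank (competition ranking).  The set may be
    larger than ``nominal_k`` when genes tie at the cutoff score.
    """

    entries: list[tuple[str, float, int]]
    source: str
    nominal_k: int

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def to_set(self) -> set[str]:
        return set(self.genes)

    def __len__(self) -> int:
        return len(self.entries)


# --------------------------------------------------------------------------
# local metrics

def degree_scores(g: GeneGraph | nx.Graph) -> dict[str, float]:
    """Number of incident edges."""
    G = as_nx(g)
    return {v: float(d) for v, d in G.degree()}


def clustering_coefficient_scores(g: GeneGraph | nx.Graph) -> dict[str, float]:
    """Fraction of realized edges among each node's neighbours; k<2 -> 0."""
    G = as_nx(g)
    return {v: float(c) for v, c in nx.clustering(G).items()}


def _max_neighborhood_component(G: nx.Graph, v) -> nx.Graph:
    """Largest connected component of the neighbourhood-induced subgraph.

    Largest by node count; edge count breaks ties (then lexicographic node
    set, for determinism).
    """
    sub = G.subgraph(list(G.neighbors(v)))
    if sub.number_of_nodes() == 0:
        return sub
    comps = [sub.subgraph(c) for c in nx.connected_components(sub)]
    return max(
        comps,
        key=lambda c: (c.number_of_nodes(), c.number_of_edges(), tuple(sorted(map(str, c.nodes)))),
    )


def mnc_scores(g: GeneGraph | nx.Graph) -> dict[str, float]:
    """Node count of the maximum neighborhood component; isolated node -> 0."""
    G = as_nx(g)
    return {v: float(_max_neighborhood_component(G, v).number_of_nodes()) for v in G}


def dmnc_scores(
    g: GeneGraph | nx.Graph, params: MetricParams = MetricParams()
) -> dict[str, float]:
    """E / N**epsilon over the maximum neighborhood component; N<=1 -> 0."""
    G = as_nx(g)
    eps = params.dmnc_epsilon
    out: dict[str, float] = {}
    for v in G:
        comp = _max_neighborhood_component(G, v)
        n = comp.number_of_nodes()
        out[v] = comp.number_of_edges() / n**eps if n > 1 else 0.0
    return out


def mcc_scores(g: GeneGraph | nx.Graph) -> dict[str, float]:
    """Sum of (|C|-1)! over maximal cliques C containing the node.

    Special rule: a node whose neighbourhood contains no edges scores its
    degree instead (applied per node).
    """
    G = as_nx(g)
    out = {v: 0.0 for v in G}
    no_edge_neighborhood = {
        v for v in G if _neighborhood_edge_count(G, v) == 0
    }
    for clique in nx.find_cliques(G):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += w
    for v in no_edge_neighborhood:
        out[v] = float(G.degree(v))
    return out


def _neighborhood_edge_count(G: nx.Graph, v) -> int:
    nbrs = list(G.neighbors(v))
    return G.subgraph(nbrs).number_of_edges()


# --------------------------------------------------------------------------
# global metrics

def betweenness_scores(g: GeneGraph | nx.Graph) -> dict[str, float]:
    """Sum over unordered pairs s!=v!=t of sigma_st(v)/sigma_st."""
    G = as_nx(g)
    return {v: float(b) for v, b in nx.betweenness_centrality(G, normalized=False).items()}


def _sigma_and_dist(G: nx.Graph):
    """All-sources BFS: distance and shortest-path-count matrices."""
    nodes = sorted(G.nodes, key=str)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                for w in G.neighbors(u):
                    wi = idx[w]
                    if np.isinf(dist[si, wi]):
                        dist[si, wi] = d + 1
                        nxt.append(w)
                    if dist[si, wi] == d + 1:
                        sigma[si, wi] += sigma[si, idx[u]]
            frontier = nxt
            d += 1
    return nodes, idx, dist, sigma


def stress_scores(g: GeneGraph | nx.Graph) -> dict[str, float]:
    """Count of shortest paths through the node (endpoints excluded,
    unordered endpoint pairs)."""
    G = as_nx(g)
    nodes, idx, dist, sigma = _sigma_and_dist(G)
    n = len(nodes)
    out: dict[str, float] = {}
    for v in nodes:
        vi = idx[v]
        # paths s-..-v-..-t: sigma(s,v)*sigma(v,t) when on a geodesic
        on_geo = dist[vi][None, :] + dist[:, vi][:, None] == dist  # [s, t]
        counts = np.where(on_geo, sigma[:, vi][:, None] * sigma[vi][None, :], 0.0)
        counts[vi, :] = 0.0
        counts[:, vi] = 0.0
        np.fill_diagonal(counts, 0.0)
        out[v] = float(counts.sum() / 2.0)
    return out


def closeness_scores(g: GeneGraph | nx.Graph) -> dict[str, float]:
    """Reciprocal-distance closeness: sum of 1/dist to reachable nodes."""
    G = as_nx(g)
    return {v: float(h) for v, h in nx.harmonic_centrality(G).items()}


def radiality_scores(g: GeneGraph | nx.Graph) -> dict[str, float]:
    """Per component: sum_w (diameter + 1 - d(v, w)) / (n_c - 1)."""
    G = as_nx(g)
    out: dict[str, float] = {}
    for comp_nodes in nx.connected_components(G):
        comp = G.subgraph(comp_nodes)
        n_c = comp.number_of_nodes()
        if n_c == 1:
            out[next(iter(comp_nodes))] = 0.0
            continue
        dist = dict(nx.all_pairs_shortest_path_length(comp))
        diam = max(max(d.values()) for d in dist.values())
        for v in comp_nodes:
            total = sum(diam + 1 - d for w, d in dist[v].items() if w != v)
            out[v] = total / (n_c - 1)
    return out


def eccentricity_scores(g: GeneGraph | nx.Graph) -> dict[str, float]:
    """Maximum distance to any reachable node; singleton component -> 0.

    Raw eccentricity is large for peripheral nodes; whether a ranking
    should treat large or small values as "top" is a caller choice (see
    ``top_k(..., ascending=True)``).
    """
    G = as_nx(g)
    out: dict[str, float] = {}
    for comp_nodes in nx.connected_components(G):
        comp = G.subgraph(comp_nodes)
        if comp.number_of_nodes() == 1:
            out[next(iter(comp_nodes))] = 0.0
        else:
            out.update({v: float(e) for v, e in nx.eccentricity(comp).items()})
    return out


def _bfs_tree_parents(G: nx.Graph, source) -> dict:
    """Deterministic BFS shortest-path tree: each node's parent is its
    lowest-sorting neighbour among those one step closer to the source."""
    dist = nx.single_source_shortest_path_length(G, source)
    parents: dict = {}
    for v, d in dist.items():
        if v == source:
            continue
        candidates = [u for u in G.neighbors(v) if dist.get(u, -1) == d - 1]
        parents[v] = min(candidates, key=str)
    return parents


def bottleneck_scores(
    g: GeneGraph | nx.Graph, params: MetricParams = MetricParams()
) -> dict[str, float]:
    """For each source's shortest-path tree, +1 for every non-source node
    whose subtree (itself included) exceeds ``bottleneck_fraction`` of the
    tree's node count."""
    G = as_nx(g)
    out = {v: 0.0 for v in G}
    for s in G:
        parents = _bfs_tree_parents(G, s)
        tree_size = len(parents) + 1
        if tree_size == 1:
            continue
        threshold = params.bottleneck_fraction * tree_size
        subtree = {v: 1 for v in parents}
        subtree[s] = 1
        # accumulate subtree sizes bottom-up: order children before parents
        for v in sorted(parents, key=lambda x: -_depth(parents, x)):
            subtree[parents[v]] += subtree[v]
        for v in parents:  # source excluded from its own tree's scoring
            if subtree[v] > threshold:
                out[v] += 1.0
    return out


def _depth(parents: dict, v) -> int:
    d = 0
    while v in parents:
        v = parents[v]
        d += 1
    return d


def epc_scores(
    g: GeneGraph | nx.Graph, params: MetricParams = MetricParams()
) -> dict[str, float]:
    """Monte-Carlo edge-percolated component size (self excluded)."""
    means, _ = epc_scores_with_se(g, params)
    return means


def epc_scores_with_se(
    g: GeneGraph | nx.Graph, params: MetricParams = MetricParams()
) -> tuple[dict[str, float], dict[str, float]]:
    """EPC means plus Monte-Carlo standard errors of those means."""
    G = as_nx(g)
    nodes = sorted(G.nodes, key=str)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = sorted(tuple(sorted((idx[a], idx[b]))) for a, b in G.edges())
    n = len(nodes)
    rng = np.random.default_rng(params.seed)
    totals = np.zeros(n)
    sq_totals = np.zeros(n)
    reps = params.epc_realizations
    for _ in range(reps):
        if edges:
            keep = rng.random(len(edges)) < params.epc_retention
        else:
            keep = np.zeros(0, dtype=bool)
        # union-find over surviving edges
        parent = np.arange(n)

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (a, b), k in zip(edges, keep):
            if k:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        roots = np.fromiter((find(i) for i in range(n)), dtype=int, count=n)
        _, inverse, counts = np.unique(roots, return_inverse=True, return_counts=True)
        comp_sizes = counts[inverse] - 1  # exclude the node itself
        totals += comp_sizes
        sq_totals += comp_sizes.astype(float) ** 2
    means = totals / reps
    var = np.maximum(sq_totals / reps - means**2, 0.0)
    se = np.sqrt(var / reps)
    return (
        {v: float(means[idx[v]]) for v in nodes},
        {v: float(se[idx[v]]) for v in nodes},
    )


# --------------------------------------------------------------------------

_METRIC_FUNCS: dict[str, Callable] = {
    "degree": degree_scores,
    "clustering_coefficient": clustering_coefficient_scores,
    "mnc": mnc_scores,
    "dmnc": dmnc_scores,
    "mcc": mcc_scores,
    "betweenness": betweenness_scores,
    "stress": stress_scores,
    "closeness": closeness_scores,
    "radiality": radiality_scores,
    "eccentricity": eccentricity_scores,
    "bottleneck": bottleneck_scores,
    "epc": epc_scores,
}

_NEEDS_PARAMS = {"dmnc", "bottleneck", "epc"}


def compute_metric(
    g: GeneGraph | nx.Graph, metric: str, params: MetricParams = MetricParams()
) -> dict[str, float]:
    """Compute one metric by canonical name."""
    if metric not in _METRIC_FUNCS:
        raise KeyError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
    func = _METRIC_FUNCS[metric]
    return func(g, params) if metric in _NEEDS_PARAMS else func(g)


def score_all(
    g: GeneGraph | nx.Graph, params: MetricParams = MetricParams()
) -> MetricScores:
    """All twelve metrics on one graph."""
    scores = {m: compute_metric(g, m, params) for m in METRIC_NAMES}
    return MetricScores(scores=scores, params=params)


def top_k(
    scores: Mapping[str, float],
    k: int,
    source: str = "",
    ascending: bool = False,
) -> RankedGeneSet:
    """Tie-aware top-k: genes tied with the k-th score are all included.

    Sorted by score (descending by default; ``ascending=True`` ranks small
    scores first, e.g. for a centre-first eccentricity ranking), with a
    secondary alphabetical sort for determinism.  Ranks are shared within
    ties (competition ranking).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    items = sorted(
        scores.items(), key=lambda kv: ((kv[1] if ascending else -kv[1]), str(kv[0]))
    )
    if k > len(items):
        logger.warning(
            "top_k: k=%d exceeds the %d scored genes; returning all", k, len(items)
        )
        k = len(items)
    cutoff = items[k - 1][1]
    kept = [kv for kv in items if (kv[1] <= cutoff if ascending else kv[1] >= cutoff)]
    entries: list[tuple[str, float, int]] = []
    rank = 0
    prev: float | None = None
    for i, (gene, score) in enumerate(kept, 1):
        if prev is None or score != prev:
            rank = i
            prev = score
        entries.append((gene, float(score), rank))
    if len(kept) > k:
        logger.warning(
            "top_k(%s): tie expansion, %d genes share the cutoff score (nominal k=%d)",
            source or "scores",
            len(kept),
            k,
        )
    return RankedGeneSet(entries=entries, source=source, nominal_k=k)
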