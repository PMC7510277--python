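"""Hub-gene identification on interaction networks.

Ten node-centrality measures (degree, maximal clique centrality, maximum
neighborhood component, closeness, bottleneck, eccentricity, radiality, edge
percolated component, betweenness, stress) are combined by a rank-based
weighted-average ensemble; the top of the aggregate ranking are the hub
candidates. Definitions follow the conventions of the Cytoscape hub-screening
ecosystem. Path-based scores are computed per connected component; a node in
a singleton component scores 0 under every path-based measure.

Intended for the moderately sized networks of this workflow (up to a few
hundred nodes); maximal-clique enumeration is exact and exponential in the
worst case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .data_io import GeneRanking, InteractionNetwork

__all__ = [
    "ALL_METHODS",
    "CentralityTable",
    "EnsembleRanking",
    "shared_genes",
    "path_centrality",
    "mcc_centrality",
    "mnc_centrality",
    "bottleneck_centrality",
    "epc_centrality",
    "compute_centralities",
    "ensemble_rank",
    "top_hubs",
]

PATH_METHODS = (
    "degree",
    "closeness",
    "betweenness",
    "stress",
    "eccentricity",
    "radiality",
)
ALL_METHODS = (
    "degree",
    "mcc",
    "mnc",
    "closeness",
    "bottleneck",
    "eccentricity",
    "radiality",
    "epc",
    "betweenness",
    "stress",
)


@dataclass
class CentralityTable:
    """Per-method node scores; every node appears in every method's map."""

    methods: list[str]
    scores: dict[str, dict[str, float]]
    higher_is_central: dict[str, bool]

    def __post_init__(self) -> None:
        nodes = None
        for m in self.methods:
            keys = set(self.scores[m])
            if nodes is None:
                nodes = keys
            elif keys != nodes:
                raise ValueError(f"method {m!r} scores a different node set")
            vals = np.array(list(self.scores[m].values()), dtype=float)
            if vals.size and not np.all(np.isfinite(vals)):
                raise ValueError(f"method {m!r} produced non-finite scores")


@dataclass
class EnsembleRanking:
    """Nodes ordered most-central first by weighted mean fractional rank."""

    nodes: list[str]
    aggregate: list[float]
    method_weights: dict[str, float]


def shared_genes(rankA: GeneRanking, rankB: GeneRanking, k: int) -> list[str]:
    """Genes in the top-k of both rankings, ordered by summed rank (best first)."""
    if not 1 <= k <= min(len(rankA), len(rankB)):
        raise ValueError(f"k={k} out of range for rankings of length "
                         f"{len(rankA)} and {len(rankB)}")
    topA = {g: r for r, g in enumerate(rankA.gene_ids[:k], start=1)}
    topB = {g: r for r, g in enumerate(rankB.gene_ids[:k], start=1)}
    common = set(topA) & set(topB)
    return sorted(common, key=lambda g: (topA[g] + topB[g], g))


def _components(g: nx.Graph) -> list[set]:
    return [set(c) for c in nx.connected_components(g)]


def path_centrality(net: InteractionNetwork, method: str) -> dict[str, float]:
    """Shortest-path-based centralities, computed per connected component.

    degree: neighbor count. closeness: 1 / sum of distances within the node's
    component. betweenness: unnormalized shortest-path load. stress: number of
    shortest paths passing through the node. eccentricity: 1 / max distance
    (higher = more central). radiality: sum over component peers of
    (component diameter + 1 - distance) / (component size - 1).
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if method == "degree":
        return {v: float(d) for v, d in g.degree()}
    if method == "betweenness":
        return {
            v: float(b)
            for v, b in nx.betweenness_centrality(g, normalized=False).items()
        }
    if method == "stress":
        return _stress(g)
    if method not in PATH_METHODS:
        raise ValueError(f"unknown method {method!r}")

    out: dict[str, float] = {}
    for comp in _components(g):
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        sub = g.subgraph(comp)
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dist.values())
        n = len(comp)
        for v in comp:
            dv = dist[v]
            if method == "closeness":
                out[v] = 1.0 / sum(dv.values())
            elif method == "eccentricity":
                out[v] = 1.0 / max(dv.values())
            elif method == "radiality":
                out[v] = sum(diam + 1 - d for w, d in dv.items() if w != v) / (n - 1)
    return out


def _stress(g: nx.Graph) -> dict[str, float]:
    """Stress(v) = number of shortest s-t paths through v (s != v != t),
    each unordered pair counted once."""
    nodes = list(g.nodes)
    dist: dict = {}
    sigma: dict = {}
    for s in nodes:
        d, sg = _bfs_counts(g, s)
        dist[s] = d
        sigma[s] = sg
    stress = {v: 0.0 for v in nodes}
    for v in nodes:
        for i, s in enumerate(nodes):
            if s == v or v not in dist[s]:
                continue
            for t in nodes[i + 1:]:
                if t == v or t not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    stress[v] += sigma[s][v] * sigma[v][t]
    return stress


def _bfs_counts(g: nx.Graph, s) -> tuple[dict, dict]:
    """BFS distances and shortest-path counts from s."""
    dist = {s: 0}
    sigma = {s: 1}
    queue = [s]
    while queue:
        nxt = []
        for u in queue:
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0
                    nxt.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        queue = nxt
    return dist, sigma


def mcc_centrality(net: InteractionNetwork) -> dict[str, float]:
    """Maximal clique centrality: MCC(v) = sum over maximal cliques C
    containing v (|C| >= 2) of (|C| - 1)!. Isolated nodes score 0."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    out = {v: 0.0 for v in g.nodes}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += w
    return out


def mnc_centrality(net: InteractionNetwork) -> dict[str, float]:
    """Maximum neighborhood component: size of the largest connected component
    of the subgraph induced by v's neighbors (v excluded)."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        out[v] = float(max(len(c) for c in nx.connected_components(sub)))
    return out


def bottleneck_centrality(net: InteractionNetwork) -> dict[str, float]:
    """BottleNeck score via breadth-first shortest-path trees.

    For each root r one BFS tree is built (deterministic: each node's parent
    is its lowest-id predecessor on a shortest path). A node w != r earns one
    point from root r when the number of tree nodes whose tree path to r
    passes through w — w's strict descendants — exceeds a quarter of the
    component size.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    score = {v: 0.0 for v in g.nodes}
    for comp in _components(g):
        n = len(comp)
        if n == 1:
            continue
        sub = g.subgraph(comp)
        for r in comp:
            dist, _ = _bfs_counts(sub, r)
            parent = {}
            for w in comp:
                if w == r:
                    continue
                preds = [u for u in sub.neighbors(w) if dist[u] == dist[w] - 1]
                parent[w] = min(preds)
            desc = {v: 0 for v in comp}  # strict descendants in the tree
            for w in sorted(comp, key=lambda v: -dist[v]):
                if w == r:
                    continue
                desc[parent[w]] += desc[w] + 1
            for w in comp:
                if w != r and desc[w] > n / 4.0:
                    score[w] += 1.0
    return score


def epc_centrality(
    net: InteractionNetwork,
    trials: int = 1000,
    retain_prob: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """Edge percolated component: mean size, over seeded random edge
    percolations (each edge kept with ``retain_prob``), of the component
    containing each node."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0.0 <= retain_prob <= 1.0:
        raise ValueError("retain_prob must be in [0, 1]")
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = list(g.edges)
    rng = np.random.default_rng(seed)
    totals = np.zeros(len(nodes))
    for _ in range(trials):
        if edges:
            keep = rng.random(len(edges)) < retain_prob
            kept = [e for e, k in zip(edges, keep) if k]
        else:
            kept = []
        h = nx.Graph()
        h.add_nodes_from(nodes)
        h.add_edges_from(kept)
        for comp in nx.connected_components(h):
            size = len(comp)
            for v in comp:
                totals[index[v]] += size
    return {v: float(totals[index[v]] / trials) for v in nodes}


def compute_centralities(
    net: InteractionNetwork,
    methods: Sequence[str] = ALL_METHODS,
    epc_trials: int = 1000,
    epc_retain: float = 0.5,
    seed: int = 0,
) -> CentralityTable:
    """Score every node under each requested method."""
    scores: dict[str, dict[str, float]] = {}
    for m in methods:
        if m in PATH_METHODS:
            scores[m] = path_centrality(net, m)
        elif m == "mcc":
            scores[m] = mcc_centrality(net)
        elif m == "mnc":
            scores[m] = mnc_centrality(net)
        elif m == "bottleneck":
            scores[m] = bottleneck_centrality(net)
        elif m == "epc":
            scores[m] = epc_centrality(net, epc_trials, epc_retain, seed)
        else:
            raise ValueError(f"unknown method {m!r}")
    # eccentricity is stored as 1/ecc, so every method is higher-is-central
    return CentralityTable(
        methods=list(methods),
        scores=scores,
        higher_is_central={m: True for m in methods},
    )


def ensemble_rank(
    table: CentralityTable, weights: Mapping[str, float] | None = None
) -> EnsembleRanking:
    """Weighted-average rank ensemble.

    Each method's scores become fractional ranks (most central = 1, ties get
    the average rank; lower-is-central methods are rank-inverted), the
    aggregate is their weighted mean (uniform by default), and nodes are
    ordered by ascending aggregate, ties broken by node id.
    """
    methods = table.methods
    if not methods:
        raise ValueError("no centrality methods in table")
    if weights is None:
        w = {m: 1.0 for m in methods}
    else:
        w = {m: float(weights[m]) for m in methods}
        if any(v < 0 for v in w.values()):
            raise ValueError("method weights must be non-negative")
    total = sum(w.values())
    if total == 0:
        raise ValueError("method weights sum to zero")
    w = {m: v / total for m, v in w.items()}

    nodes = sorted(table.scores[methods[0]])
    agg = np.zeros(len(nodes))
    for m in methods:
        vals = np.array([table.scores[m][v] for v in nodes], dtype=float)
        if table.higher_is_central.get(m, True):
            ranks = rankdata(-vals, method="average")
        else:
            ranks = rankdata(vals, method="average")
        agg += w[m] * ranks
    order = sorted(range(len(nodes)), key=lambda i: (agg[i], nodes[i]))
    return EnsembleRanking(
        nodes=[nodes[i] for i in order],
        aggregate=[float(agg[i]) for i in order],
        method_weights=w,
    )


def top_hubs(ensemble: EnsembleRanking, k: int = 10) -> list[str]:
    """First k nodes of the ensemble ranking."""
    if not 1 <= k <= len(ensemble.nodes):
        raise ValueError(f"k={k} out of range [1, {len(ensemble.nodes)}]")
    return ensemble.nodes[:k]
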