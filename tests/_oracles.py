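"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive pure Python (BFS on adjacency dicts,
exhaustive path and clique enumeration, generic numeric optimizers) and never
calls into mcbfsnw, so the two routes stay independent.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------- graphs

def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_dist(adj, s):
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def components(adj):
    seen = set()
    comps = []
    for v in adj:
        if v in seen:
            continue
        comp = set(bfs_dist(adj, v))
        seen |= comp
        comps.append(comp)
    return comps


def all_shortest_paths(adj, s, t):
    """Every shortest s-t path, as node tuples, by predecessor backtracking."""
    dist = bfs_dist(adj, s)
    if t not in dist:
        return []
    paths = []

    def back(v, suffix):
        if v == s:
            paths.append((s,) + suffix)
            return
        for u in adj[v]:
            if u in dist and dist[u] == dist[v] - 1:
                back(u, (v,) + suffix)

    back(t, ())
    return paths


def oracle_degree(nodes, edges):
    adj = adjacency(nodes, edges)
    return {v: float(len(adj[v])) for v in nodes}


def oracle_closeness(nodes, edges):
    adj = adjacency(nodes, edges)
    out = {}
    for v in nodes:
        dist = bfs_dist(adj, v)
        total = sum(dist.values())
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def oracle_eccentricity(nodes, edges):
    adj = adjacency(nodes, edges)
    out = {}
    for v in nodes:
        ecc = max(bfs_dist(adj, v).values())
        out[v] = 1.0 / ecc if ecc > 0 else 0.0
    return out


def oracle_radiality(nodes, edges):
    adj = adjacency(nodes, edges)
    out = {}
    for comp in components(adj):
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        dists = {v: bfs_dist(adj, v) for v in comp}
        diam = max(max(d.values()) for d in dists.values())
        for v in comp:
            out[v] = sum(
                diam + 1 - d for w, d in dists[v].items() if w != v
            ) / (len(comp) - 1)
    return out


def oracle_betweenness(nodes, edges):
    adj = adjacency(nodes, edges)
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out


def oracle_stress(nodes, edges):
    adj = adjacency(nodes, edges)
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        for p in all_shortest_paths(adj, s, t):
            for v in p[1:-1]:
                out[v] += 1.0
    return out


def oracle_mnc(nodes, edges):
    adj = adjacency(nodes, edges)
    out = {}
    for v in nodes:
        nbrs = adj[v]
        if not nbrs:
            out[v] = 0.0
            continue
        sub = {u: adj[u] & nbrs for u in nbrs}
        out[v] = float(max(len(c) for c in components(sub)))
    return out


def oracle_mcc(nodes, edges):
    """MCC by exhaustive subset enumeration (cliques of size >= 2 only)."""
    nodes = list(nodes)
    eset = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(frozenset(p) in eset for p in itertools.combinations(sub, 2))

    cliques = []
    for r in range(2, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if not is_clique(sub):
                continue
            if any(is_clique(sub + (w,)) for w in nodes if w not in sub):
                continue  # extendable: not maximal
            cliques.append(sub)
    out = {v: 0.0 for v in nodes}
    for c in cliques:
        w = math.factorial(len(c) - 1)
        for v in c:
            out[v] += w
    return out


def random_graph(rng, n_max=7, p_edge=0.45):
    """A random simple graph on 2..n_max string-labeled nodes."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"v{i}" for i in range(n)]
    edges = {
        frozenset((a, b))
        for a, b in itertools.combinations(nodes, 2)
        if rng.random() < p_edge
    }
    return nodes, edges


# ---------------------------------------------------------- optimizers

def solve_w_qp(A, P, delta):
    """Generic numeric minimizer of sum_n P_n sum_k W_k A_nk + delta sum W^2
    subject to sum W = 1 (equality constraint only)."""
    A = np.asarray(A, dtype=float)
    P = np.asarray(P, dtype=float)
    p = A.shape[1]
    T = P @ A

    def f(w):
        return float(T @ w + delta * np.sum(w**2))

    def grad(w):
        return T + 2.0 * delta * w

    res = minimize(
        f, np.full(p, 1.0 / p), jac=grad, method="SLSQP",
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    assert res.success, res.message
    return res.x


def solve_p_entropy(B, rho):
    """Numeric minimizer of <P, B> + rho * sum P log P over the simplex."""
    B = np.asarray(B, dtype=float)
    m = B.shape[0]

    def f(q):
        q = np.clip(q, 1e-300, None)
        return float(B @ q + rho * np.sum(q * np.log(q)))

    def grad(q):
        q = np.clip(q, 1e-300, None)
        return B + rho * (np.log(q) + 1.0)

    res = minimize(
        f, np.full(m, 1.0 / m), jac=grad, method="SLSQP",
        bounds=[(1e-12, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda q: q.sum() - 1.0}],
        options={"ftol": 1e-16, "maxiter": 1000},
    )
    assert res.success, res.message
    return res.x
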