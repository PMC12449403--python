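"""Independent brute-force oracles for the graph measures.

These enumerate simple paths / triples exhaustively (feasible for n <= 7)
and share no code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np

from carenet.networks import ProviderGraph


def undirected_simple_edges(graph: ProviderGraph) -> set[frozenset]:
    return {
        frozenset((u, v)) for (u, v) in graph.edges if u != v
    }


def _all_simple_paths(adj: dict, s: str, t: str) -> list[list[str]]:
    paths = []
    stack = [(s, [s])]
    while stack:
        u, path = stack.pop()
        if u == t:
            paths.append(path)
            continue
        for w in adj[u]:
            if w not in path:
                stack.append((w, path + [w]))
    return paths


def shortest_path_census(graph: ProviderGraph):
    """For every ordered pair: (distance, all shortest simple paths)."""
    nodes = sorted(graph.roles)
    adj = {v: set() for v in nodes}
    for e in undirected_simple_edges(graph):
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    census = {}
    for s, t in itertools.permutations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            census[(s, t)] = (None, [])
            continue
        d = min(len(p) for p in paths) - 1
        census[(s, t)] = (d, [p for p in paths if len(p) - 1 == d])
    return nodes, census


def brute_betweenness(graph: ProviderGraph) -> dict[str, float]:
    nodes, census = shortest_path_census(graph)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    if n < 3:
        return bc
    for s, t in itertools.combinations(nodes, 2):
        d, paths = census[(s, t)]
        if d is None or not paths:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / sigma
    scale = (n - 1) * (n - 2) / 2.0
    return {v: bc[v] / scale for v in nodes}


def brute_closeness(graph: ProviderGraph) -> dict[str, float]:
    nodes, census = shortest_path_census(graph)
    n = len(nodes)
    out = {}
    for v in nodes:
        dists = [
            census[(v, u)][0]
            for u in nodes
            if u != v and census[(v, u)][0] is not None
        ]
        if n <= 1 or not dists:
            out[v] = 0.0
        else:
            r = len(dists)
            out[v] = (r / (n - 1)) * (r / sum(dists))
    return out


def brute_eccentricities(graph: ProviderGraph) -> dict[str, int]:
    nodes, census = shortest_path_census(graph)
    out = {}
    for v in nodes:
        dists = [
            census[(v, u)][0]
            for u in nodes
            if u != v and census[(v, u)][0] is not None
        ]
        out[v] = max(dists) if dists else 0
    return out


def brute_transitivity(graph: ProviderGraph) -> float:
    nodes = sorted(graph.roles)
    edges = undirected_simple_edges(graph)
    triangles = sum(
        1
        for a, b, c in itertools.combinations(nodes, 3)
        if frozenset((a, b)) in edges
        and frozenset((b, c)) in edges
        and frozenset((a, c)) in edges
    )
    triples = 0
    for center in nodes:
        k = sum(1 for e in edges if center in e)
        triples += k * (k - 1) // 2
    return 0.0 if triples == 0 else 3.0 * triangles / triples


def dense_eigenvector(graph: ProviderGraph):
    """Leading eigenvector via numpy's dense symmetric solver, max-scaled.

    Returns None when the dominant eigenvalue is not clearly separated
    (degenerate cases where any normalized eigenvector is non-unique).
    """
    nodes = sorted(graph.roles)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for (u, v), w in graph.edges.items():
        if u == v:
            continue
        A[idx[u], idx[v]] += w
        A[idx[v], idx[u]] += w
    if not A.any():
        return {v: 0.0 for v in nodes}
    vals, vecs = np.linalg.eigh(A)
    if n > 1 and vals[-1] - abs(vals[-2]) < 1e-6:
        return None
    vec = np.abs(vecs[:, -1])
    vec /= vec.max()
    return {v: float(vec[i]) for i, v in enumerate(nodes)}


def random_graph(rng: np.random.Generator, n_max: int = 7) -> ProviderGraph:
    """Random small directed weighted graph for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.15, 0.8))
    g = ProviderGraph(network_id="random")
    g.roles = {f"n{i}": "other" for i in range(n)}
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.edges[(f"n{i}", f"n{j}")] = int(rng.integers(1, 4))
    return g
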