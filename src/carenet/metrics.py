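"""Network measures, implemented from first principles.

Conventions (each the default of the corresponding keyword switch):

* **betweenness, closeness, eccentricity/diameter/radius** are computed on
  the *unweighted undirected* projection of the directed message graph —
  the robust choice for the highly fragmented encounter-level networks,
  where many components are isolated dyads;
* **eigenvector centrality** uses the *weighted undirected* projection and
  is scaled so the maximum entry equals 1;
* **density** is the directed edge count over n(n−1) ordered pairs;
* **global clustering** is transitivity: 3 × triangles / connected triples
  (paths of length 2), on the unweighted undirected projection.

Betweenness follows the pair-dependency accumulation scheme (one BFS per
source, partial dependencies propagated down the shortest-path DAG) and is
normalized by (n−1)(n−2)/2, so a node on every shortest path between all
other pairs of a connected network scores 1. Closeness uses the
reachable-set (Wasserman–Faust) correction so scores of nodes in small
components are comparable across networks. Unreachable pairs contribute
nothing anywhere; distances are within-component only.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import ProviderGraph, undirected_projection


class NumericalError(RuntimeError):
    """An iterative computation failed to converge."""


@dataclass
class NetworkSummary:
    network_id: str
    n_nodes: int
    n_edges: int
    density: float
    diameter: int
    radius: int
    clustering: float
    eccentricities: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Internal indexed views
# ---------------------------------------------------------------------------


def _indexed(graph: ProviderGraph, directed: bool = False):
    """(nodes, adjacency lists) with integer node indices, deterministic order."""
    nodes = graph.nodes  # sorted
    idx = {v: i for i, v in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    if directed:
        seen = set()
        for (u, v) in graph.edges:
            if (u, v) not in seen:
                seen.add((u, v))
                adj[idx[u]].append(idx[v])
    else:
        seen = set()
        for (u, v) in graph.edges:
            a, b = idx[u], idx[v]
            if a == b:
                continue
            if (min(a, b), max(a, b)) not in seen:
                seen.add((min(a, b), max(a, b)))
                adj[a].append(b)
                adj[b].append(a)
    for lst in adj:
        lst.sort()
    return nodes, adj


def _bfs_distances(adj: list[list[int]], source: int) -> dict[int, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------


def betweenness_centrality(
    graph: ProviderGraph, directed: bool = False
) -> dict[str, float]:
    """Normalized shortest-path betweenness; all zeros for n < 3."""
    nodes, adj = _indexed(graph, directed=directed)
    n = len(nodes)
    bc = np.zeros(n)
    if n < 3:
        return {v: 0.0 for v in nodes}
    for s in range(n):
        # single-source shortest paths with path counting
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        stack: list[int] = []
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for v in reversed(stack):
            for u in preds[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    if not directed:
        bc /= 2.0  # each unordered pair visited from both endpoints
        scale = (n - 1) * (n - 2) / 2.0
    else:
        scale = (n - 1) * (n - 2)
    bc /= scale
    return {v: float(bc[i]) for i, v in enumerate(nodes)}


def closeness_centrality(
    graph: ProviderGraph, directed: bool = False
) -> dict[str, float]:
    """Reachable-set-corrected closeness: (|R|/(n−1)) · (|R|/Σ d)."""
    nodes, adj = _indexed(graph, directed=directed)
    n = len(nodes)
    out: dict[str, float] = {}
    for i, v in enumerate(nodes):
        dist = _bfs_distances(adj, i)
        reach = len(dist) - 1
        total = sum(dist.values())
        if n <= 1 or reach == 0 or total == 0:
            out[v] = 0.0
        else:
            out[v] = (reach / (n - 1)) * (reach / total)
    return out


def eigenvector_centrality(
    graph: ProviderGraph,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Leading eigenvector of the weighted undirected adjacency.

    Power iteration from the all-ones vector, with a unit diagonal shift so
    bipartite components cannot oscillate; the result is scaled to max 1.
    Nodes outside the dominant component converge to (near-)zero values.
    An edgeless graph returns all zeros.
    """
    nodes = graph.nodes
    n = len(nodes)
    proj = undirected_projection(graph)
    if not proj:
        return {v: 0.0 for v in nodes}
    idx = {v: i for i, v in enumerate(nodes)}
    rows = np.fromiter((idx[u] for (u, v) in proj), dtype=np.int64, count=len(proj))
    cols = np.fromiter((idx[v] for (u, v) in proj), dtype=np.int64, count=len(proj))
    w = np.fromiter(proj.values(), dtype=np.float64, count=len(proj))

    x = np.ones(n)
    for _ in range(max_iter):
        y = x.copy()  # unit shift: y = (A + I) x
        np.add.at(y, rows, w * x[cols])
        np.add.at(y, cols, w * x[rows])
        y /= y.max()
        residual = float(np.max(np.abs(y - x)))
        x = y
        if residual < tol:
            return {v: float(x[i]) for i, v in enumerate(nodes)}
    raise NumericalError(
        f"eigenvector iteration did not converge in {max_iter} steps "
        f"(residual {residual:.3e})"
    )


# ---------------------------------------------------------------------------
# Whole-network measures
# ---------------------------------------------------------------------------


def eccentricities(graph: ProviderGraph) -> dict[str, int]:
    """Max distance to reachable nodes, per node (undirected, per component)."""
    nodes, adj = _indexed(graph)
    out = {}
    for i, v in enumerate(nodes):
        dist = _bfs_distances(adj, i)
        out[v] = max(dist.values()) if dist else 0
    return out


def network_summary(graph: ProviderGraph) -> NetworkSummary:
    n = graph.n_nodes
    e = graph.n_edges
    density = e / (n * (n - 1)) if n >= 2 else 0.0
    ecc = eccentricities(graph)
    diameter = max(ecc.values()) if ecc else 0
    radius = min(ecc.values()) if ecc else 0
    return NetworkSummary(
        network_id=graph.network_id,
        n_nodes=n,
        n_edges=e,
        density=density,
        diameter=diameter,
        radius=radius,
        clustering=transitivity(graph),
        eccentricities=ecc,
    )


def transitivity(graph: ProviderGraph) -> float:
    """3 × triangles / connected triples on the simple undirected projection."""
    nodes, adj = _indexed(graph)
    nbrs = [set(a) for a in adj]
    triples = sum(len(a) * (len(a) - 1) // 2 for a in nbrs)
    if triples == 0:
        return 0.0
    tri3 = 0  # every triangle counted once per edge, i.e. 3x
    for u in range(len(nodes)):
        for v in nbrs[u]:
            if v > u:
                tri3 += len(nbrs[u] & nbrs[v])
    return tri3 / triples


def average_local_clustering(graph: ProviderGraph) -> float:
    """Mean of per-node local clustering (alternative convention)."""
    nodes, adj = _indexed(graph)
    nbrs = [set(a) for a in adj]
    if not nodes:
        return 0.0
    vals = []
    for u in range(len(nodes)):
        k = len(nbrs[u])
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(len(nbrs[u] & nbrs[v]) for v in nbrs[u]) / 2
        vals.append(links / (k * (k - 1) / 2))
    return float(np.mean(vals))


def degree_frequency(graph: ProviderGraph) -> dict[int, int]:
    """Node counts by degree = distinct in-neighbours + distinct out-neighbours."""
    outs: dict[str, set[str]] = {v: set() for v in graph.roles}
    ins: dict[str, set[str]] = {v: set() for v in graph.roles}
    for (u, v) in graph.edges:
        outs[u].add(v)
        ins[v].add(u)
    freq: dict[int, int] = {}
    for v in graph.roles:
        d = len(outs[v]) + len(ins[v])
        freq[d] = freq.get(d, 0) + 1
    return dict(sorted(freq.items()))


def node_degrees(graph: ProviderGraph) -> dict[str, int]:
    outs: dict[str, set[str]] = {v: set() for v in graph.roles}
    ins: dict[str, set[str]] = {v: set() for v in graph.roles}
    for (u, v) in graph.edges:
        outs[u].add(v)
        ins[v].add(u)
    return {v: len(outs[v]) + len(ins[v]) for v in graph.roles}


def centrality_table(graph: ProviderGraph, directed: bool = False) -> pd.DataFrame:
    """One row per node: degree and the three normalized centralities."""
    bc = betweenness_centrality(graph, directed=directed)
    cc = closeness_centrality(graph, directed=directed)
    ec = eigenvector_centrality(graph)
    deg = node_degrees(graph)
    rows = [
        {
            "network_id": graph.network_id,
            "provider_id": v,
            "role": graph.roles[v],
            "degree": deg[v],
            "betweenness": bc[v],
            "closeness": cc[v],
            "eigenvector": ec[v],
        }
        for v in graph.nodes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "network_id",
            "provider_id",
            "role",
            "degree",
            "betweenness",
            "closeness",
            "eigenvector",
        ],
    )
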