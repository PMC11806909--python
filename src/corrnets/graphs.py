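"""Thresholded signed networks and the seven network statistics.

A network is built from a correlation matrix by keeping every feature pair
whose coefficient passes a magnitude threshold (default |r| >= 0.8,
boundary inclusive, negative correlations included).  Nodes are the edge
endpoints only: features with no strong correlation drop out, which is what
makes the bootstrapped node count an informative statistic rather than the
constant number of features.

All graph algorithms here are implemented from first principles:

* degree centrality: degree / (N - 1), averaged over nodes; its average is
  algebraically identical to density, 2E / (N (N - 1));
* transitivity: 3 * triangles / connected triples (global clustering);
* closeness: Wasserman-Faust component-corrected closeness
  ((k_u - 1)/(N - 1)) * ((k_u - 1) / sum of shortest-path distances within
  u's component of size k_u), so disconnected graphs are well defined;
* betweenness: Brandes' dependency-accumulation algorithm over unweighted
  BFS shortest paths, normalized by (N - 1)(N - 2)/2 per unordered pair
  (equivalently raw ordered-pair dependencies divided by (N - 1)(N - 2)).

Shortest paths are unweighted: an edge is an edge, correlation magnitude
styles the drawing but does not define distances.  Degenerate cases (empty
graph, N <= 2, no connected triples) yield 0 by convention so bootstrap
loops never divide by zero.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .correlate import CorrelationMatrix

__all__ = [
    "EdgeMode",
    "NetworkGraph",
    "NetworkStats",
    "METRIC_NAMES",
    "threshold_graph",
    "graph_metrics",
    "calculate_network_statistics",
    "stats_to_records",
]

EdgeMode = Literal["both", "positive", "negative"]

#: Report order of the seven per-network statistics.
METRIC_NAMES: tuple[str, ...] = (
    "n_edges",
    "n_nodes",
    "avg_degree_centrality",
    "transitivity",
    "avg_closeness",
    "avg_betweenness",
    "density",
)


@dataclass(frozen=True)
class NetworkGraph:
    """Undirected signed weighted graph from a thresholded correlation matrix.

    ``edges`` maps label-sorted node pairs ``(u, v)`` with ``u < v`` to the
    signed correlation weight.  ``nodes`` may include isolated nodes only for
    induced subgraphs produced by rendering filters; threshold graphs never
    contain them.
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float] = field(repr=False)
    threshold: float = 0.8
    mode: EdgeMode = "both"

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(sorted(self.nodes)))
        node_set = set(self.nodes)
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u > v:
                raise ValueError(f"edge key {u, v} not label-sorted")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge {u, v} references unknown node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for (u, v) in self.edges if node in (u, v))

    def degrees(self) -> dict[str, int]:
        deg = {u: 0 for u in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {u: [] for u in self.nodes}
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj


@dataclass(frozen=True)
class NetworkStats:
    """The seven per-network statistics of one bootstrap replicate."""

    n_edges: int
    n_nodes: int
    avg_degree_centrality: float
    transitivity: float
    avg_closeness: float
    avg_betweenness: float
    density: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def threshold_graph(
    matrix: CorrelationMatrix,
    threshold: float = 0.8,
    mode: EdgeMode = "both",
) -> NetworkGraph:
    """Build the signed network of correlations passing the threshold.

    Parameters
    ----------
    matrix : CorrelationMatrix
        Symmetric Spearman matrix.
    threshold : float in (0, 1]
        Magnitude cutoff, boundary inclusive: mode "both" keeps
        |r| >= threshold, "positive" keeps r >= threshold, "negative" keeps
        r <= -threshold.
    mode : {"both", "positive", "negative"}
        Which correlation sign(s) may form edges.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if mode not in ("both", "positive", "negative"):
        raise ValueError(f"unknown mode {mode!r}")

    ids = matrix.feature_ids
    vals = matrix.values
    edges: dict[tuple[str, str], float] = {}
    p = len(ids)
    for i in range(p):
        for j in range(i + 1, p):
            r = vals[i, j]
            if mode == "both":
                keep = abs(r) >= threshold
            elif mode == "positive":
                keep = r >= threshold
            else:
                keep = r <= -threshold
            if keep:
                u, v = sorted((ids[i], ids[j]))
                edges[(u, v)] = float(r)
    nodes = sorted({n for e in edges for n in e})
    return NetworkGraph(tuple(nodes), edges, threshold, mode)


def _bfs(adj: dict[str, list[str]], source: str):
    """Single-source BFS returning visit order, distances, path counts, parents."""
    dist = {source: 0}
    sigma = {source: 1.0}
    parents: dict[str, list[str]] = {source: []}
    order = []
    queue = deque([source])
    while queue:
        u = queue.popleft()
        order.append(u)
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0.0
                parents[w] = []
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
                parents[w].append(u)
    return order, dist, sigma, parents


def graph_metrics(graph: NetworkGraph) -> NetworkStats:
    """Compute the seven statistics of one network.

    Empty graphs yield all-zero statistics; metrics with undefined
    denominators (N <= 2 for betweenness, no connected triples for
    transitivity) are 0.
    """
    nodes = graph.nodes
    n = len(nodes)
    e = graph.n_edges
    if n == 0:
        return NetworkStats(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0)

    deg = graph.degrees()
    adj = graph.adjacency()

    # mean over nodes of degree/(N-1) equals 2E/(N(N-1)) because the integer
    # degree sum is exactly 2E; computing both through the same expression
    # keeps the identity with density exact in floating point too
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0
    avg_degree_centrality = sum(deg.values()) / (n * (n - 1)) if n >= 2 else 0.0

    # transitivity: triangles via common-neighbor counts on each edge
    neighbor_sets = {u: set(vs) for u, vs in adj.items()}
    triangle_thirds = sum(
        len(neighbor_sets[u] & neighbor_sets[v]) for u, v in graph.edges
    )  # each triangle counted once per edge => 3x
    triples = sum(d * (d - 1) // 2 for d in deg.values())
    transitivity = triangle_thirds / triples if triples > 0 else 0.0

    closeness_sum = 0.0
    betweenness = {u: 0.0 for u in nodes}
    for s in nodes:
        order, dist, sigma, parents = _bfs(adj, s)
        # closeness with Wasserman-Faust component correction
        k = len(dist)  # size of s's component
        total = sum(dist.values())
        if k > 1 and total > 0 and n > 1:
            closeness_sum += ((k - 1) / (n - 1)) * ((k - 1) / total)
        # Brandes dependency accumulation
        delta = {u: 0.0 for u in dist}
        for w in reversed(order):
            for u in parents[w]:
                delta[u] += (sigma[u] / sigma[w]) * (1.0 + delta[w])
            if w != s:
                betweenness[w] += delta[w]

    avg_closeness = closeness_sum / n
    if n > 2:
        # raw values accumulate over ordered (s, t) pairs; dividing by
        # (N-1)(N-2) normalizes per unordered pair into [0, 1]
        scale = 1.0 / ((n - 1) * (n - 2))
        avg_betweenness = sum(b * scale for b in betweenness.values()) / n
    else:
        avg_betweenness = 0.0

    return NetworkStats(
        n_edges=e,
        n_nodes=n,
        avg_degree_centrality=avg_degree_centrality,
        transitivity=transitivity,
        avg_closeness=avg_closeness,
        avg_betweenness=avg_betweenness,
        density=density,
    )


def calculate_network_statistics(
    matrices: Sequence[CorrelationMatrix],
    threshold: float = 0.8,
    mode: EdgeMode = "both",
) -> list[NetworkStats]:
    """Threshold each correlation matrix and compute its statistics.

    Returns one :class:`NetworkStats` per input matrix, in order — the
    bootstrap sampling distribution of each statistic when the inputs are
    replicate matrices.
    """
    if len(matrices) == 0:
        raise ValueError("no correlation matrices given")
    return [graph_metrics(threshold_graph(m, threshold, mode)) for m in matrices]


def stats_to_records(stats: Sequence[NetworkStats]) -> list[dict[str, float]]:
    """Long-form records (replicate index + seven metrics) for CSV export."""
    return [{"replicate": i, **s.as_dict()} for i, s in enumerate(stats)]
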