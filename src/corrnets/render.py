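"""Deterministic signed-network visualization and node-connectivity reports.

Figures follow the field's signed-network conventions: sky-blue nodes, blue
edges for positive correlations, red for negative, edge width proportional
to |r|, written as SVG.  The layout is a seeded force-directed embedding so
identical inputs produce identical geometry.  Every node and edge element
carries an SVG group id (``node-<label>``, ``edge-<u>--<v>``) so rendered
counts can be verified programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd
from matplotlib.lines import Line2D

from .correlate import CorrelationMatrix, average_correlation
from .graphs import EdgeMode, NetworkGraph, threshold_graph

__all__ = [
    "RenderSpec",
    "build_network_graph",
    "top_nodes",
    "most_connected_nodes",
    "nodes_edges_table",
    "top_nodes_network_graph",
]


@dataclass(frozen=True)
class RenderSpec:
    """Visual style of a network figure.

    Edge width maps linearly from the threshold to |r| = 1:
    ``w = w_min + (w_max - w_min) * (|r| - threshold) / (1 - threshold)``.
    """

    node_color: str = "skyblue"
    positive_edge_color: str = "blue"
    negative_edge_color: str = "red"
    edge_width_min: float = 0.5
    edge_width_max: float = 4.0
    node_size: float = 300.0
    layout_seed: int = 7
    figsize: tuple[float, float] = (8.0, 8.0)

    def edge_width(self, weight: float, threshold: float) -> float:
        if threshold >= 1.0:
            return self.edge_width_max
        frac = (abs(weight) - threshold) / (1.0 - threshold)
        return self.edge_width_min + (self.edge_width_max - self.edge_width_min) * max(
            0.0, min(1.0, frac)
        )


def _as_average(matrices) -> CorrelationMatrix:
    if isinstance(matrices, CorrelationMatrix):
        return matrices
    return average_correlation(list(matrices))


def _prune_by_max_degree(graph: NetworkGraph, max_degree: int) -> NetworkGraph:
    """Keep nodes with degree <= max_degree (on the unpruned graph), take the
    induced subgraph, and drop nodes the pruning left isolated."""
    deg = graph.degrees()
    keep = {u for u, d in deg.items() if d <= max_degree}
    edges = {(u, v): w for (u, v), w in graph.edges.items() if u in keep and v in keep}
    nodes = sorted({n for e in edges for n in e})
    return NetworkGraph(tuple(nodes), edges, graph.threshold, graph.mode)


def _draw(graph: NetworkGraph, spec: RenderSpec, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    pos = nx.spring_layout(g, seed=spec.layout_seed) if graph.n_nodes else {}

    with plt.rc_context({"svg.hashsalt": "corrnets"}):
        fig, ax = plt.subplots(figsize=spec.figsize)
        ax.set_axis_off()
        for (u, v), w in sorted(graph.edges.items()):
            color = spec.positive_edge_color if w >= 0 else spec.negative_edge_color
            (line,) = ax.plot(
                [pos[u][0], pos[v][0]],
                [pos[u][1], pos[v][1]],
                color=color,
                linewidth=spec.edge_width(w, graph.threshold),
                zorder=1,
            )
            line.set_gid(f"edge-{u}--{v}")
        for u in graph.nodes:
            dot = ax.scatter(
                [pos[u][0]], [pos[u][1]], s=spec.node_size, c=spec.node_color, zorder=2
            )
            dot.set_gid(f"node-{u}")
            ax.annotate(
                u, pos[u], ha="center", va="center", fontsize=7, zorder=3
            )
        legend_handles = [
            Line2D([], [], color=spec.positive_edge_color, label="positive correlation"),
            Line2D([], [], color=spec.negative_edge_color, label="negative correlation"),
        ]
        ax.legend(handles=legend_handles, loc="upper right", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)


def build_network_graph(
    matrices: CorrelationMatrix | Sequence[CorrelationMatrix],
    threshold: float = 0.8,
    mode: EdgeMode = "both",
    max_degree: int | None = None,
    spec: RenderSpec | None = None,
    path: str | Path | None = None,
) -> tuple[NetworkGraph, Path | None]:
    """Build (and optionally render) a thresholded network.

    A list of correlation matrices is averaged first, so the drawn network
    is the bootstrap-consensus network.  ``max_degree`` removes hub nodes
    whose degree (in the unfiltered network) exceeds the cap, then drops
    nodes left isolated — useful for inspecting the non-hub periphery.
    ``mode`` restricts edges to one correlation sign.

    Returns the (possibly pruned) graph and the SVG path if one was written.
    """
    matrix = _as_average(matrices)
    graph = threshold_graph(matrix, threshold, mode)
    if max_degree is not None:
        graph = _prune_by_max_degree(graph, max_degree)
    written = None
    if path is not None:
        _draw(graph, spec or RenderSpec(), path)
        written = Path(path)
    return graph, written


def top_nodes(graph: NetworkGraph, k: int = 20) -> list[tuple[str, int]]:
    """The (up to) k highest-degree nodes as (node, degree) pairs.

    Sorted by degree descending; ties broken by node label ascending so the
    ordering is total and reproducible.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    deg = graph.degrees()
    ranked = sorted(deg.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


def most_connected_nodes(graph: NetworkGraph) -> tuple[str, int]:
    """The single most connected node (smallest label on ties)."""
    if graph.n_nodes == 0:
        raise ValueError("graph has no nodes")
    return top_nodes(graph, 1)[0]


def nodes_edges_table(graph: NetworkGraph) -> pd.DataFrame:
    """Per-node edge counts; degrees sum to twice the edge count."""
    deg = graph.degrees()
    return pd.DataFrame(
        {"node": list(graph.nodes), "n_edges": [deg[u] for u in graph.nodes]}
    )


def top_nodes_network_graph(
    matrices: CorrelationMatrix | Sequence[CorrelationMatrix],
    threshold: float = 0.8,
    k: int = 20,
    mode: EdgeMode = "both",
    spec: RenderSpec | None = None,
    path: str | Path | None = None,
) -> tuple[NetworkGraph, Path | None]:
    """Render the induced subgraph on the k most connected nodes.

    The full thresholded network is built first; the k highest-degree nodes
    (ties by label) are kept along with every edge internal to them.  Kept
    nodes stay in the figure even if the restriction leaves them isolated.
    """
    matrix = _as_average(matrices)
    full = threshold_graph(matrix, threshold, mode)
    keep = {u for u, _ in top_nodes(full, k)}
    edges = {(u, v): w for (u, v), w in full.edges.items() if u in keep and v in keep}
    sub = NetworkGraph(tuple(sorted(keep)), edges, threshold, mode)
    written = None
    if path is not None:
        _draw(sub, spec or RenderSpec(), path)
        written = Path(path)
    return sub, written
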