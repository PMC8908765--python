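"""Static matplotlib views of the trained map and transition network."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .som import GridSpec

__all__ = [
    "plot_neuron_map",
    "plot_paths",
    "plot_network",
]


def _hex_scatter(ax, grid: GridSpec, values, cmap="viridis", label=None):
    pos = grid.positions
    marker = "h" if grid.topology == "hexagonal" else "s"
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=values, s=380, marker=marker, cmap=cmap)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    if label:
        plt.colorbar(sc, ax=ax, label=label, shrink=0.8)
    return sc


def plot_neuron_map(
    grid: GridSpec, values: np.ndarray, path, title: str = "", label: str | None = None
) -> None:
    """Per-neuron scalar (U-matrix, population, property, cluster id)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    _hex_scatter(ax, grid, values, label=label)
    ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_paths(grid: GridSpec, paths, path, labels=None, title: str = "Pathways") -> None:
    """Per-replica BMU pathways overlaid on the neuron sheet."""
    fig, ax = plt.subplots(figsize=(6, 5))
    pos = grid.positions
    _hex_scatter(ax, grid, np.zeros(grid.n_neurons), cmap="Greys")
    cmap = plt.get_cmap("tab10")
    for i, p in enumerate(paths):
        color = cmap((labels[i] if labels is not None else i) % 10)
        xy = pos[np.asarray(p, dtype=int)]
        jitter = (i % 5 - 2) * 0.03
        ax.plot(xy[:, 0] + jitter, xy[:, 1] + jitter, color=color, alpha=0.6, lw=1.2)
    ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_network(tg, path, seed: int = 0, title: str = "Transition network") -> None:
    """Force-directed layout of the transition graph, seeded for determinism."""
    g = tg.graph
    fig, ax = plt.subplots(figsize=(6, 6))
    layout = nx.spring_layout(g, seed=seed, weight="probability")
    comm = tg.communities or {}
    colors = [comm.get(n, 0) for n in g.nodes]
    nx.draw_networkx_nodes(g, layout, node_color=colors, cmap="tab20", node_size=120, ax=ax)
    nx.draw_networkx_edges(g, layout, ax=ax, alpha=0.3, arrowsize=6)
    nx.draw_networkx_labels(g, layout, font_size=5, ax=ax)
    ax.set_title(title)
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
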