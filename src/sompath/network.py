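"""Transition-network analysis of BMU pathways.

Within-replica frame pairs (t, t+lag) are tallied into a neuron-level
count matrix, row-normalized into an approximate transition matrix P,
and turned into a directed graph whose edges carry both the probability
and a shortest-path cost of −ln P[i, j].  On the graph the package
computes Walktrap communities (on symmetrized count affinities),
eigenvector-centrality community representatives, Brandes betweenness
(on −log costs), and committor probabilities — the probability of
hitting a node set A before a set B — by solving the discrete boundary
value problem of the Markov chain.

No reweighting of biased-simulation counts is performed: quantities
derived from P are kinetically meaningful only for unbiased (or
externally reweighted) sampling; otherwise they indicate barrier
locations rather than rates.  ``transition_matrix`` accepts optional
per-frame weights as a hook for external reweighting schemes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .pathways import PathwaySet
from .som import GridSpec

__all__ = [
    "TransitionModel",
    "TransitionGraph",
    "CommittorResult",
    "transition_matrix",
    "build_graph",
    "detect_communities",
    "community_representatives",
    "betweenness",
    "eigenvector_centrality",
    "committor",
]


@dataclass
class TransitionModel:
    """Lag-τ transition counts and the row-stochastic matrix P."""

    counts: np.ndarray
    P: np.ndarray
    lag: int
    occupied: np.ndarray  # bool mask: neurons with >= 1 outgoing count

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass
class TransitionGraph:
    """Directed transition graph plus analysis annotations."""

    graph: nx.DiGraph
    model: TransitionModel
    communities: dict[int, int] | None = None
    community_representatives: dict[int, int] | None = None
    centralities: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, **d} for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)


def transition_matrix(
    paths: PathwaySet | list[np.ndarray],
    n_states: int,
    lag: int = 1,
    frame_weights: list[np.ndarray] | None = None,
) -> TransitionModel:
    """Count within-replica (t, t+lag) BMU transitions and normalize.

    Pairs spanning a replica boundary are never counted.  Rows with no
    outgoing counts are flagged unoccupied and left at zero rather than
    normalized.  ``frame_weights`` (per replica, per source frame)
    weights each observed pair — a hook for bias reweighting; by default
    every pair counts 1.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    path_list = paths.paths if isinstance(paths, PathwaySet) else list(paths)
    counts = np.zeros((n_states, n_states))
    for r, p in enumerate(path_list):
        p = np.asarray(p, dtype=int)
        if len(p) <= lag:
            warnings.warn(
                f"replica {r} has {len(p)} frames <= lag {lag}; it contributes "
                "no transitions",
                stacklevel=2,
            )
            continue
        src = p[:-lag]
        dst = p[lag:]
        if frame_weights is not None:
            w = np.asarray(frame_weights[r], dtype=float)[: len(src)]
        else:
            w = np.ones(len(src))
        np.add.at(counts, (src, dst), w)
    out_tot = counts.sum(axis=1)
    occupied = out_tot > 0
    P = np.zeros_like(counts)
    P[occupied] = counts[occupied] / out_tot[occupied, None]
    return TransitionModel(counts=counts, P=P, lag=lag, occupied=occupied)


def build_graph(model: TransitionModel, grid: GridSpec | None = None) -> TransitionGraph:
    """Directed graph on occupied neurons; edge iff P[i, j] > 0.

    Each edge carries ``count``, ``probability`` and ``cost`` = −ln P.
    Self-loops are kept in the matrix and on the graph (marked) but are
    excluded from shortest-path and community computations downstream.
    """
    g = nx.DiGraph()
    pos = grid.positions if grid is not None else None
    for i in np.flatnonzero(model.occupied):
        attrs = {}
        if pos is not None:
            attrs = {"x": float(pos[i, 0]), "y": float(pos[i, 1])}
        g.add_node(int(i), **attrs)
    # nodes that only ever appear as targets still belong to the network
    for i, j in zip(*np.nonzero(model.P)):
        if int(j) not in g:
            attrs = {}
            if pos is not None:
                attrs = {"x": float(pos[j, 0]), "y": float(pos[j, 1])}
            g.add_node(int(j), **attrs)
        g.add_edge(
            int(i),
            int(j),
            count=float(model.counts[i, j]),
            probability=float(model.P[i, j]),
            cost=float(-np.log(model.P[i, j])),
        )
    return TransitionGraph(graph=g, model=model)


def _symmetrized_affinity(tg: TransitionGraph, nodes: list[int]) -> np.ndarray:
    """W = C + Cᵀ on the given nodes, self-loops dropped."""
    idx = {n: i for i, n in enumerate(nodes)}
    C = tg.model.counts[np.ix_(nodes, nodes)]
    W = C + C.T
    np.fill_diagonal(W, 0.0)
    return W


def detect_communities(tg: TransitionGraph, steps: int = 4) -> dict[int, int]:
    """Walktrap community detection (Pons–Latapy).

    Short random walks of length ``steps`` on the symmetrized
    count-weighted graph define node distances that are merged
    agglomeratively; the partition with maximum modularity along the
    merge sequence is returned.  Weakly disconnected components are
    handled independently.  Affinities (counts), not −log costs, weight
    the walks: a high transition probability must mean *closeness* to
    the random walker.
    """
    import igraph as ig

    if tg.graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    membership: dict[int, int] = {}
    next_id = 0
    und = tg.graph.to_undirected()
    for comp in nx.connected_components(und):
        nodes = sorted(comp)
        W = _symmetrized_affinity(tg, nodes)
        if len(nodes) == 1 or W.sum() == 0:
            for n in nodes:
                membership[n] = next_id
            next_id += 1
            continue
        src, dst = np.nonzero(np.triu(W))
        h = ig.Graph(
            n=len(nodes),
            edges=list(zip(src.tolist(), dst.tolist())),
            edge_attrs={"weight": W[src, dst].tolist()},
        )
        dendro = h.community_walktrap(weights="weight", steps=steps)
        clustering = dendro.as_clustering()
        for local, m in enumerate(clustering.membership):
            membership[nodes[local]] = next_id + m
        next_id += len(set(clustering.membership))
    tg.communities = membership
    nx.set_node_attributes(tg.graph, membership, "community")
    return membership


def eigenvector_centrality(
    W: np.ndarray, tol: float = 1e-10, max_iter: int = 100000
) -> np.ndarray:
    """Principal-eigenvector scores of a symmetric affinity matrix.

    Power iteration with L2 normalization, converged when successive
    iterates differ by less than ``tol`` in the max norm.  A small
    uniform shift keeps the iteration inside the non-negative cone even
    for bipartite-like structures.
    """
    n = W.shape[0]
    if n == 1:
        return np.ones(1)
    # shift by the largest row sum keeps the dominant eigenvalue simple
    shift = W.sum(axis=1).max()
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        nv = W @ v + shift * v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return np.full(n, 1.0 / np.sqrt(n))
        nv /= norm
        if np.abs(nv - v).max() < tol:
            return nv
        v = nv
    return v


def community_representatives(tg: TransitionGraph) -> dict[int, int]:
    """Highest-eigenvector-centrality node of each community subgraph.

    Centrality is computed on the community-induced subgraph with
    symmetrized probability weights; ties go to the lowest neuron index
    (singleton communities return their node directly).
    """
    if tg.communities is None:
        raise ValueError("run detect_communities first")
    reps: dict[int, int] = {}
    by_comm: dict[int, list[int]] = {}
    for node, c in tg.communities.items():
        by_comm.setdefault(c, []).append(node)
    for c, nodes in by_comm.items():
        nodes = sorted(nodes)
        if len(nodes) == 1:
            reps[c] = nodes[0]
            continue
        P = tg.model.P[np.ix_(nodes, nodes)]
        W = P + P.T
        np.fill_diagonal(W, 0.0)
        scores = eigenvector_centrality(W)
        reps[c] = nodes[int(np.argmax(scores))]  # argmax -> lowest index on ties
    tg.community_representatives = reps
    return reps


def betweenness(tg: TransitionGraph) -> dict[int, float]:
    """Node betweenness on the directed graph with −log-probability costs.

    Counts, per node, the (fractionally shared) number of all-pairs
    shortest paths through it; high values flag obligate-passage
    conformations.  Self-loops are ignored — they never lie on a
    shortest path.
    """
    g = nx.DiGraph(
        (u, v, d) for u, v, d in tg.graph.edges(data=True) if u != v
    )
    g.add_nodes_from(tg.graph.nodes)
    scores = nx.betweenness_centrality(g, weight="cost", normalized=False)
    tg.centralities["betweenness"] = scores
    nx.set_node_attributes(tg.graph, scores, "betweenness")
    return scores


@dataclass
class CommittorResult:
    """Per-node probability of hitting set A before set B.

    ``q`` is indexed by neuron id; NaN marks nodes from which neither A
    nor B is reachable (the committor is undefined there).
    """

    q: np.ndarray
    A: list[int]
    B: list[int]

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"committor": self.q})
        df.index.name = "neuron"
        df.to_csv(path)


def committor(model: TransitionModel, A, B) -> CommittorResult:
    """Solve q(i) = Σ_j P[i,j] q(j) with q=1 on A and q=0 on B.

    States with no path into A ∪ B get NaN rather than raising: an
    absorbing side basin simply has no defined committor.
    """
    A = sorted(int(a) for a in A)
    B = sorted(int(b) for b in B)
    if not A or not B:
        raise ValueError("A and B must be non-empty")
    if set(A) & set(B):
        raise ValueError("A and B must be disjoint")
    n = model.n_states
    occ = np.flatnonzero(model.occupied)
    for s in A + B:
        if not (0 <= s < n):
            raise ValueError(f"state {s} out of range")
    q = np.full(n, np.nan)
    q[A] = 1.0
    q[B] = 0.0
    boundary = set(A) | set(B)
    # interior states: occupied, not boundary, and able to reach A ∪ B
    support = nx.DiGraph()
    support.add_nodes_from(range(n))
    src, dst = np.nonzero(model.P)
    support.add_edges_from(zip(src.tolist(), dst.tolist()))
    reaches: set[int] = set()
    rev = support.reverse(copy=False)
    for s in boundary:
        reaches |= nx.descendants(rev, s)
    reaches |= boundary
    interior = [i for i in occ if i not in boundary and i in reaches]
    if interior:
        idx = {s: i for i, s in enumerate(interior)}
        P_II = model.P[np.ix_(interior, interior)]
        rhs = model.P[np.ix_(interior, A)].sum(axis=1)
        from scipy.linalg import solve

        q_int = solve(np.eye(len(interior)) - P_II, rhs)
        q[interior] = np.clip(q_int, 0.0, 1.0)
    return CommittorResult(q=q, A=A, B=B)
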