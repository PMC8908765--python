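"""Per-replica pathway tracing and clustering on the trained map.

Each replica's frame-by-frame BMU sequence is a pathway across the
neuron sheet.  Pathways are compared with one of two metrics on neuron
map positions:

* time-dependent (``td``): mean map distance between the BMUs of
  corresponding frames — appropriate when replicas evolve in lockstep
  (e.g. constant-velocity steered MD).  Unequal lengths are padded by
  repeating the final BMU, treating the end state as persistent.
* time-independent (``ti``): for each frame of one path, the map
  distance to the *closest* BMU of the other path, averaged over frames,
  then symmetrized by the arithmetic mean of the two directions —
  appropriate when replicas evolve at different speeds (e.g. infrequent
  metadynamics).

Pathways are grouped by average-linkage agglomerative clustering of the
resulting distance matrix; the cut (by count or height) is left to the
user, with the dendrogram exported for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .som import BmuAssignment, GridSpec

__all__ = [
    "PathwaySet",
    "trace_paths",
    "path_distance_td",
    "path_distance_ti",
    "path_distance_matrix",
    "cluster_paths",
]


@dataclass
class PathwaySet:
    """Per-replica BMU sequences plus (optionally) pairwise distances."""

    paths: list[np.ndarray]
    grid: GridSpec | None = None
    metric: str | None = None
    distance_matrix: np.ndarray | None = None
    path_tree: np.ndarray | None = None
    path_labels: np.ndarray | None = None
    names: list[str] | None = None

    @property
    def n_replicas(self) -> int:
        return len(self.paths)

    def distances_to_csv(self, path: str | Path) -> None:
        names = self.names or [f"rep{i}" for i in range(self.n_replicas)]
        df = pd.DataFrame(self.distance_matrix, index=names, columns=names)
        df.to_csv(path)


def trace_paths(assign: BmuAssignment) -> PathwaySet:
    """Split the BMU stream at replica boundaries, order preserved."""
    if assign.replicas.total_frames != assign.n_frames:
        raise ValueError("replica lengths inconsistent with frame count")
    paths = []
    start = 0
    for n in assign.replicas.lengths:
        paths.append(assign.bmu[start : start + n].copy())
        start += n
    return PathwaySet(paths=paths, names=assign.replicas.names)


def _check_paths(p1: np.ndarray, p2: np.ndarray) -> None:
    if len(p1) == 0 or len(p2) == 0:
        raise ValueError("paths must be non-empty")


def path_distance_td(
    p1: np.ndarray, p2: np.ndarray, grid: GridSpec, _md: np.ndarray | None = None
) -> float:
    """Time-dependent path distance: mean frame-wise BMU map distance.

    The shorter path is padded by repeating its last BMU.
    """
    _check_paths(p1, p2)
    md = grid.map_distances() if _md is None else _md
    n = max(len(p1), len(p2))
    a = np.concatenate([p1, np.full(n - len(p1), p1[-1], dtype=int)])
    b = np.concatenate([p2, np.full(n - len(p2), p2[-1], dtype=int)])
    return float(md[a, b].mean())


def path_distance_ti(
    p1: np.ndarray, p2: np.ndarray, grid: GridSpec, _md: np.ndarray | None = None
) -> float:
    """Time-independent path distance, symmetrized.

    Directed form d(p→q): mean over frames of p of the minimum map
    distance to any BMU of q.  The returned value is
    (d(p1→p2) + d(p2→p1)) / 2.
    """
    _check_paths(p1, p2)
    md = grid.map_distances() if _md is None else _md
    u1 = np.unique(p1)
    u2 = np.unique(p2)
    d12 = md[np.asarray(p1)[:, None], u2[None, :]].min(axis=1).mean()
    d21 = md[np.asarray(p2)[:, None], u1[None, :]].min(axis=1).mean()
    return float((d12 + d21) / 2.0)


def path_distance_matrix(
    pathset: PathwaySet, grid: GridSpec, metric: str = "ti"
) -> PathwaySet:
    """Fill the replica × replica distance matrix for the chosen metric."""
    if metric not in ("td", "ti"):
        raise ValueError("metric must be 'td' or 'ti'")
    fn = path_distance_td if metric == "td" else path_distance_ti
    md = grid.map_distances()
    n = pathset.n_replicas
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = fn(pathset.paths[i], pathset.paths[j], grid, _md=md)
    pathset.grid = grid
    pathset.metric = metric
    pathset.distance_matrix = dm
    return pathset


def cluster_paths(
    pathset_or_matrix: PathwaySet | np.ndarray,
    k: int | None = None,
    height: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering of the pathway distance matrix.

    Cut the merge tree either at ``k`` clusters or at ``height``; exactly
    one must be given.  Returns ``(labels, linkage_tree)`` and, when a
    :class:`PathwaySet` was passed, stores both on it.
    """
    if isinstance(pathset_or_matrix, PathwaySet):
        pathset = pathset_or_matrix
        if pathset.distance_matrix is None:
            raise ValueError("compute the distance matrix first")
        dm = pathset.distance_matrix
    else:
        pathset = None
        dm = np.asarray(pathset_or_matrix, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be square and symmetric")
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    tree = linkage(squareform(dm, checks=False), method="average")
    if k is not None:
        raw = fcluster(tree, t=k, criterion="maxclust")
    else:
        raw = fcluster(tree, t=height, criterion="distance")
    # renumber labels in order of first appearance for stable output
    mapping: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        labels[i] = mapping[r]
    if pathset is not None:
        pathset.path_tree = tree
        pathset.path_labels = labels
    return labels, tree
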