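"""Grouping trained neurons into a small number of interpretable clusters.

After training, the codebook vectors are clustered by agglomerative
hierarchical clustering (Euclidean distance, complete linkage).  The
cluster count is either user-fixed or picked as the argmax of the mean
silhouette width over a candidate range — 9–15 by default, a window
coarse enough to summarize a binding process without fragmenting the
map.  Representatives are also selected: per occupied neuron, the frame
closest to its codebook vector; per cluster, the member neuron closest
to the population-weighted mean codebook of the cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .io_features import FeatureMatrix
from .som import BmuAssignment, SomModel

__all__ = [
    "NeuronClustering",
    "cluster_neurons",
    "silhouette_select",
    "mean_silhouette_width",
    "silhouette_samples",
    "neuron_representative_frames",
    "cluster_representative_neurons",
]


@dataclass
class NeuronClustering:
    """Cluster labels per neuron plus the merge history behind them."""

    labels: np.ndarray
    k: int
    linkage_tree: np.ndarray
    silhouettes: dict[int, float] | None = None
    representative_frame: np.ndarray | None = None
    representative_neuron: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(np.unique(self.labels)) != self.k:
            raise ValueError("labels must take exactly k distinct values")

    def to_csv(self, path: str | Path, population: np.ndarray | None = None) -> None:
        df = pd.DataFrame({"cluster": self.labels})
        df.index.name = "neuron"
        if population is not None:
            df["population"] = population
        if self.representative_frame is not None:
            df["representative_frame"] = self.representative_frame
        df.to_csv(path)


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    """Renumber cluster ids 0..k-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        out[i] = mapping[r]
    return out


def cluster_neurons(model: SomModel, k: int) -> NeuronClustering:
    """Complete-linkage agglomerative clustering of codebook vectors."""
    n = model.n_neurons
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    tree = linkage(model.codebook, method="complete", metric="euclidean")
    raw = fcluster(tree, t=k, criterion="maxclust")
    return NeuronClustering(labels=_relabel_first_occurrence(raw), k=k, linkage_tree=tree)


def silhouette_samples(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette width per point from a square distance matrix.

    s(i) = (b - a) / max(a, b) with ``a`` the mean distance of point i to
    its own cluster (excluding itself) and ``b`` the smallest mean
    distance to any other cluster.  Points in singleton clusters score 0,
    as does the degenerate 0/0 case of coincident points.
    """
    labels = np.asarray(labels)
    n = len(labels)
    uniq = np.unique(labels)
    out = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            continue  # singleton convention: 0
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        out[i] = 0.0 if denom == 0 else (b - a) / denom
    return out


def mean_silhouette_width(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width of a labelled point set (Euclidean)."""
    dist = squareform(pdist(points))
    return float(silhouette_samples(dist, labels).mean())


def silhouette_select(
    model: SomModel, k_min: int = 9, k_max: int = 15
) -> tuple[int, NeuronClustering]:
    """Pick the cluster count maximizing mean silhouette width.

    Every k in [k_min, k_max] is evaluated on the codebook vectors; ties
    go to the smallest k.  The returned clustering carries the full
    per-k silhouette profile for manual inspection/override.
    """
    n = model.n_neurons
    if not 2 <= k_min <= k_max <= n:
        raise ValueError(f"need 2 <= k_min <= k_max <= {n}")
    tree = linkage(model.codebook, method="complete", metric="euclidean")
    dist = squareform(pdist(model.codebook))
    profile: dict[int, float] = {}
    labellings: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        raw = fcluster(tree, t=k, criterion="maxclust")
        labels = _relabel_first_occurrence(raw)
        labellings[k] = labels
        if len(np.unique(labels)) < 2:
            profile[k] = 0.0
        else:
            profile[k] = float(silhouette_samples(dist, labels).mean())
    best_k = max(profile, key=lambda k: (profile[k], -k))
    clustering = NeuronClustering(
        labels=labellings[best_k],
        k=len(np.unique(labellings[best_k])),
        linkage_tree=tree,
        silhouettes=profile,
    )
    return best_k, clustering


def neuron_representative_frames(
    assign: BmuAssignment, features: FeatureMatrix, model: SomModel
) -> np.ndarray:
    """Per neuron, the assigned frame closest to its codebook vector.

    Float array with NaN for unoccupied neurons; ties go to the earliest
    frame.
    """
    if features.n_frames != assign.n_frames:
        raise ValueError("assignment inconsistent with feature matrix")
    out = np.full(model.n_neurons, np.nan)
    for j in np.unique(assign.bmu):
        frames = np.flatnonzero(assign.bmu == j)
        d = np.sqrt(((features.values[frames] - model.codebook[j]) ** 2).sum(axis=1))
        out[j] = frames[int(np.argmin(d))]  # argmin -> first (earliest) on ties
    return out


def cluster_representative_neurons(
    clustering: NeuronClustering, model: SomModel, population: np.ndarray
) -> np.ndarray:
    """Per cluster, the member neuron nearest the weighted-mean codebook.

    The mean codebook vector of each cluster is weighted by neuron
    population; clusters with zero total population fall back to the
    unweighted mean.  Ties go to the lowest neuron index.
    """
    population = np.asarray(population, dtype=float)
    if population.shape != (model.n_neurons,):
        raise ValueError("population length must equal neuron count")
    reps = np.empty(clustering.k, dtype=int)
    for c in range(clustering.k):
        members = np.flatnonzero(clustering.labels == c)
        w = population[members]
        if w.sum() == 0:
            w = np.ones_like(w)
        mean = (model.codebook[members] * w[:, None]).sum(axis=0) / w.sum()
        d = np.sqrt(((model.codebook[members] - mean) ** 2).sum(axis=1))
        reps[c] = members[int(np.argmin(d))]
    clustering.representative_neuron = reps
    return reps
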