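"""Hexagonal-lattice self-organizing map: training and per-neuron maps.

The map is a Kohonen SOM trained online: each cycle presents every frame
in a fresh random permutation; the best matching unit (BMU) and its grid
neighbourhood move toward the input, with learning rate and neighbourhood
radius decaying linearly over the run.  Neurons are indexed row-major
from the bottom-left corner of the sheet.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import train_epoch
from .io_features import FeatureMatrix, ReplicaIndex

__all__ = [
    "GridSpec",
    "SomModel",
    "BmuAssignment",
    "make_grid",
    "train_som",
    "find_bmu",
    "map_frames",
    "neighbor_distance_map",
    "neuron_population",
    "average_property_map",
]

_SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the 2-D neuron sheet.

    Hexagonal convention: the neuron in column ``c`` of row ``r`` sits at
    map position ``(c + 0.5*(r % 2), r*sqrt(3)/2)``, so nearest neighbours
    are exactly 1 map unit apart.  Rectangular grids use integer lattice
    positions.  With ``periodic`` set, map distances are computed under
    minimum-image wrapping (the sheet becomes a torus).
    """

    rows: int
    cols: int
    topology: str = "hexagonal"
    periodic: bool = False

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid needs at least 2 rows and 2 columns")
        if self.topology not in ("hexagonal", "rectangular"):
            raise ValueError(f"unsupported topology: {self.topology!r}")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    @property
    def positions(self) -> np.ndarray:
        """(n_neurons, 2) map coordinates, neuron index = row*cols + col."""
        r, c = np.divmod(np.arange(self.n_neurons), self.cols)
        if self.topology == "hexagonal":
            x = c + 0.5 * (r % 2)
            y = r * _SQRT3_2
        else:
            x = c.astype(float)
            y = r.astype(float)
        return np.column_stack([x, y])

    def map_distances(self) -> np.ndarray:
        """Pairwise Euclidean map distances between all neurons."""
        pos = self.positions
        if not self.periodic:
            diff = pos[:, None, :] - pos[None, :, :]
            return np.sqrt((diff**2).sum(-1))
        # minimum image over the 9 periodic copies of the sheet
        if self.topology == "hexagonal":
            ax = np.array([self.cols, 0.0])
            ay = np.array([0.5 * (self.rows % 2), self.rows * _SQRT3_2])
        else:
            ax = np.array([self.cols, 0.0])
            ay = np.array([0.0, self.rows])
        best = np.full((self.n_neurons, self.n_neurons), np.inf)
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                shifted = pos + i * ax + j * ay
                diff = shifted[:, None, :] - pos[None, :, :]
                d = np.sqrt((diff**2).sum(-1))
                np.minimum(best, d, out=best)
        return best


def make_grid(
    rows: int, cols: int, topology: str = "hexagonal", periodic: bool = False
) -> GridSpec:
    """Construct a :class:`GridSpec` (validates arguments)."""
    return GridSpec(rows=rows, cols=cols, topology=topology, periodic=periodic)


@dataclass
class SomModel:
    """Trained map: codebook vectors plus grid geometry and run config."""

    grid: GridSpec
    codebook: np.ndarray
    feature_labels: list[str]
    training_config: dict = field(default_factory=dict)
    quantization_error_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[0] != self.grid.n_neurons:
            raise ValueError("codebook row count must equal rows*cols")

    @property
    def n_neurons(self) -> int:
        return self.codebook.shape[0]

    @property
    def n_features(self) -> int:
        return self.codebook.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialize to a zip archive: codebook CSV + JSON metadata."""
        meta = {
            "rows": self.grid.rows,
            "cols": self.grid.cols,
            "topology": self.grid.topology,
            "periodic": self.grid.periodic,
            "training_config": self.training_config,
            "quantization_error_trace": list(map(float, self.quantization_error_trace)),
        }
        df = pd.DataFrame(self.codebook, columns=self.feature_labels)
        df.index.name = "neuron"
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("codebook.csv", df.to_csv())
            zf.writestr("metadata.json", json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SomModel":
        with zipfile.ZipFile(path) as zf:
            with zf.open("codebook.csv") as fh:
                df = pd.read_csv(fh, index_col=0)
            meta = json.loads(zf.read("metadata.json"))
        grid = GridSpec(
            rows=meta["rows"],
            cols=meta["cols"],
            topology=meta["topology"],
            periodic=meta["periodic"],
        )
        return cls(
            grid=grid,
            codebook=df.to_numpy(dtype=float),
            feature_labels=list(df.columns),
            training_config=meta["training_config"],
            quantization_error_trace=np.asarray(meta["quantization_error_trace"]),
        )


@dataclass
class BmuAssignment:
    """Per-frame best-matching-unit annotation."""

    bmu: np.ndarray
    bmu_distance: np.ndarray
    replicas: ReplicaIndex

    def __post_init__(self) -> None:
        self.bmu = np.asarray(self.bmu, dtype=int)
        self.bmu_distance = np.asarray(self.bmu_distance, dtype=float)
        if self.bmu.shape != self.bmu_distance.shape:
            raise ValueError("bmu and bmu_distance must have equal length")
        if self.replicas.total_frames != len(self.bmu):
            raise ValueError("replica lengths must sum to frame count")

    @property
    def n_frames(self) -> int:
        return len(self.bmu)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "replica": self.replicas.replica_of_frame(),
                "bmu": self.bmu,
                "bmu_distance": self.bmu_distance,
            }
        )
        df.index.name = "frame"
        df.to_csv(path)


def _default_schedules(grid: GridSpec, cycles: int, n_frames: int, schedules: dict | None):
    """Per-presentation learning-rate and radius arrays, linear decay.

    Radius starts at 2/3 of the maximum map distance and ends at 0.5 (so
    the final phase updates essentially the BMU alone); learning rate
    decays 0.05 -> 0.01.  Both are overridable via ``schedules`` keys
    ``lr=(start, end)`` and ``radius=(start, end)``.
    """
    schedules = dict(schedules or {})
    lr0, lr1 = schedules.get("lr", (0.05, 0.01))
    max_d = float(grid.map_distances().max())
    r0, r1 = schedules.get("radius", (max_d * 2.0 / 3.0, 0.5))
    total = cycles * n_frames
    t = np.arange(total, dtype=float) / max(total - 1, 1)
    lrs = lr0 + (lr1 - lr0) * t
    radii = r0 + (r1 - r0) * t
    return lrs, radii, {"lr": (lr0, lr1), "radius": (r0, r1)}


def train_som(
    features: FeatureMatrix,
    grid: GridSpec,
    cycles: int = 5000,
    seed: int = 0,
    schedules: dict | None = None,
    init: str = "sample",
) -> SomModel:
    """Train the SOM online over ``cycles`` full passes of the data.

    The codebook is initialized from data rows sampled without
    replacement (``init="sample"``, the default) or uniformly at random
    within the per-feature data range (``init="random"``).  A single seed
    drives initialization and every per-cycle permutation, so the result
    is bit-reproducible for a fixed seed.

    Returns a :class:`SomModel` whose ``quantization_error_trace`` holds
    the mean presented-frame BMU distance of each cycle.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    data = np.ascontiguousarray(features.values, dtype=float)
    n_frames, n_feat = data.shape
    if n_frames == 0:
        raise ValueError("empty feature matrix")
    n_neurons = grid.n_neurons
    if n_frames < n_neurons:
        warnings.warn(
            f"fewer frames ({n_frames}) than neurons ({n_neurons}); "
            "the map will be sparsely populated",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    if init == "sample":
        idx = rng.choice(n_frames, size=n_neurons, replace=n_frames < n_neurons)
        codebook = data[idx].copy()
    elif init == "random":
        lo, hi = data.min(axis=0), data.max(axis=0)
        codebook = rng.uniform(lo, hi, size=(n_neurons, n_feat))
    else:
        raise ValueError(f"unknown init mode: {init!r}")
    codebook = np.ascontiguousarray(codebook)
    map_dist = np.ascontiguousarray(grid.map_distances())
    lrs, radii, sched_used = _default_schedules(grid, cycles, n_frames, schedules)
    qe = np.empty(cycles)
    for c in range(cycles):
        order = np.ascontiguousarray(rng.permutation(n_frames))
        s0 = c * n_frames
        qe[c] = train_epoch(
            codebook,
            data,
            order,
            np.ascontiguousarray(lrs[s0 : s0 + n_frames]),
            np.ascontiguousarray(radii[s0 : s0 + n_frames]),
            map_dist,
        )
    config = {
        "cycles": cycles,
        "seed": seed,
        "init": init,
        "schedules": {k: list(v) for k, v in sched_used.items()},
    }
    return SomModel(
        grid=grid,
        codebook=codebook,
        feature_labels=list(features.feature_labels),
        training_config=config,
        quantization_error_trace=qe,
    )


def find_bmu(vector: np.ndarray, model: SomModel) -> tuple[int, float]:
    """Best matching unit of one feature vector: Euclidean argmin.

    Ties are broken toward the lowest neuron index.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (model.n_features,):
        raise ValueError(
            f"vector length {vector.shape} does not match codebook "
            f"feature count {model.n_features}"
        )
    d2 = ((model.codebook - vector) ** 2).sum(axis=1)
    best = int(np.argmin(d2))
    return best, float(np.sqrt(d2[best]))


def map_frames(features: FeatureMatrix, model: SomModel) -> BmuAssignment:
    """Assign every frame to its BMU (vectorized exhaustive search)."""
    if features.n_features != model.n_features:
        raise ValueError("feature count does not match the trained codebook")
    x = features.values
    # ||x - w||^2 = ||x||^2 - 2 x.w + ||w||^2, computed blockwise
    w2 = (model.codebook**2).sum(axis=1)
    d2 = (x**2).sum(axis=1)[:, None] - 2.0 * x @ model.codebook.T + w2[None, :]
    np.maximum(d2, 0.0, out=d2)
    bmu = np.argmin(d2, axis=1)
    # recompute winning distances directly: the expanded form above can
    # suffer catastrophic cancellation near zero
    dist = np.sqrt(((x - model.codebook[bmu]) ** 2).sum(axis=1))
    return BmuAssignment(bmu=bmu, bmu_distance=dist, replicas=features.replicas)


def neighbor_distance_map(model: SomModel) -> np.ndarray:
    """U-matrix-style summary: mean codebook distance to grid neighbours.

    Neighbours are neurons at map distance <= 1 (+ tolerance), excluding
    the neuron itself; border neurons average over their reduced set.
    Reveals cluster borders as ridges of large values.
    """
    md = model.grid.map_distances()
    neigh = (md <= 1.0 + 1e-9) & (md > 0)
    diff = model.codebook[:, None, :] - model.codebook[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    out = np.empty(model.n_neurons)
    for i in range(model.n_neurons):
        out[i] = dist[i, neigh[i]].mean()
    return out


def neuron_population(assign: BmuAssignment, n_neurons: int) -> np.ndarray:
    """Frames assigned to each neuron (zeros for unoccupied neurons)."""
    return np.bincount(assign.bmu, minlength=n_neurons)


def average_property_map(
    assign: BmuAssignment, values: np.ndarray, n_neurons: int | None = None
) -> np.ndarray:
    """Per-neuron mean of a per-frame scalar (e.g. SMD pulling force).

    Unoccupied neurons are NaN, never zero — a zero average and an empty
    neuron are different things on a property map.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (assign.n_frames,):
        raise ValueError("values length must equal frame count")
    n = n_neurons if n_neurons is not None else int(assign.bmu.max()) + 1
    sums = np.bincount(assign.bmu, weights=values, minlength=n)
    counts = np.bincount(assign.bmu, minlength=n)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out
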