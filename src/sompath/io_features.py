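"""Trajectory coordinate input and intermolecular-distance features.

Coordinates of a pre-selected set of protein and ligand atoms are read
from GROMACS-style ``.xvg`` dumps (one time column followed by x/y/z
triplets per atom, as written by ``gmx traj -ox``) or supplied directly
as arrays.  The feature matrix used for map training is the full set of
pairwise protein-atom/ligand-atom Euclidean distances, optionally capped
so that the unbound state — where all distances are large and noisy —
does not dominate training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoordinateSeries",
    "ReplicaIndex",
    "FeatureMatrix",
    "read_xvg",
    "write_xvg",
    "compute_distances",
    "cartesian_features",
    "apply_cap",
    "concat_features",
]


class MalformedRowError(ValueError):
    """A data row has the wrong number of columns."""


class EmptyInputError(ValueError):
    """The file contains no data rows."""


class SelectionError(ValueError):
    """Protein/ligand atom selection is invalid."""


@dataclass
class CoordinateSeries:
    """Per-frame 3D positions for an ordered atom selection.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian positions.  The distance unit (nm or Å) is carried in
        ``unit`` and never converted implicitly.
    times : ndarray of shape (n_frames,), optional
        Time stamps in ps.
    atom_labels : list of str
        Ordered atom identifiers.
    protein_indices, ligand_indices : sequence of int
        Disjoint partition of the atoms into the receptor set and the
        ligand set.  May be left empty at read time and assigned later
        with :meth:`assign_partition`.
    unit : str
        Distance unit label, default ``"A"`` (Å).
    metadata : list of str
        Retained ``@``-directive lines from an xvg header.
    """

    coords: np.ndarray
    times: np.ndarray | None = None
    atom_labels: list[str] = field(default_factory=list)
    protein_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    ligand_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    unit: str = "A"
    metadata: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise EmptyInputError("coordinate series must contain at least one frame")
        if not self.atom_labels:
            self.atom_labels = [f"atom{i}" for i in range(self.n_atoms)]
        if len(self.atom_labels) != self.n_atoms:
            raise ValueError("atom_labels length must equal atom count")
        self.protein_indices = np.asarray(self.protein_indices, dtype=int)
        self.ligand_indices = np.asarray(self.ligand_indices, dtype=int)
        both = np.concatenate([self.protein_indices, self.ligand_indices])
        if len(np.unique(both)) != len(both):
            raise SelectionError("protein and ligand selections must be disjoint")
        if both.size and (both.min() < 0 or both.max() >= self.n_atoms):
            raise SelectionError("selection index out of range")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def assign_partition(
        self, protein: Sequence[int], ligand: Sequence[int]
    ) -> "CoordinateSeries":
        """Return a copy with the protein/ligand atom partition set."""
        return replace(
            self,
            protein_indices=np.asarray(protein, dtype=int),
            ligand_indices=np.asarray(ligand, dtype=int),
        )


@dataclass
class ReplicaIndex:
    """Frame counts delimiting independent simulation replicas."""

    lengths: list[int]
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.lengths = [int(n) for n in self.lengths]
        if any(n < 1 for n in self.lengths):
            raise ValueError("every replica must contain at least 1 frame")
        if self.names is not None and len(self.names) != len(self.lengths):
            raise ValueError("names length must match lengths")

    @property
    def n_replicas(self) -> int:
        return len(self.lengths)

    @property
    def total_frames(self) -> int:
        return int(sum(self.lengths))

    @property
    def offsets(self) -> np.ndarray:
        """Start offset of each replica in the concatenated frame stream."""
        return np.concatenate([[0], np.cumsum(self.lengths)[:-1]]).astype(int)

    def replica_of_frame(self) -> np.ndarray:
        """Replica id for every frame of the concatenated stream."""
        return np.repeat(np.arange(self.n_replicas), self.lengths)


@dataclass
class FeatureMatrix:
    """Frames × features table feeding SOM training.

    ``values`` holds one row per frame.  When built from
    :func:`compute_distances` the columns are all protein-atom/ligand-atom
    pair distances in row-major (protein, ligand) order; ``cap`` records
    the clamp applied by :func:`apply_cap` (``None`` if uncapped).
    """

    values: np.ndarray
    feature_labels: list[str]
    replicas: ReplicaIndex
    cap: float | None = None
    unit: str = "A"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames × features)")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix must not contain missing values")
        if len(self.feature_labels) != self.values.shape[1]:
            raise ValueError("feature_labels length must match feature count")
        if self.replicas.total_frames != self.values.shape[0]:
            raise ValueError("replica lengths must sum to the frame count")
        if self.cap is not None and self.values.size and self.values.max() > self.cap + 1e-12:
            raise ValueError("values exceed the recorded cap")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write as headered CSV with a frame index and replica column."""
        df = pd.DataFrame(self.values, columns=self.feature_labels)
        df.insert(0, "replica", self.replicas.replica_of_frame())
        df.index.name = "frame"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, cap: float | None = None) -> "FeatureMatrix":
        from itertools import groupby

        df = pd.read_csv(path, index_col=0)
        rep = df.pop("replica").to_list()
        lengths = [len(list(g)) for _, g in groupby(rep)]
        return cls(
            values=df.to_numpy(dtype=float),
            feature_labels=list(df.columns),
            replicas=ReplicaIndex(lengths),
            cap=cap,
        )


def read_xvg(path: str | Path, atoms_per_frame: int) -> CoordinateSeries:
    """Read a GROMACS coordinate dump: time column + 3 columns per atom.

    Lines starting with ``#`` are comments; ``@`` lines are Grace
    directives retained as metadata.  Raises :class:`MalformedRowError`
    naming the offending line when a row's column count is not
    ``1 + 3*atoms_per_frame`` and :class:`EmptyInputError` when no data
    rows are present.
    """
    path = Path(path)
    expected = 1 + 3 * atoms_per_frame
    times: list[float] = []
    rows: list[np.ndarray] = []
    metadata: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.startswith("@"):
                metadata.append(stripped)
                continue
            parts = stripped.split()
            if len(parts) != expected:
                raise MalformedRowError(
                    f"{path.name}:{lineno}: expected {expected} columns "
                    f"(1 time + 3×{atoms_per_frame} coords), got {len(parts)}"
                )
            vals = np.array(parts, dtype=float)
            times.append(vals[0])
            rows.append(vals[1:])
    if not rows:
        raise EmptyInputError(f"{path.name}: no data rows")
    coords = np.asarray(rows).reshape(len(rows), atoms_per_frame, 3)
    return CoordinateSeries(coords=coords, times=np.asarray(times), metadata=metadata)


def write_xvg(series: CoordinateSeries, path: str | Path, fmt: str = "%.8g") -> None:
    """Write a CoordinateSeries in the xvg dialect :func:`read_xvg` consumes."""
    with open(path, "w") as fh:
        fh.write("# written by sompath\n")
        for line in series.metadata:
            fh.write(line + "\n")
        times = (
            series.times
            if series.times is not None
            else np.arange(series.n_frames, dtype=float)
        )
        flat = series.coords.reshape(series.n_frames, -1)
        for t, row in zip(times, flat):
            cols = [fmt % t] + [fmt % v for v in row]
            fh.write("\t".join(cols) + "\n")


def compute_distances(series: CoordinateSeries) -> FeatureMatrix:
    """All protein-atom × ligand-atom Euclidean distances, per frame.

    Feature order is row-major over (protein index, ligand index) and
    identical in every frame.  The result is uncapped; apply
    :func:`apply_cap` afterwards.
    """
    if series.protein_indices.size < 1 or series.ligand_indices.size < 1:
        raise SelectionError("both protein and ligand selections must be non-empty")
    prot = series.coords[:, series.protein_indices, :]  # (F, P, 3)
    lig = series.coords[:, series.ligand_indices, :]  # (F, L, 3)
    diff = prot[:, :, None, :] - lig[:, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))  # (F, P, L)
    values = dist.reshape(series.n_frames, -1)
    labels = [
        f"{series.atom_labels[p]}-{series.atom_labels[l]}"
        for p in series.protein_indices
        for l in series.ligand_indices
    ]
    return FeatureMatrix(
        values=values,
        feature_labels=labels,
        replicas=ReplicaIndex([series.n_frames]),
        unit=series.unit,
    )


def cartesian_features(series: CoordinateSeries) -> FeatureMatrix:
    """Pass-through feature mode: raw ligand-atom Cartesian coordinates.

    An alternative to intermolecular distances for systems where absolute
    position already encodes the process; no distances are computed.
    """
    idx = series.ligand_indices if series.ligand_indices.size else np.arange(series.n_atoms)
    values = series.coords[:, idx, :].reshape(series.n_frames, -1)
    labels = [
        f"{series.atom_labels[a]}.{ax}" for a in idx for ax in ("x", "y", "z")
    ]
    return FeatureMatrix(
        values=values,
        feature_labels=labels,
        replicas=ReplicaIndex([series.n_frames]),
        unit=series.unit,
    )


def apply_cap(matrix: FeatureMatrix, cap: float = 12.0) -> FeatureMatrix:
    """Clamp every distance at ``cap`` (default 12 Å).

    Capping keeps the unbound state — all pair distances large and noisy —
    from dominating training.  Element-wise ``min(v, cap)``; idempotent;
    the input matrix is left unmodified.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    return FeatureMatrix(
        values=np.minimum(matrix.values, cap),
        feature_labels=list(matrix.feature_labels),
        replicas=matrix.replicas,
        cap=float(cap),
        unit=matrix.unit,
    )


def concat_features(
    matrices: Sequence[FeatureMatrix], names: Sequence[str] | None = None
) -> FeatureMatrix:
    """Stack per-replica feature matrices into one with a ReplicaIndex.

    Each input must describe a single replica with identical feature
    labels; caps must agree.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    labels = matrices[0].feature_labels
    for m in matrices[1:]:
        if m.feature_labels != labels:
            raise ValueError("feature labels differ between replicas")
    caps = {m.cap for m in matrices}
    if len(caps) > 1:
        raise ValueError("inconsistent caps between replicas")
    lengths = [m.n_frames for m in matrices]
    return FeatureMatrix(
        values=np.vstack([m.values for m in matrices]),
        feature_labels=list(labels),
        replicas=ReplicaIndex(lengths, list(names) if names is not None else None),
        cap=caps.pop(),
        unit=matrices[0].unit,
    )
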