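"""Synthetic ligand-unbinding trajectories with known pathway structure.

A geometric surrogate for enhanced-sampling unbinding data: a fixed
ring of "protein" atoms surrounds a bound site at the origin, and a
rigid "ligand" is translated along one of two exit channels that share
their bound and unbound endpoints but diverge in between.  Gaussian
positional noise scatters frames around the channel.  There is no force
field and no thermodynamics — the point is ground-truth pathway labels
and bound/unbound endpoints against which every analysis stage can be
validated.

Default geometry: the bound waypoint sits at the origin, the two
channels diverge by 90° and rejoin at radius 20 (feature units), the
protein is 8 atoms on a ring of radius 6 and the ligand a rigid
3-atom triangle.  With the default distance cap of 12 the unbound
portion of every channel is clipped flat, exercising the capping
rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_features import (
    CoordinateSeries,
    FeatureMatrix,
    apply_cap,
    compute_distances,
    concat_features,
)

__all__ = [
    "FunnelSpec",
    "generate_funnel",
    "generate_recrossing",
    "funnel_features",
    "channel_probe_features",
]

_DEFAULT_CHANNELS = (
    # channel 0: exits through +y before bending back to the shared unbound point
    ((0.0, 0.0, 0.0), (7.0, 7.0, 0.0), (14.0, 9.0, 0.0), (20.0, 0.0, 0.0)),
    # channel 1: mirror image through -y
    ((0.0, 0.0, 0.0), (7.0, -7.0, 0.0), (14.0, -9.0, 0.0), (20.0, 0.0, 0.0)),
)


@dataclass
class FunnelSpec:
    """Parameters of the two-channel unbinding surrogate."""

    n_replicas: int = 20
    frames_per_replica: int = 200
    channels: tuple = _DEFAULT_CHANNELS
    channel_assignment: list[int] | None = None  # default: alternating
    noise_sigma: float = 0.5
    n_protein_atoms: int = 8
    n_ligand_atoms: int = 3
    protein_ring_radius: float = 6.0
    ligand_radius: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        chans = [np.asarray(c, dtype=float) for c in self.channels]
        if any(len(c) < 2 for c in chans):
            raise ValueError("every channel needs at least 2 waypoints")
        first = {tuple(c[0]) for c in chans}
        last = {tuple(c[-1]) for c in chans}
        if len(first) != 1 or len(last) != 1:
            raise ValueError("channels must share their bound and unbound endpoints")
        self.channels = tuple(chans)

    @property
    def assignment(self) -> np.ndarray:
        if self.channel_assignment is not None:
            return np.asarray(self.channel_assignment, dtype=int)
        return np.arange(self.n_replicas) % len(self.channels)


def _protein_atoms(spec: FunnelSpec) -> np.ndarray:
    """Fixed receptor atoms: a ring around the bound-state waypoint."""
    ang = 2 * np.pi * np.arange(spec.n_protein_atoms) / spec.n_protein_atoms
    return np.column_stack(
        [
            spec.protein_ring_radius * np.cos(ang),
            spec.protein_ring_radius * np.sin(ang),
            np.zeros_like(ang),
        ]
    )


def _ligand_offsets(spec: FunnelSpec) -> np.ndarray:
    """Rigid ligand geometry: atoms on a small ring in the xy plane."""
    ang = 2 * np.pi * np.arange(spec.n_ligand_atoms) / spec.n_ligand_atoms
    return np.column_stack(
        [
            spec.ligand_radius * np.cos(ang),
            spec.ligand_radius * np.sin(ang),
            np.zeros_like(ang),
        ]
    )


def interpolate_channel(waypoints: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Points along a polyline at given fractions of its arc length."""
    waypoints = np.asarray(waypoints, dtype=float)
    seg = np.sqrt(((np.diff(waypoints, axis=0)) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.asarray(fractions, dtype=float) * cum[-1]
    out = np.empty((len(s), 3))
    for d in range(3):
        out[:, d] = np.interp(s, cum, waypoints[:, d])
    return out


def _series_from_centers(
    centers: np.ndarray, spec: FunnelSpec, rng: np.random.Generator
) -> CoordinateSeries:
    """Assemble frames: fixed protein ring + rigid ligand at noisy centers."""
    n = len(centers)
    prot = _protein_atoms(spec)
    lig_off = _ligand_offsets(spec)
    noisy = centers + rng.normal(0.0, spec.noise_sigma, size=centers.shape)
    coords = np.empty((n, spec.n_protein_atoms + spec.n_ligand_atoms, 3))
    coords[:, : spec.n_protein_atoms, :] = prot[None, :, :]
    coords[:, spec.n_protein_atoms :, :] = noisy[:, None, :] + lig_off[None, :, :]
    labels = [f"P{i}" for i in range(spec.n_protein_atoms)] + [
        f"L{i}" for i in range(spec.n_ligand_atoms)
    ]
    return CoordinateSeries(
        coords=coords,
        times=np.arange(n, dtype=float),
        atom_labels=labels,
        protein_indices=np.arange(spec.n_protein_atoms),
        ligand_indices=spec.n_protein_atoms + np.arange(spec.n_ligand_atoms),
    )


def generate_funnel(spec: FunnelSpec) -> tuple[list[CoordinateSeries], np.ndarray]:
    """One unbinding trajectory per replica plus ground-truth channel labels.

    Each replica moves the ligand bound → unbound along its assigned
    channel at constant arc-length speed; ``noise_sigma`` Gaussian noise
    is added to the rigid-body translation.  Deterministic for a fixed
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = spec.assignment
    if len(labels) != spec.n_replicas:
        raise ValueError("channel_assignment length must equal n_replicas")
    fractions = np.linspace(0.0, 1.0, spec.frames_per_replica)
    series = []
    for r in range(spec.n_replicas):
        centers = interpolate_channel(spec.channels[labels[r]], fractions)
        series.append(_series_from_centers(centers, spec, rng))
    return series, labels.copy()


def generate_recrossing(
    spec: FunnelSpec,
    n_events: int,
    channel_probs: tuple[float, ...] | None = None,
) -> tuple[CoordinateSeries, pd.DataFrame]:
    """One long trajectory with repeated unbinding/rebinding traversals.

    Emulates a single enhanced-sampling run that samples many binding
    and unbinding events: ``n_events`` one-way traversals alternate
    bound→unbound and unbound→bound, each over ``frames_per_replica``
    frames, with the channel of each event drawn from ``channel_probs``
    (uniform by default).  Returns the trajectory and an event log with
    one row per traversal (event, channel, direction).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    probs = (
        np.full(len(spec.channels), 1.0 / len(spec.channels))
        if channel_probs is None
        else np.asarray(channel_probs, dtype=float)
    )
    if len(probs) != len(spec.channels) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("channel_probs must be a distribution over channels")
    rng = np.random.default_rng(spec.seed)
    fractions = np.linspace(0.0, 1.0, spec.frames_per_replica)
    blocks = []
    log = []
    for e in range(n_events):
        ch = int(rng.choice(len(spec.channels), p=probs))
        unbinding = e % 2 == 0
        frac = fractions if unbinding else fractions[::-1]
        blocks.append(interpolate_channel(spec.channels[ch], frac))
        log.append(
            {
                "event": e,
                "channel": ch,
                "direction": "unbinding" if unbinding else "rebinding",
            }
        )
    centers = np.vstack(blocks)
    series = _series_from_centers(centers, spec, rng)
    return series, pd.DataFrame(log)


def channel_probe_features(
    spec: FunnelSpec,
    channel: int,
    fractions: np.ndarray,
    cap: float | None = 12.0,
) -> np.ndarray:
    """Noiseless feature vectors for probe points along one channel.

    Useful for locating the map neurons that represent ordered positions
    along a known pathway (e.g. to order neurons for committor checks):
    each row is the capped protein–ligand distance vector of the rigid
    ligand placed exactly at the given arc-length fraction.
    """
    centers = interpolate_channel(spec.channels[channel], np.asarray(fractions))
    prot = _protein_atoms(spec)
    lig_off = _ligand_offsets(spec)
    out = np.empty((len(centers), spec.n_protein_atoms * spec.n_ligand_atoms))
    for i, c in enumerate(centers):
        lig = c + lig_off
        d = np.sqrt(((prot[:, None, :] - lig[None, :, :]) ** 2).sum(-1))
        out[i] = d.ravel()
    if cap is not None:
        out = np.minimum(out, cap)
    return out


def funnel_features(
    spec: FunnelSpec, cap: float | None = 12.0
) -> tuple[FeatureMatrix, np.ndarray]:
    """Convenience: generate, compute capped distances, stack replicas."""
    series, labels = generate_funnel(spec)
    mats = [compute_distances(s) for s in series]
    fm = concat_features(mats, names=[f"rep{i}" for i in range(len(mats))])
    if cap is not None:
        fm = apply_cap(fm, cap)
    return fm, labels
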