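"""End-to-end protocol runner: features → map → clusters → paths → network.

`run_pipeline` executes the three protocol stages on a validated
:class:`RunConfig` and writes every tabular result, plot and a manifest
to the output directory.  Identical config + seed reproduces identical
numeric outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import plots
from .io_features import (
    FeatureMatrix,
    ReplicaIndex,
    apply_cap,
    cartesian_features,
    compute_distances,
    concat_features,
    read_xvg,
)
from .neuron_clustering import (
    cluster_neurons,
    cluster_representative_neurons,
    neuron_representative_frames,
    silhouette_select,
)
from .network import (
    betweenness,
    build_graph,
    committor,
    community_representatives,
    detect_communities,
    transition_matrix,
)
from .pathways import cluster_paths, path_distance_matrix, trace_paths
from .som import (
    average_property_map,
    make_grid,
    map_frames,
    neighbor_distance_map,
    neuron_population,
    train_som,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A protocol stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a full protocol run."""

    # inputs: either xvg files (one per replica) or a feature CSV
    xvg_files: list[str] = field(default_factory=list)
    atoms_per_frame: int | None = None
    n_protein_atoms: int | None = None
    feature_csv: str | None = None
    replica_lengths: list[int] | None = None
    feature_mode: str = "distances"  # or "cartesian"
    # map
    rows: int = 10
    cols: int = 10
    topology: str = "hexagonal"
    periodic: bool = False
    cycles: int = 5000
    cap: float | None = 12.0
    seed: int = 0
    # clustering
    k: int | None = None
    k_min: int = 9
    k_max: int = 15
    # paths / network
    path_metric: str = "ti"
    path_k: int = 2
    lag: int = 1
    committor_a: list[int] = field(default_factory=list)
    committor_b: list[int] = field(default_factory=list)
    property_file: str | None = None
    outdir: str = "sompath_out"

    def validate(self) -> None:
        if not self.xvg_files and self.feature_csv is None:
            raise ValueError("provide xvg files or a feature CSV")
        for f in list(self.xvg_files) + (
            [self.feature_csv] if self.feature_csv else []
        ) + ([self.property_file] if self.property_file else []):
            if f and not Path(f).exists():
                raise FileNotFoundError(f)
        if self.xvg_files and (self.atoms_per_frame is None or self.n_protein_atoms is None):
            raise ValueError("xvg input needs atoms_per_frame and n_protein_atoms")
        if self.cycles < 1 or self.lag < 1:
            raise ValueError("cycles and lag must be >= 1")
        if self.path_metric not in ("td", "ti"):
            raise ValueError("path_metric must be 'td' or 'ti'")
        if self.feature_mode not in ("distances", "cartesian"):
            raise ValueError("feature_mode must be 'distances' or 'cartesian'")


def _load_features(cfg: RunConfig) -> FeatureMatrix:
    if cfg.feature_csv is not None:
        fm = FeatureMatrix.from_csv(cfg.feature_csv)
        if cfg.replica_lengths:
            fm = FeatureMatrix(
                values=fm.values,
                feature_labels=fm.feature_labels,
                replicas=ReplicaIndex(cfg.replica_lengths),
                cap=fm.cap,
            )
        if cfg.cap is not None and cfg.feature_mode == "distances":
            fm = apply_cap(fm, cfg.cap)
        return fm
    mats = []
    for f in cfg.xvg_files:
        series = read_xvg(f, cfg.atoms_per_frame)
        series = series.assign_partition(
            protein=range(cfg.n_protein_atoms),
            ligand=range(cfg.n_protein_atoms, cfg.atoms_per_frame),
        )
        if cfg.feature_mode == "cartesian":
            mats.append(cartesian_features(series))
        else:
            mats.append(compute_distances(series))
    fm = concat_features(mats, names=[Path(f).stem for f in cfg.xvg_files])
    if cfg.cap is not None and cfg.feature_mode == "distances":
        fm = apply_cap(fm, cfg.cap)
    return fm


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Run stages a (features) → b (map) → c (paths/network); write outputs.

    Returns a dict of the in-memory results keyed by artifact name.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    features = _stage("features")(_load_features)(cfg)
    features.to_csv(out / "features.csv")
    results["features"] = features

    @_stage("training")
    def _train():
        grid = make_grid(cfg.rows, cfg.cols, cfg.topology, cfg.periodic)
        model = train_som(features, grid, cycles=cfg.cycles, seed=cfg.seed)
        assign = map_frames(features, model)
        return grid, model, assign

    grid, model, assign = _train()
    model.save(out / "som_model.zip")
    pd.DataFrame(
        model.codebook, columns=model.feature_labels
    ).rename_axis("neuron").to_csv(out / "codebook.csv")
    assign.to_csv(out / "bmu.csv")
    results["model"], results["assign"] = model, assign

    @_stage("neuron_maps")
    def _maps():
        umatrix = neighbor_distance_map(model)
        population = neuron_population(assign, model.n_neurons)
        pd.DataFrame(
            {"neighbor_distance": umatrix, "population": population}
        ).rename_axis("neuron").to_csv(out / "neuron_maps.csv")
        plots.plot_neuron_map(
            grid, umatrix, out / "umatrix.png", "Neighbor distance", "mean distance"
        )
        plots.plot_neuron_map(
            grid, population, out / "population.png", "Population", "frames"
        )
        return umatrix, population

    umatrix, population = _maps()
    results["umatrix"], results["population"] = umatrix, population

    @_stage("property_map")
    def _property():
        values = np.loadtxt(cfg.property_file)
        prop = average_property_map(assign, values, model.n_neurons)
        pd.DataFrame({"mean_property": prop}).rename_axis("neuron").to_csv(
            out / "property_map.csv"
        )
        plots.plot_neuron_map(
            grid, prop, out / "property_map.png", "Average property", "mean"
        )
        return prop

    if cfg.property_file:
        results["property_map"] = _property()

    @_stage("neuron_clustering")
    def _cluster():
        if cfg.k is not None:
            clustering = cluster_neurons(model, cfg.k)
            chosen = cfg.k
        else:
            chosen, clustering = silhouette_select(model, cfg.k_min, cfg.k_max)
            pd.Series(clustering.silhouettes, name="mean_silhouette").rename_axis(
                "k"
            ).to_csv(out / "silhouette.csv")
        clustering.representative_frame = neuron_representative_frames(
            assign, features, model
        )
        cluster_representative_neurons(clustering, model, population)
        clustering.to_csv(out / "neuron_clusters.csv", population=population)
        pd.DataFrame(
            {"representative_neuron": clustering.representative_neuron}
        ).rename_axis("cluster").to_csv(out / "cluster_representatives.csv")
        plots.plot_neuron_map(
            grid, clustering.labels, out / "clusters.png", f"Neuron clusters (k={chosen})"
        )
        return chosen, clustering

    chosen_k, clustering = _cluster()
    results["clustering"], results["chosen_k"] = clustering, chosen_k

    @_stage("pathways")
    def _paths():
        pathset = trace_paths(assign)
        path_distance_matrix(pathset, grid, metric=cfg.path_metric)
        pathset.distances_to_csv(out / "path_distance.csv")
        labels, tree = cluster_paths(pathset, k=cfg.path_k)
        pd.DataFrame(
            tree, columns=["child_a", "child_b", "height", "size"]
        ).to_csv(out / "path_dendrogram.csv", index=False)
        pd.DataFrame({"path_cluster": labels}).rename_axis("replica").to_csv(
            out / "path_labels.csv"
        )
        plots.plot_paths(grid, pathset.paths, out / "paths.png", labels=labels)
        return pathset

    pathset = _paths()
    results["pathset"] = pathset

    @_stage("network")
    def _network():
        tm = transition_matrix(pathset, n_states=model.n_neurons, lag=cfg.lag)
        pd.DataFrame(tm.counts).to_csv(out / "transition_counts.csv")
        pd.DataFrame(tm.P).to_csv(out / "transition_probability.csv")
        tg = build_graph(tm, grid=grid)
        comm = detect_communities(tg)
        reps = community_representatives(tg)
        btw = betweenness(tg)
        nodes = tg.nodes
        pd.DataFrame(
            {
                "community": [comm[n] for n in nodes],
                "betweenness": [btw[n] for n in nodes],
                "cluster": [int(clustering.labels[n]) for n in nodes],
            },
            index=pd.Index(nodes, name="neuron"),
        ).to_csv(out / "communities.csv")
        pd.DataFrame(
            {"representative_neuron": pd.Series(reps)}
        ).rename_axis("community").sort_index().to_csv(
            out / "community_representatives.csv"
        )
        for n in nodes:
            tg.graph.nodes[n]["cluster"] = int(clustering.labels[n])
            tg.graph.nodes[n]["population"] = int(population[n])
        tg.to_graphml(out / "graph.graphml")
        tg.edge_list().to_csv(out / "edges.csv", index=False)
        plots.plot_network(tg, out / "network.png", seed=cfg.seed)
        return tm, tg

    tm, tg = _network()
    results["transition_model"], results["transition_graph"] = tm, tg

    @_stage("committor")
    def _committor():
        res = committor(tm, cfg.committor_a, cfg.committor_b)
        res.to_csv(out / "committor.csv")
        return res

    if cfg.committor_a and cfg.committor_b:
        results["committor"] = _committor()

    try:
        ver = version("sompath")
    except PackageNotFoundError:  # pragma: no cover
        ver = "unknown"
    manifest = {"config": asdict(cfg), "seed": cfg.seed, "version": ver}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
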