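import numpy as np
import pytest

import sompath as sp
from sompath.io_features import FeatureMatrix, ReplicaIndex

from .oracles import brute_bmu


def feature_matrix(values, lengths=None):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        values=values,
        feature_labels=[f"f{i}" for i in range(values.shape[1])],
        replicas=ReplicaIndex(lengths or [len(values)]),
    )


class TestGrid:
    def test_hexagonal_unit_spacings(self):
        grid = sp.make_grid(4, 4)
        pos = grid.positions
        # same row neighbours
        assert np.linalg.norm(pos[1] - pos[0]) == pytest.approx(1.0)
        # adjacent rows: offset (0.5, sqrt(3)/2) -> unit distance
        assert np.linalg.norm(pos[4] - pos[0]) == pytest.approx(1.0)
        # two rows apart, same column
        assert np.linalg.norm(pos[8] - pos[0]) == pytest.approx(np.sqrt(3))

    def test_rectangular_positions(self):
        grid = sp.make_grid(3, 4, topology="rectangular")
        assert np.array_equal(grid.positions[5], [1, 1])

    def test_positions_unique(self):
        for topo in ("hexagonal", "rectangular"):
            grid = sp.make_grid(5, 7, topology=topo)
            assert len(np.unique(grid.positions, axis=0)) == grid.n_neurons

    def test_periodic_wraps_shorter(self):
        flat = sp.make_grid(6, 6, topology="rectangular")
        torus = sp.make_grid(6, 6, topology="rectangular", periodic=True)
        # opposite corners: far on the sheet, close on the torus
        assert torus.map_distances()[0, 35] < flat.map_distances()[0, 35]
        assert torus.map_distances()[0, 5] == pytest.approx(1.0)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            sp.make_grid(1, 5)
        with pytest.raises(ValueError):
            sp.make_grid(3, 3, topology="triangular")


class TestFindBmu:
    def test_exact_codebook_row(self, small_model):
        _, model, _ = small_model
        idx, d = sp.find_bmu(model.codebook[7], model)
        assert idx == 7
        assert d == 0.0

    def test_tie_breaks_low_index(self):
        grid = sp.make_grid(2, 2)
        model = sp.SomModel(
            grid=grid,
            codebook=np.array([[1.0], [0.0], [0.0], [2.0]]),
            feature_labels=["f"],
        )
        idx, _ = sp.find_bmu(np.array([0.0]), model)
        assert idx == 1

    def test_dimension_mismatch(self, small_model):
        _, model, _ = small_model
        with pytest.raises(ValueError):
            sp.find_bmu(np.zeros(model.n_features + 1), model)

    def test_matches_exhaustive_oracle(self, rng):
        grid = sp.make_grid(10, 10)
        codebook = rng.normal(size=(100, 5))
        model = sp.SomModel(grid=grid, codebook=codebook, feature_labels=list("abcde"))
        for v in rng.normal(size=(100, 5)):
            idx, d = sp.find_bmu(v, model)
            oidx, od = brute_bmu(v, codebook)
            assert idx == oidx
            assert d == pytest.approx(od)


class TestTraining:
    def test_single_vector_fixed_point(self):
        v = np.array([3.0, -1.0, 2.0])
        fm = feature_matrix(np.tile(v, (20, 1)))
        model = sp.train_som(fm, sp.make_grid(3, 3), cycles=50, seed=0)
        assert np.abs(model.codebook - v).max() < 1e-6
        assert model.quantization_error_trace[-1] < 1e-6

    def test_warns_when_fewer_frames_than_neurons(self):
        fm = feature_matrix(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.warns(UserWarning, match="fewer frames"):
            sp.train_som(fm, sp.make_grid(3, 3), cycles=2, seed=0)

    def test_bit_identical_for_fixed_seed(self, small_funnel):
        _, fm, _ = small_funnel
        grid = sp.make_grid(5, 5)
        m1 = sp.train_som(fm, grid, cycles=20, seed=42)
        m2 = sp.train_som(fm, grid, cycles=20, seed=42)
        assert np.array_equal(m1.codebook, m2.codebook)
        assert np.array_equal(m1.quantization_error_trace, m2.quantization_error_trace)

    def test_seed_changes_result(self, small_funnel):
        _, fm, _ = small_funnel
        grid = sp.make_grid(5, 5)
        m1 = sp.train_som(fm, grid, cycles=20, seed=42)
        m2 = sp.train_som(fm, grid, cycles=20, seed=43)
        assert not np.array_equal(m1.codebook, m2.codebook)

    def test_two_separated_clusters_map_to_disjoint_contiguous_regions(self, rng):
        a = rng.normal(0.0, 0.3, size=(150, 4))
        b = rng.normal(20.0, 0.3, size=(150, 4))
        fm = feature_matrix(np.vstack([a, b]))
        grid = sp.make_grid(6, 6)
        model = sp.train_som(fm, grid, cycles=60, seed=7)
        assign = sp.map_frames(fm, model)
        set_a, set_b = set(assign.bmu[:150]), set(assign.bmu[150:])
        assert not set_a & set_b
        # contiguity: each BMU region is connected via map-distance-1 hops
        md = grid.map_distances()
        for region in (set_a, set_b):
            nodes = sorted(region)
            seen = {nodes[0]}
            frontier = [nodes[0]]
            while frontier:
                cur = frontier.pop()
                for other in nodes:
                    if other not in seen and md[cur, other] <= 1.0 + 1e-9:
                        seen.add(other)
                        frontier.append(other)
            assert seen == region

    def test_quantization_error_decreases(self):
        for seed in range(20):
            spec = sp.FunnelSpec(n_replicas=4, frames_per_replica=50, seed=seed)
            fm, _ = sp.funnel_features(spec)
            model = sp.train_som(fm, sp.make_grid(4, 4), cycles=30, seed=seed)
            trace = model.quantization_error_trace
            assert trace[-1] < trace[0]

    def test_invalid_cycles(self, small_funnel):
        _, fm, _ = small_funnel
        with pytest.raises(ValueError):
            sp.train_som(fm, sp.make_grid(3, 3), cycles=0, seed=0)

    def test_random_init_mode(self, small_funnel):
        _, fm, _ = small_funnel
        model = sp.train_som(fm, sp.make_grid(4, 4), cycles=5, seed=0, init="random")
        assert model.codebook.shape == (16, fm.n_features)


class TestMapFrames:
    def test_identity_on_codebook(self, small_model):
        _, model, _ = small_model
        fm = feature_matrix(model.codebook.copy())
        assign = sp.map_frames(fm, model)
        assert np.array_equal(assign.bmu, np.arange(model.n_neurons))
        assert np.allclose(assign.bmu_distance, 0.0)

    def test_single_frame(self, small_model):
        _, model, _ = small_model
        fm = feature_matrix(model.codebook[3:4])
        assign = sp.map_frames(fm, model)
        assert assign.n_frames == 1
        assert assign.bmu[0] == 3

    def test_matches_exhaustive_oracle(self, small_model, rng):
        _, model, _ = small_model
        x = rng.uniform(0, 12, size=(500, model.n_features))
        assign = sp.map_frames(feature_matrix(x), model)
        for i in range(0, 500, 7):
            oidx, od = brute_bmu(x[i], model.codebook)
            assert assign.bmu[i] == oidx
            assert assign.bmu_distance[i] == pytest.approx(od)


class TestNeuronSummaries:
    def test_identical_codebook_gives_zero_umatrix(self):
        grid = sp.make_grid(3, 3)
        model = sp.SomModel(
            grid=grid, codebook=np.ones((9, 2)), feature_labels=["a", "b"]
        )
        assert np.allclose(sp.neighbor_distance_map(model), 0.0)

    def test_2x2_rectangular_hand_computed(self):
        grid = sp.make_grid(2, 2, topology="rectangular")
        model = sp.SomModel(
            grid=grid,
            codebook=np.array([[0.0], [1.0], [2.0], [3.0]]),
            feature_labels=["f"],
        )
        # neighbours at map distance 1: 0-(1,2), 1-(0,3), 2-(0,3), 3-(1,2)
        expect = [(1 + 2) / 2, (1 + 2) / 2, (2 + 1) / 2, (2 + 1) / 2]
        assert np.allclose(sp.neighbor_distance_map(model), expect)

    def test_umatrix_homogeneity(self, small_model):
        _, model, _ = small_model
        doubled = sp.SomModel(
            grid=model.grid,
            codebook=model.codebook * 2,
            feature_labels=model.feature_labels,
        )
        assert np.allclose(
            sp.neighbor_distance_map(doubled), 2 * sp.neighbor_distance_map(model)
        )

    def test_umatrix_feature_permutation_invariant(self, small_model, rng):
        _, model, _ = small_model
        perm = rng.permutation(model.n_features)
        permuted = sp.SomModel(
            grid=model.grid,
            codebook=model.codebook[:, perm],
            feature_labels=[model.feature_labels[i] for i in perm],
        )
        assert np.allclose(
            sp.neighbor_distance_map(permuted), sp.neighbor_distance_map(model)
        )

    def test_population_conserves_and_matches_tally(self, small_model, rng):
        grid, model, assign = small_model
        pop = sp.neuron_population(assign, model.n_neurons)
        assert pop.sum() == assign.n_frames
        for j in range(model.n_neurons):
            assert pop[j] == int((assign.bmu == j).sum())

    def test_population_all_on_one_neuron(self):
        assign = sp.BmuAssignment(
            bmu=np.full(10, 3),
            bmu_distance=np.zeros(10),
            replicas=ReplicaIndex([10]),
        )
        pop = sp.neuron_population(assign, 8)
        assert pop[3] == 10 and pop.sum() == 10

    def test_property_map_mean_and_missing(self):
        assign = sp.BmuAssignment(
            bmu=np.array([0, 0, 2]),
            bmu_distance=np.zeros(3),
            replicas=ReplicaIndex([3]),
        )
        out = sp.average_property_map(assign, np.array([2.0, 4.0, 7.0]), n_neurons=4)
        assert out[0] == pytest.approx(3.0)
        assert np.isnan(out[1]) and np.isnan(out[3])
        assert out[2] == pytest.approx(7.0)

    def test_property_map_matches_groupby(self, small_model, rng):
        _, model, assign = small_model
        vals = rng.normal(size=assign.n_frames)
        out = sp.average_property_map(assign, vals, model.n_neurons)
        for j in range(model.n_neurons):
            mask = assign.bmu == j
            if mask.any():
                assert out[j] == pytest.approx(vals[mask].mean())
            else:
                assert np.isnan(out[j])

    def test_property_map_length_mismatch(self, small_model):
        _, model, assign = small_model
        with pytest.raises(ValueError):
            sp.average_property_map(assign, np.zeros(assign.n_frames + 1))


def test_topology_preserved_on_funnel(small_funnel, small_model, rng):
    """Consecutive frames land closer on the map than random frame pairs."""
    grid, model, assign = small_model
    md = grid.map_distances()
    consec = []
    start = 0
    for n in assign.replicas.lengths:
        b = assign.bmu[start : start + n]
        consec.extend(md[b[:-1], b[1:]])
        start += n
    i = rng.integers(0, assign.n_frames, 2000)
    j = rng.integers(0, assign.n_frames, 2000)
    random_pairs = md[assign.bmu[i], assign.bmu[j]]
    assert np.mean(consec) < np.mean(random_pairs)


def test_model_save_load_round_trip(tmp_path, small_model):
    _, model, _ = small_model
    p = tmp_path / "model.zip"
    model.save(p)
    back = sp.SomModel.load(p)
    assert np.allclose(back.codebook, model.codebook)
    assert back.grid == model.grid
    assert back.feature_labels == model.feature_labels
    assert back.training_config["seed"] == model.training_config["seed"]
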