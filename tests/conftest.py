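import numpy as np
import pytest

import sompath as sp


@pytest.fixture(scope="session")
def small_funnel():
    """Reduced two-channel fixture: 8 replicas × 80 frames, capped distances."""
    spec = sp.FunnelSpec(n_replicas=8, frames_per_replica=80, seed=11)
    features, labels = sp.funnel_features(spec)
    return spec, features, labels


@pytest.fixture(scope="session")
def small_model(small_funnel):
    """A 6×6 hex SOM trained briefly on the small funnel fixture."""
    _, features, _ = small_funnel
    grid = sp.make_grid(6, 6)
    model = sp.train_som(features, grid, cycles=80, seed=5)
    assign = sp.map_frames(features, model)
    return grid, model, assign


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
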