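import numpy as np
import pytest

from eplff.datasets import make_protocol_split
from eplff.network import build_network
from eplff.preprocess import fit_sensor_scale
from eplff.protocols import run_online_protocol
from eplff.synthetic import BatchSpec, DriftState, generate_dataset, make_profiles


@pytest.fixture(scope="session")
def small_profiles():
    """Three well-separated odorant profiles on a 16-sensor array."""
    return make_profiles(3, min_pairwise_angle=30.0, seed=7, labels=["a", "b", "c"])


@pytest.fixture(scope="session")
def small_batch(small_profiles):
    drift = DriftState.fresh(16, noise_relative=0.05)
    return generate_dataset(
        small_profiles,
        [BatchSpec(n_samples=90, batch_id=1)],
        seed=7,
        base_drift=drift,
    )[0]


@pytest.fixture(scope="session")
def small_split(small_batch):
    return make_protocol_split(
        small_batch,
        shots_per_class=1,
        validation_fraction=0.1,
        class_order=["a", "b", "c"],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scale(small_split):
    return fit_sensor_scale(small_split.validation)


@pytest.fixture(scope="session")
def small_online(small_split, small_scale):
    """One small trained network + its online-protocol result (shared;
    read-only for all tests that use it)."""
    net = build_network(16, n_gc=400, seed=7)
    res = run_online_protocol(net, small_split, small_scale, class_order=["a", "b", "c"])
    return net, res


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
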