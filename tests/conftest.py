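import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spikecim as sc
from spikecim.training import TrainConfig, train

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    return sc.NetworkSpec.default()


@pytest.fixture(scope="session")
def random_net(default_spec):
    return sc.build_network(default_spec, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """Small balanced synthetic set with a 4:1 split."""
    return sc.synth_dataset(n_per_class=60, noise_sd=0.05, seed=5)


@pytest.fixture(scope="session")
def small_trained(small_dataset):
    """A briefly trained spiking network (short time window) used as the
    shared subject for quantization / crossbar experiments."""
    spec = sc.NetworkSpec.default(T=12)
    net = sc.build_network(spec, seed=3)
    cfg = TrainConfig(epochs=10, batch_size=25, lr=1e-3, T=12, seed=3)
    net, hist = train(net, small_dataset, cfg)
    assert hist.test_accuracy[-1] > 0.6, "fixture network failed to learn"
    return net


@pytest.fixture(scope="session")
def fixture_beats():
    """Held-out beats for crossbar inference experiments."""
    ds = sc.synth_dataset(n_per_class=25, noise_sd=0.05, seed=17)
    X, y = ds.arrays(None)
    return X, y
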