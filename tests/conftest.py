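import numpy as np
import pytest

from tcpl.config import TrainConfig, small_model_config
from tcpl.meta import meta_train
from tcpl.network import TCPLNetwork
from tcpl.simulate import BenchmarkSpec, make_benchmark_arrays


def numeric_gradient(f, x, eps=1e-6):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f(x)
        x[i] = x0 - eps
        fm = f(x)
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture(scope="session")
def tiny_benchmark():
    """4 subjects, 4 classes, 8 channels, 1-s epochs: fast but structured."""
    spec = BenchmarkSpec(n_subjects=4, n_classes=4, n_channels=8,
                         trials_per_class=12, epoch_s=1.0, subject_jitter=0.3,
                         noise_sigma=0.3, seed=11)
    return make_benchmark_arrays(spec)


@pytest.fixture(scope="session")
def tiny_trained(tiny_benchmark):
    """A briefly meta-trained small model shared by adaptation/loss tests."""
    cfg = small_model_config()
    tc = TrainConfig(batch_episodes=4, max_epochs=2, patience=5,
                     episodes_per_epoch=8, n_shot=3, query_cap=8)
    rng = np.random.default_rng(0)
    first = next(iter(tiny_benchmark.values()))
    net = TCPLNetwork(first.data.shape[1], 4, first.data.shape[2], cfg, rng)
    data = {sid: (s.data, s.labels) for sid, s in tiny_benchmark.items()}
    state = meta_train(data, net, tc, rng)
    return state
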