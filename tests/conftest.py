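import numpy as np
import pytest

from agebend.dataio import ExpressionDataset
from agebend.simulate import SimulationConfig, simulate_dataset


def make_dataset(n_probes=5, n_samples=8, seed=0, ages=None, sex=None,
                 values=None, normalized=True):
    """Small hand-controllable dataset for unit tests."""
    rng = np.random.default_rng(seed)
    if values is not None:
        values = np.asarray(values, dtype=float)
        n_samples = values.shape[1]
    if ages is None:
        ages = np.linspace(30, 86, n_samples)
    ages = np.asarray(ages, dtype=float)
    n_samples = len(ages)
    if sex is None:
        sex = np.array(["female", "male"] * (n_samples // 2 + 1))[:n_samples]
    if values is None:
        values = rng.normal(8.0, 1.0, size=(n_probes, n_samples))
    return ExpressionDataset(
        probe_ids=[f"p{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        ages=ages,
        sex=np.asarray(sex, dtype=object),
        values=np.asarray(values, dtype=float),
        normalized=normalized,
    )


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def two_bend_dataset():
    """Standard simulated study: two bends at 45 and 75, reciprocal signal."""
    cfg = SimulationConfig(seed=42)
    return simulate_dataset(cfg)


@pytest.fixture
def noise_dataset():
    """Pure-noise dataset: no bends, no signal probes."""
    cfg = SimulationConfig(n_probes=500, n_samples=30, bend_ages=(),
                          signal_probes_per_bend=0, seed=7)
    return simulate_dataset(cfg)
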