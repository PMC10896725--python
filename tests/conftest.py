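import numpy as np
import pytest

from gazemem import simulate
from gazemem.dataset import GazeEpoch


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study conditions: 64 trials at 100 Hz."""
    return simulate.SyntheticConfig(n_trials=64, sampling_rate=100.0, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate.generate_dataset(small_config)


@pytest.fixture(scope="session")
def medium_dataset():
    """128 trials at 100 Hz, no artifacts (clean analysis fixture)."""
    cfg = simulate.SyntheticConfig(n_trials=128, sampling_rate=100.0, seed=7,
                                   artifact_rate=0.0)
    return simulate.generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def detectable_injections(log, refractory_ms=100.0):
    """Injected saccades at least one refractory interval after the previous
    injection in the same trial epoch (the ones detection can report)."""
    out = []
    for (_, _), sub in log.sort_values("onset_ms").groupby(["epoch", "trial_id"]):
        last = -np.inf
        for _, r in sub.iterrows():
            if r["onset_ms"] - last >= refractory_ms:
                out.append(r)
                last = r["onset_ms"]
    return out


def make_epoch(xy, time_ms=None, valid=None):
    """Wrap raw arrays in a GazeEpoch."""
    xy = np.asarray(xy, float)
    n, t, _ = xy.shape
    if time_ms is None:
        time_ms = np.arange(t, dtype=float) * 10.0
    if valid is None:
        valid = np.ones((n, t), bool)
    return GazeEpoch(time_ms=np.asarray(time_ms, float), xy=xy,
                     valid=np.asarray(valid, bool), trial_ids=np.arange(n))
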