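import numpy as np
import pytest

import hdemg
from hdemg.simulate import LatencyModel, SimulationParams


@pytest.fixture(scope="session")
def small_layout():
    return hdemg.make_sleeve_layout("small")


@pytest.fixture(scope="session")
def toy_schedule():
    """3 movements x 2 reps, able profile: short but structurally complete."""
    return hdemg.make_cue_schedule(
        ["Hand Close", "Hand Open", "Forearm Supination"], 2, "able", seed=7
    )


@pytest.fixture(scope="session")
def clean_recording(small_layout, toy_schedule):
    """High-SNR, zero-latency recording: labels match activity exactly."""
    params = SimulationParams(
        snr_db=20.0, latency_model=LatencyModel(0.0, 0.0), seed=11
    )
    return hdemg.simulate_emg(toy_schedule, small_layout, params)


@pytest.fixture(scope="session")
def clean_features(clean_recording):
    ft, stats = hdemg.preprocess_recording(clean_recording)
    return ft, stats


def separable_features(n_classes=13, n_per_class=40, n_channels=16, sep=6.0, seed=0):
    """Gaussian class blobs in stacked-feature space, inter-mean distance
    ``sep`` times the noise SD — linearly separable by construction."""
    rng = np.random.default_rng(seed)
    dim = n_channels * 4
    centers = rng.standard_normal((n_classes, dim))
    centers *= sep / np.linalg.norm(centers, axis=1, keepdims=True) * np.sqrt(dim)
    X = np.concatenate(
        [centers[c] + rng.standard_normal((n_per_class, dim)) for c in range(n_classes)]
    )
    y = np.repeat(np.arange(n_classes), n_per_class)
    perm = rng.permutation(y.size)
    return X[perm], y[perm]
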