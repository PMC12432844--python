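import numpy as np
import pytest

from audiencesync import GroupRecording, Recording, SimConfig, simulate_audience


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_group():
    """4 subjects x 4 channels x 150 s at 100 Hz with a delta-band shared
    source; cheap enough for repeated use."""
    cfg = SimConfig(n_subjects=4, n_channels=4, sample_rate=100.0,
                    duration=150.0, snr=1.0, artifact_rate=0.0, seed=7)
    group, truth = simulate_audience(cfg)
    return cfg, group, truth


def make_identical_group(n_subjects=5, n_channels=4, n_samples=4000,
                         rate=250.0, seed=0):
    """All subjects share one realisation: ISC must be exactly 1."""
    x = np.random.default_rng(seed).standard_normal((n_channels, n_samples))
    labels = [f"ch{i}" for i in range(n_channels)]
    recs = [Recording(f"S{i}", list(labels), rate, x.copy())
            for i in range(n_subjects)]
    return GroupRecording(recs, aligned=True)


def make_independent_group(n_subjects=6, n_channels=4, n_samples=30000,
                           rate=250.0, seed=0):
    g = np.random.default_rng(seed)
    labels = [f"ch{i}" for i in range(n_channels)]
    recs = [Recording(f"S{i}", list(labels), rate,
                      g.standard_normal((n_channels, n_samples)))
            for i in range(n_subjects)]
    return GroupRecording(recs, aligned=True)
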