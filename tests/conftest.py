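import numpy as np
import pytest

from eedcl.synthio import GeneratorConfig, generate_dataset, \
    make_subject_profile
from eedcl.types import Recording, Segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_gcfg():
    """Small, fast generator conditions shared across tests."""
    return GeneratorConfig(n_subjects=2, n_classes=2, trials_per_class=3,
                           n_channels=4, duration_s=4.0, fs=64.0,
                           class_effect=2.0, seed=5)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_gcfg):
    return generate_dataset(tiny_gcfg)


@pytest.fixture
def toy_recording():
    rng = np.random.default_rng(0)
    return Recording(samples=rng.normal(size=(4, 512)), fs=128.0,
                     subject_id="S0", trial_id="S0_c0_t0", class_label=0)


@pytest.fixture
def toy_segment():
    rng = np.random.default_rng(1)
    return Segment(samples=rng.normal(size=(4, 256)), fs=64.0,
                   subject_id="S0", trial_id="S0_c0_t0", class_label=0)


def labelled_segments(n_per_class=4, n_subjects=2, n_channels=3, window=64,
                      seed=0):
    """Small synthetic labelled segment pool for pairing/training tests."""
    rng = np.random.default_rng(seed)
    segs = []
    for s in range(n_subjects):
        for c in range(2):
            for k in range(n_per_class):
                segs.append(Segment(
                    samples=rng.normal(size=(n_channels, window)), fs=64.0,
                    t_start=float(k), subject_id=f"S{s}",
                    trial_id=f"S{s}_c{c}_t{k}", class_label=c))
    return segs
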