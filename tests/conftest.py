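import numpy as np
import pytest

from xmodal_affect.synthetic import SimulationConfig, generate_recording


@pytest.fixture(scope="session")
def small_config():
    """Short trials, few channels — enough structure for every stage."""
    return SimulationConfig(
        n_subjects=2, trials_per_subject=8, trial_seconds=12.0, baseline_seconds=2.0,
        eeg_rate=128.0, peri_rate=128.0, n_eeg_channels=4, n_peri_channels=2,
        n_classes=2, effect_size=3.0, noise_sd=1.0, seed=42,
    )


@pytest.fixture(scope="session")
def small_recording(small_config):
    return generate_recording(small_config, subject_id=0, trial_index=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
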