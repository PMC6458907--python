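import numpy as np
import pytest

from painpattern import Mask, SyntheticConfig, generate_dataset


def random_mask(rng, shape=(16, 16, 16), p=0.3, affine=None):
    if affine is None:
        affine = np.eye(4)
    return Mask(rng.random(shape) < p, affine)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def calibration_config(seed, **overrides):
    """Signal-free 12-subject event-related cohort on a ~500-voxel ROI."""
    kw = dict(design="event_related_4mod", n_subjects=12, n_runs=1,
              stimuli_per_run_per_modality=4, grid_shape=(14, 13, 13),
              modality_pattern_amplitude=0.0, shared_intensity_amplitude=0.0,
              subject_pattern_jitter_sd=0.0, noise_sd=1.0, seed=seed)
    kw.update(overrides)
    return SyntheticConfig(**kw)


def pain_signal_config(seed, snr=5.0, **overrides):
    """Pain-specific embedded pattern at the given amplitude/noise ratio."""
    kw = dict(design="event_related_4mod", n_subjects=12, n_runs=1,
              stimuli_per_run_per_modality=4, grid_shape=(14, 13, 13),
              modality_pattern_amplitude={"pain": snr, "touch": 0.0,
                                          "audition": 0.0, "vision": 0.0},
              shared_intensity_amplitude=0.0, noise_sd=1.0, seed=seed)
    kw.update(overrides)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def strong_pain_dataset():
    return generate_dataset(pain_signal_config(seed=777))
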