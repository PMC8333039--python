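import numpy as np
import pytest

from dyslexiscan import SimConfig, simulate_cohort, simulate_trace


@pytest.fixture(scope="session")
def fast_cfg() -> SimConfig:
    """Short-trace configuration for unit tests (not the study conditions)."""
    return SimConfig(
        lr_line_duration_s=(0.3, 0.06),
        fixation_jitter_sd=2.0,
        eye_noise_sd=0.8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(fast_cfg):
    cohort, manifest = simulate_cohort(20, 20, fast_cfg)
    return cohort, manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def noiseless_lr_trace():
    cfg = SimConfig(fixation_jitter_sd=0.0, eye_noise_sd=0.0, seed=5)
    return simulate_trace("LR", cfg, np.random.default_rng(5))
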