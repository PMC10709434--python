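import numpy as np
import pytest

from conceptnav import design, synth


@pytest.fixture(scope="session")
def session_spec():
    """One deterministic full session (8 runs x 48 trials)."""
    return design.generate_session("sub-01", seed=11)


@pytest.fixture(scope="session")
def noiseless_config():
    """Small, noise-free cohort configuration for exact forward checks."""
    return synth.CohortConfig(
        n_subjects=1,
        n_voxels=60,
        noise=synth.NoiseModel(
            white_std=0.0, ar1=0.0, drift_amplitude=0.0, subject_std=0.0
        ),
        simulate_gaze=False,
    )


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_config):
    """A noise-free subject carrying every planted code at default gains."""
    return synth.simulate_subject("sub-01", seed=5, config=noiseless_config)


@pytest.fixture(scope="session")
def planted_subject():
    """One subject at the default (calibrated) noise and gains."""
    cfg = synth.CohortConfig(n_subjects=1, n_voxels=150, simulate_gaze=False)
    return synth.simulate_subject("sub-01", seed=9, config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
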