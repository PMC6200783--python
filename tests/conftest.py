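import numpy as np
import pytest

from choroflow import PhantomParams, generate_phantom_eye, load_reference_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20180)


@pytest.fixture(scope="session")
def reference_cohort():
    """The packaged 61-eye normal cohort."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def default_phantom_eye():
    """One phantom eye at the default study conditions, fixed seed."""
    return generate_phantom_eye(PhantomParams(seed=7))


@pytest.fixture(scope="session")
def noiseless_phantom_eye():
    """Noiseless, gain-1 phantom in the exact-recovery regime
    (choriocapillaris at least twice the luminal signal)."""
    params = PhantomParams(
        noise_sd=0.0, artifact_gain=1.0, cc_intensity=200, lumen_intensity=80, seed=1
    )
    return generate_phantom_eye(params)
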