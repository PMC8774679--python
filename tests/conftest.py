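import numpy as np
import pytest

from eatseg import phantom


@pytest.fixture(scope="session")
def default_subject():
    """One default phantom subject (64x64, 25 frames, noise + bias on)."""
    params = phantom.PhantomParams(seed=4)
    series, labels, systole, diastole = phantom.render_cine(params)
    return params, series, labels, systole, diastole


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject default cohort, shared across tests."""
    return phantom.sample_cohort(6, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
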