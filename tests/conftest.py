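import numpy as np
import pytest

from mrcpbmi.preprocess import filter_chain, make_epochs
from mrcpbmi.synthetic_data import (
    DEFAULT_MODEL_CHANNELS,
    MrcpParams,
    SessionPlan,
    generate_session,
)

MODEL_CHANNELS = list(DEFAULT_MODEL_CHANNELS)


@pytest.fixture(scope="session")
def closed_loop_session():
    """One closed-loop style block: 20 trials, 3 catch, modest jitter."""
    return generate_session(
        SessionPlan(n_blocks=1, trials_per_block=20, catch_per_block=3, rng_seed=42),
        MrcpParams(peak_jitter_sd_s=0.1),
    )


@pytest.fixture(scope="session")
def calibration_epochs():
    """Two calibration blocks (38 trial pairs) at default SNR."""
    session = generate_session(
        SessionPlan(n_blocks=2, trials_per_block=20, catch_per_block=0, rng_seed=7),
        MrcpParams(peak_jitter_sd_s=0.2),
    )
    return make_epochs(filter_chain(session))


@pytest.fixture(scope="session")
def separable_epochs():
    """Low-noise, low-jitter epochs: the classes are nearly separable."""
    session = generate_session(
        SessionPlan(n_blocks=2, trials_per_block=20, catch_per_block=0, rng_seed=21),
        MrcpParams(peak_jitter_sd_s=0.05),
        noise_level_uv=0.5,
    )
    return make_epochs(filter_chain(session))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
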