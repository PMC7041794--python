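import numpy as np
import pytest

from idrens.sampler import SamplerParams, sample_ensemble, excluded_volume_reference
from idrens.sequences import get_variant


@pytest.fixture(scope="session")
def wt_seq():
    return get_variant("WT")


@pytest.fixture(scope="session")
def small_params():
    """Tiny sampling design for fast unit tests: 2 runs x 300 configurations."""
    return SamplerParams.desk_scale(divisor=1000, n_runs=2, base_seed=3)


@pytest.fixture(scope="session")
def wt_ensemble(wt_seq, small_params):
    return sample_ensemble(wt_seq, small_params)


@pytest.fixture(scope="session")
def ev_ensemble(wt_seq, small_params):
    return excluded_volume_reference(wt_seq, small_params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
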