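import numpy as np
import pytest

import ineqdecomp as iq


@pytest.fixture(scope="session")
def schema():
    return iq.default_schema()


@pytest.fixture(scope="session")
def small_wave():
    """One modest synthetic wave shared by cheap tests."""
    return iq.generate_wave(iq.default_baseline_spec(n=2000, seed=11))


@pytest.fixture(scope="session")
def small_results(small_wave, schema):
    return iq.WagstaffModel(small_wave, schema).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
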