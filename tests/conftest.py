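import numpy as np
import pytest

from spinedyn import synthetic_data as sd


@pytest.fixture(scope="session")
def abgc_table():
    """Default abGC layout: 111 cells x 3 layers, seeded."""
    return sd.generate_spine_table(sd.default_abgc_config(seed=7))


@pytest.fixture(scope="session")
def ca1_table():
    return sd.generate_spine_table(sd.default_ca1_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
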