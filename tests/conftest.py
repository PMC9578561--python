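import numpy as np
import pandas as pd
import pytest

from planartox import schema as sc
from planartox.synthetic_screen import make_dilution_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def schema():
    return sc.default_schema()


@pytest.fixture(scope="session")
def quarter_log_series():
    return np.array(make_dilution_series(31.6, 10, 0.25))


def hill(conc, rmax, ec50, h):
    c = np.asarray(conc, dtype=float)
    return rmax * c ** h / (c ** h + ec50 ** h)


@pytest.fixture(scope="session")
def hill_curve():
    return hill
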