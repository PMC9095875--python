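import numpy as np
import pytest

import sccosol as s


@pytest.fixture(scope="session")
def table2():
    return s.load_dataset("builtin:table2")


@pytest.fixture(scope="session")
def constants():
    return s.SubstanceConstants()


@pytest.fixture(scope="session")
def y_exp(table2):
    _, _, _, y = table2.arrays()
    return y


@pytest.fixture(scope="session")
def fast_cfg():
    """Small multistart budget for unit tests; smart starts carry the load."""
    return s.FitConfig(objective="aard", n_starts=4, seed=1)
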