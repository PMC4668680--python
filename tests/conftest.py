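import numpy as np
import pytest

import mchbench as m


@pytest.fixture(scope="session")
def years_grid():
    return np.arange(1990, 2012)


@pytest.fixture(scope="session")
def ring10():
    return m.make_region_graph(10, "ring")


@pytest.fixture(scope="session")
def line3():
    return m.make_region_graph(3, "line")
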