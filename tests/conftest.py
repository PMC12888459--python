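import numpy as np
import pandas as pd
import pytest

from specscreen import tables


@pytest.fixture(scope="session")
def table3():
    return tables.load_fixture("table3")


@pytest.fixture(scope="session")
def table6():
    return tables.load_fixture("table6")


@pytest.fixture(scope="session")
def table8():
    return tables.load_fixture("table8")


@pytest.fixture(scope="session")
def table9():
    return tables.load_fixture("table9")


@pytest.fixture(scope="session")
def published_weights():
    return tables.load_fixture("weights")


@pytest.fixture(scope="session")
def herb_map():
    return tables.load_fixture("herb_map")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_peaks(rng):
    """6-peak × 5-observation positive table for generic operations."""
    areas = pd.DataFrame(
        rng.lognormal(mean=8.0, sigma=0.4, size=(6, 5)),
        index=[f"P{i}" for i in range(1, 7)],
        columns=[f"G{j}" for j in range(1, 6)],
    )
    return tables.PeakTable(areas=areas)
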