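import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def table1_df():
    from fecmap.datasets import load_polymorphism_table

    return load_polymorphism_table()


@pytest.fixture(scope="session")
def table1_polys():
    from fecmap.datasets import table1_polymorphisms

    return table1_polymorphisms()


@pytest.fixture(scope="session")
def table1_records():
    from fecmap.datasets import table1_share_records

    return table1_share_records()
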