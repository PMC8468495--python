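import numpy as np
import pandas as pd
import pytest

from synthfair import DatasetSchema, TabularDataset, make_pair
from synthfair.simulate import asd_like_schema, atus_like_schema, mimic_like_schema


@pytest.fixture(scope="session")
def mimic_schema():
    return mimic_like_schema()


@pytest.fixture(scope="session")
def atus_schema():
    return atus_like_schema()


@pytest.fixture(scope="session")
def asd_schema():
    return asd_like_schema()


@pytest.fixture(scope="session")
def binary_schema():
    return DatasetSchema(protected_attrs=(("gender", ("Male", "Female")),))


@pytest.fixture
def small_frame():
    return pd.DataFrame(
        {
            "gender": ["Male", "Female", "Female", "Male"],
            "age": ["15-24", "75+", "15-24", "75+"],
        }
    )


@pytest.fixture(scope="session")
def two_attr_schema():
    return DatasetSchema(
        protected_attrs=(
            ("gender", ("Male", "Female")),
            ("age", ("15-24", "75+")),
        )
    )


def identity_pair(schema, frame):
    """Pair whose synthetic table is an exact copy of the real table."""
    real = TabularDataset("real", frame.copy(), schema)
    synth = TabularDataset("synthetic", frame.copy(), schema)
    return make_pair(real, synth, schema)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
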