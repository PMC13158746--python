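import numpy as np
import pytest
from hypothesis import settings

from rfeq.catalog import default_catalog
from rfeq.io import RetailerRecord

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_record(
    catalog,
    rid="r0",
    lon=36.88,
    lat=-1.31,
    stratum="urban",
    typology="kiosk",
    gender="female",
    shelf_space="food_100",
    present=(),
):
    """A valid record with the named food groups present."""
    presence = {c: (c in present) for c in catalog.codes}
    return RetailerRecord(
        id=rid,
        lon=lon,
        lat=lat,
        stratum=stratum,
        typology=typology,
        gender=gender,
        shelf_space=shelf_space,
        presence=presence,
    )


@pytest.fixture
def record_factory(catalog):
    return lambda **kw: make_record(catalog, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
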