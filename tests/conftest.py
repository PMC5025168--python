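import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from pgxtranslate import curate, derive_annotation, encode_numeric
from pgxtranslate.examples import tpmt_table, ugt1a5_sample, ugt1a5_table


@pytest.fixture
def ugt1a5_raw():
    return ugt1a5_table()


@pytest.fixture
def ugt1a5(ugt1a5_raw):
    return curate(ugt1a5_raw)


@pytest.fixture
def ugt1a5_encoded(ugt1a5):
    return encode_numeric(ugt1a5)


@pytest.fixture
def ugt1a5_annotation(ugt1a5):
    return derive_annotation([ugt1a5])


@pytest.fixture
def sample_profile():
    return ugt1a5_sample()


@pytest.fixture
def tpmt():
    return curate(tpmt_table())
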