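import pytest

from asilidvenom.reference import DOLOPUS_PEPTIDES
from asilidvenom.synthetic import SyntheticVenomSpec


@pytest.fixture(scope="session")
def peptide_records():
    """The published mature-peptide repertoire (12 records)."""
    return DOLOPUS_PEPTIDES


@pytest.fixture
def venom_spec():
    """Default synthetic study conditions with a fixed seed."""
    return SyntheticVenomSpec(seed=20181105)
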