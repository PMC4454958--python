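import pytest

from workrisk.dose_response import AGENCY_SCHEMAS
from workrisk.substances import biphenyl_dossier


@pytest.fixture(scope="session")
def biphenyl():
    return biphenyl_dossier()


@pytest.fixture(scope="session")
def kosha():
    return AGENCY_SCHEMAS["KOSHA"]


@pytest.fixture
def write_table(tmp_path):
    """Write a small measurement table and return its path."""

    def _write(text, name="samples.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
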