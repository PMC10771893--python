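import pytest

from domaindrift import synthetic_data as sd
from domaindrift.coiledcoil import load_propensity_table
from domaindrift.records import Msa, SeqRecord


@pytest.fixture(scope="session")
def propensity_table():
    return load_propensity_table()


@pytest.fixture(scope="session")
def mammal_result():
    """One simulated mammal panel (no acceleration), shared across tests."""
    return sd.simulate_cds(sd.mammal_config(seed=11))


@pytest.fixture
def toy_msa():
    return Msa(
        [
            SeqRecord(id="A", residues="ACGTACGTAC"),
            SeqRecord(id="B", residues="ACGTACGTAA"),
            SeqRecord(id="C", residues="ACGTACGTAC"),
        ]
    )


def write_lines(path, text):
    path.write_text(text)
    return str(path)
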