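import pytest

from capripep import (
    FilterPolicy,
    ProteinSequence,
    default_candidate_table,
    default_enzymes,
    default_peptide_db,
    default_registry,
)


@pytest.fixture(scope="session")
def enzymes():
    return default_enzymes()


@pytest.fixture(scope="session")
def enzymes_by_name(enzymes):
    return {e.name: e for e in enzymes}


@pytest.fixture(scope="session")
def trypsin(enzymes_by_name):
    return enzymes_by_name["trypsin"]


@pytest.fixture(scope="session")
def pepsin(enzymes_by_name):
    return enzymes_by_name["pepsin"]


@pytest.fixture(scope="session")
def candidate_table():
    return default_candidate_table()


@pytest.fixture(scope="session")
def peptide_db():
    return default_peptide_db()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def default_policy():
    return FilterPolicy()


def make_seq(residues: str, seq_id: str = "s", gene: str = "", allele: str = "") -> ProteinSequence:
    return ProteinSequence(id=seq_id, residues=residues, gene=gene, allele=allele)


@pytest.fixture
def seq_factory():
    return make_seq
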