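import pytest

from ncrates.classification import standard_genetic_code, table1_classification
from ncrates.seqio import CodonPairAlignment


@pytest.fixture(scope="session")
def code():
    return standard_genetic_code()


@pytest.fixture(scope="session")
def cls():
    return table1_classification()


def aln_from_codons(codons_a, codons_b, pair_id="test"):
    return CodonPairAlignment(
        id=pair_id, codons_a=tuple(codons_a), codons_b=tuple(codons_b)
    )


@pytest.fixture
def make_aln():
    return aln_from_codons
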