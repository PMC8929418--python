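import pytest
from hypothesis import HealthCheck, settings

from vrskit import (
    Allele,
    LiteralSequenceExpression,
    Number,
    SequenceInterval,
    SequenceLocation,
    SequenceStore,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")

TINY1 = "CCTAC"
REP1 = "TTACACACAGG"
HOMO1 = "AAAA"


def literal_allele(sequence_id: str, start: int, end: int, alt: str) -> Allele:
    return Allele(
        location=SequenceLocation(
            sequence_id=sequence_id,
            interval=SequenceInterval(
                start=Number(value=start), end=Number(value=end)
            ),
        ),
        state=LiteralSequenceExpression(sequence=alt),
    )


@pytest.fixture()
def store() -> SequenceStore:
    s = SequenceStore()
    # tiny1 carries a second (synthetic accession-style) alias on purpose:
    # synonym invariance tests build alleles through each
    s.add_sequence(TINY1, aliases=["local:tiny1", "refseq:TINY_0001.1"])
    s.add_sequence(REP1, aliases=["local:rep1"])
    s.add_sequence(HOMO1, aliases=["local:homo1"])
    return s


@pytest.fixture()
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">tiny1\nCCTAC\n>rep1\nTTACACAC\nAGG\n")
    return path
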