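import pytest

from nmdscan.datasets import sod1_transcript, sod1_variants
from nmdscan.transcript import TranscriptModel


@pytest.fixture(scope="session")
def sod1() -> TranscriptModel:
    return sod1_transcript()


@pytest.fixture(scope="session")
def sod1_table():
    return sod1_variants()


@pytest.fixture
def single_exon() -> TranscriptModel:
    return TranscriptModel(
        transcript_id="SINGLE", cds_sequence="ATGAAATAA", exon_cds_lengths=[9]
    )


@pytest.fixture
def three_exon() -> TranscriptModel:
    # 100 codons over exons of 90/120/90 nt; junctions at 90 and 210
    cds = "ATG" + "GCT" * 98 + "TAA"
    return TranscriptModel(
        transcript_id="THREE", cds_sequence=cds, exon_cds_lengths=[90, 120, 90]
    )


def make_transcript_with_exons(exon_lengths: list[int]) -> TranscriptModel:
    """Deterministic stop-free transcript over the given exon partition."""
    total = sum(exon_lengths)
    assert total % 3 == 0
    cds = "ATG" + "GAA" * (total // 3 - 2) + "TGA"
    return TranscriptModel(
        transcript_id="X" + "_".join(map(str, exon_lengths)),
        cds_sequence=cds,
        exon_cds_lengths=exon_lengths,
    )
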