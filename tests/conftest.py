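import pytest

from ctcf_catalog.transcript import (
    DomainEntry,
    DomainMap,
    GenomicInterval,
    TranscriptModel,
)


@pytest.fixture
def t1_model():
    """Two-exon plus-strand toy: exon1 101-160, exon2 201-260, CDS 121-240."""
    return TranscriptModel(
        transcript_id="T1",
        gene_symbol="TOY",
        strand="+",
        exons=[
            GenomicInterval("chrT", 101, 160),
            GenomicInterval("chrT", 201, 260),
        ],
        cds_genomic=GenomicInterval("chrT", 121, 240),
    )


@pytest.fixture
def mini_cds_model():
    """Single-exon model with the 5-codon CDS ATG GAC TTG AGC TAA (M-D-L-S-*)."""
    return TranscriptModel(
        transcript_id="MINI",
        gene_symbol="TOY",
        strand="+",
        exons=[GenomicInterval("chrT", 1, 15)],
        cds_genomic=GenomicInterval("chrT", 1, 15),
        cds_sequence="ATGGACTTGAGCTAA",
    )


@pytest.fixture
def toy_zf_map():
    """One zinc finger spanning 10-32 with helix anchor 20, Cys 12/15, His 26/30."""
    return DomainMap(
        entries=[
            DomainEntry(
                "ZF1", 10, 32, "zinc_finger",
                cys=(12, 15), his=(26, 30), helix_anchor=20,
            ),
            DomainEntry("ZF2", 40, 60, "zinc_finger", rbd=True),
        ],
        protein_length=100,
    )
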