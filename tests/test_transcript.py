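"""Transcript geometry: interval arithmetic, coordinate mapping, domains."""

import numpy as np
import pytest

from ctcf_catalog.transcript import (
    CTCF_CDS_GRCH37,
    CTCF_GENE_GRCH37,
    CdnaCoordinate,
    CoordinateError,
    GenomicInterval,
    TranscriptModel,
    codon_of,
    ctcf_domain_map,
    dump_transcript_config,
    interval_length,
    load_transcript_config,
)
from ctcf_catalog.synthetic import generate_transcript


class TestIntervalLength:
    @pytest.mark.parametrize(
        "iv,expected",
        [
            (CTCF_GENE_GRCH37, 76_779),  # published CTCF gene span
            (CTCF_CDS_GRCH37, 27_040),  # published CDS genomic span
            (GenomicInterval("chrT", 5, 5), 1),
        ],
    )
    def test_printed_spans(self, iv, expected):
        assert interval_length(iv) == expected

    def test_equals_brute_force_count(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            start = int(rng.integers(1, 1000))
            end = start + int(rng.integers(0, 500))
            iv = GenomicInterval("chrT", start, end)
            assert interval_length(iv) == len(range(start, end + 1))

    def test_invalid_interval_rejected(self):
        with pytest.raises(CoordinateError):
            GenomicInterval("chrT", 10, 9)


class TestGenomicToCdna:
    @pytest.mark.parametrize(
        "pos,kind,base,offset",
        [
            (121, "cds", 1, 0),
            (201, "cds", 41, 0),  # exon1 holds c.1-40, exon2 starts at c.41
            (165, "intronic", 40, 5),  # 5 bases past exon1 end
            (245, "utr3", 5, 0),  # CDS ends at 240
            (110, "utr5", 11, 0),
        ],
    )
    def test_examples(self, t1_model, pos, kind, base, offset):
        c = t1_model.genomic_to_cdna(pos)
        assert (c.kind, c.base, c.offset) == (kind, base, offset)

    def test_matches_exhaustive_walk(self, t1_model):
        """Exonic coding addresses agree with walking the exon union base by base."""
        walk = []
        for exon in t1_model.exons:
            walk.extend(range(exon.start, exon.end + 1))
        coding = [p for p in walk if 121 <= p <= 240]
        for i, pos in enumerate(coding, start=1):
            c = t1_model.genomic_to_cdna(pos)
            assert (c.kind, c.base) == ("cds", i)

    def test_intronic_tie_assigns_upstream_exon(self):
        model = TranscriptModel(
            "TIE", "TOY", "+",
            [GenomicInterval("chrT", 1, 10), GenomicInterval("chrT", 20, 30)],
            GenomicInterval("chrT", 1, 30),
        )
        # intron spans 11-19; position 15 is equidistant (5) from both exon
        # edges and must anchor to the 5' exon with a positive offset
        c15 = model.genomic_to_cdna(15)
        c16 = model.genomic_to_cdna(16)
        assert (c15.base, c15.offset) == (10, 5)
        assert (c16.base, c16.offset) == (11, -4)

    def test_outside_gene_span(self, t1_model):
        with pytest.raises(CoordinateError):
            t1_model.genomic_to_cdna(90)

    @pytest.mark.parametrize(
        "pos,region", [(130, "exonic_cds"), (110, "utr5"), (180, "intronic")]
    )
    def test_annotate_position(self, t1_model, pos, region):
        assert t1_model.annotate_position(pos) == region


class TestCdnaToGenomic:
    @pytest.mark.parametrize(
        "coord,pos",
        [
            (CdnaCoordinate("cds", 1), 121),
            (CdnaCoordinate("cds", 41), 201),
            (CdnaCoordinate("utr3", 5), 245),
        ],
    )
    def test_examples(self, t1_model, coord, pos):
        assert t1_model.cdna_to_genomic(coord) == pos

    def test_round_trip_exhaustive(self, t1_model):
        span = t1_model.gene_span
        for pos in range(span.start, span.end + 1):
            coord = t1_model.genomic_to_cdna(pos)
            assert t1_model.cdna_to_genomic(coord) == pos

    def test_round_trip_random_models(self):
        for seed in range(5):
            model = generate_transcript(seed, n_exons=3, cds_codons=20)
            span = model.gene_span
            for pos in range(span.start, span.end + 1):
                assert model.cdna_to_genomic(model.genomic_to_cdna(pos)) == pos

    def test_beyond_transcript_extent(self, t1_model):
        with pytest.raises(CoordinateError):
            t1_model.cdna_to_genomic(CdnaCoordinate("utr3", 9999))


class TestMinusStrand:
    @pytest.fixture
    def minus_model(self):
        return TranscriptModel(
            "M1", "TOY", "-",
            [GenomicInterval("chrT", 201, 260), GenomicInterval("chrT", 101, 160)],
            GenomicInterval("chrT", 121, 240),
        )

    def test_coding_mapping_strictly_decreasing(self, minus_model):
        coding = []
        for exon in (GenomicInterval("chrT", 101, 160), GenomicInterval("chrT", 201, 260)):
            for pos in range(exon.start, exon.end + 1):
                c = minus_model.genomic_to_cdna(pos)
                if c.kind == "cds":
                    coding.append((pos, c.base))
        coding.sort()
        bases = [b for _, b in coding]
        assert bases == sorted(bases, reverse=True)

    def test_round_trip(self, minus_model):
        span = minus_model.gene_span
        for pos in range(span.start, span.end + 1):
            assert minus_model.cdna_to_genomic(minus_model.genomic_to_cdna(pos)) == pos


class TestCodonOf:
    @pytest.mark.parametrize(
        "cds_pos,residue,offset",
        [(1456, 486, 1), (1430, 477, 2), (3, 1, 3), (1, 1, 1)],
    )
    def test_examples(self, cds_pos, residue, offset):
        assert codon_of(cds_pos) == (residue, offset)

    def test_identity_over_range(self):
        for pos in range(1, 400):
            residue, offset = codon_of(pos)
            assert 3 * (residue - 1) + offset == pos
            assert 1 <= offset <= 3

    def test_out_of_range(self):
        with pytest.raises(CoordinateError):
            codon_of(0)
        with pytest.raises(CoordinateError):
            codon_of(100, cds_length=99)


class TestModelInvariants:
    def test_exon_lengths_sum_to_mrna(self, t1_model):
        assert t1_model.mrna_length == sum(len(e) for e in t1_model.exons)

    def test_cds_sequence_length_checked(self):
        with pytest.raises(ValueError, match="length"):
            TranscriptModel(
                "BAD", "TOY", "+",
                [GenomicInterval("chrT", 1, 15)],
                GenomicInterval("chrT", 1, 15),
                cds_sequence="ATGTAA",
            )

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            TranscriptModel(
                "BAD", "TOY", "+",
                [GenomicInterval("chrT", 1, 9)],
                GenomicInterval("chrT", 1, 9),
                cds_sequence="ATGTAATAA",
            )

    def test_config_round_trip(self, tmp_path):
        model = generate_transcript(3)
        path = tmp_path / "model.yaml"
        dump_transcript_config(model, path)
        loaded = load_transcript_config(path)
        assert loaded.exons == model.exons
        assert loaded.cds_genomic == model.cds_genomic
        assert loaded.cds_sequence == model.cds_sequence
        assert loaded.strand == model.strand


class TestDomainMap:
    def test_ctcf_published_anchors(self):
        dmap = ctcf_domain_map()
        assert dmap.domain_of(226) == "YDF"
        assert dmap.residue_role(226) == "ydf"
        assert dmap.domain_of(270) == "ZF1"
        assert dmap.residue_role(270) == "rbd"
        assert dmap.domain_of(540) == "ZF10"
        assert dmap.domain_of(600) == "C-term"
        assert dmap.domain_of(100) == "N-term"

    def test_toy_zf_roles(self, toy_zf_map):
        assert toy_zf_map.residue_role(12) == "zinc_coordinating_cys"
        assert toy_zf_map.residue_role(26) == "zinc_coordinating_his"
        assert toy_zf_map.residue_role(19) == "dna_contact"  # helix -1
        assert toy_zf_map.residue_role(22) == "dna_contact"  # helix +2
        assert toy_zf_map.residue_role(50) == "rbd"
        # between fingers -> linker; outside the ZF region -> none
        assert toy_zf_map.domain_of(35) == "linker"
        assert toy_zf_map.residue_role(35) == "linker"
        assert toy_zf_map.domain_of(80) == "none"
        assert toy_zf_map.residue_role(80) == "none"

    def test_residue_out_of_range(self, toy_zf_map):
        with pytest.raises(CoordinateError):
            toy_zf_map.domain_of(101)
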