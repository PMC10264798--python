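"""Source ingestion, standardization and cross-source deduplication."""

import numpy as np
import pytest

from ctcf_catalog.harmonize import (
    Exclusion,
    SchemaError,
    SourceRecord,
    StandardizedRecord,
    deduplicate,
    ingest_source,
    ingest_vcf,
    source_overlap_table,
    standardize,
)
from ctcf_catalog.liftover import constant_offset_chain
from ctcf_catalog.synthetic import generate_transcript
from ctcf_catalog.transcript import CdnaCoordinate


@pytest.fixture(scope="module")
def model():
    return generate_transcript(2, n_exons=2, cds_codons=30)


@pytest.fixture(scope="module")
def chains(model):
    span = model.gene_span
    return [
        constant_offset_chain(
            model.chrom, model.chrom,
            (span.start - 100 + 5000 - 1, span.end + 100 + 5000),
            -5000,
        )
    ]


def _sub_record(model, cds_pos, source="S", assembly="GRCh37", **kw):
    g = model.cdna_to_genomic(CdnaCoordinate("cds", cds_pos))
    ref = model.base_at_cds(cds_pos)
    alt = "A" if ref != "A" else "G"
    pos = g + 5000 if assembly == "GRCh38" else g
    return SourceRecord(
        source=source,
        record_id=f"{source}-{cds_pos}",
        assembly=assembly,
        chrom=model.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        **kw,
    )


class TestIngest:
    def test_clinvar_like_export(self, tmp_path):
        path = tmp_path / "cv.tsv"
        path.write_text(
            "VariationID\tAssembly\tChromosome\tPositionVCF\tReferenceAlleleVCF\t"
            "AlternateAlleleVCF\tName\tPhenotypeList\tClinicalSignificance\t"
            "OriginSimple\tTrioConfirmed\tAF\n"
            "1\tGRCh37\tchrT\t100123\tA\tG\tc.4A>G\tAutism\tPathogenic\tde novo\tyes\t\n"
            "2\t\t\t\t\t\tc.6C>T\tEpilepsy\t\t\t\t\n"
            "3\t\t\t\t\t\t\tno data at all\t\t\t\t\n"
        )
        records, exclusions = ingest_source(path, "clinvar_like", "ClinVar")
        assert len(records) == 2
        assert len(exclusions) == 1
        assert exclusions[0].reason == "ambiguous"
        assert records[0].has_coordinates
        assert records[0].trio_available
        assert records[1].hgvs_c == "c.6C>T"

    def test_unknown_schema(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(SchemaError):
            ingest_source(path, "no_such_schema")

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("NotTheIdColumn\n1\n")
        with pytest.raises(SchemaError, match="mandatory"):
            ingest_source(path, "clinvar_like")

    def test_vcf_ingestion(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chrT,length=200000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chrT\t100123\trs1\tA\tG\t.\t.\t.\n"
        )
        (rec,) = ingest_vcf(vcf, "VCFSRC")
        assert (rec.chrom, rec.pos, rec.ref, rec.alt) == ("chrT", 100123, "A", "G")


class TestStandardize:
    def test_grch38_record_lifted(self, model, chains):
        rec = _sub_record(model, 10, assembly="GRCh38")
        out = standardize(rec, chains, model)
        assert isinstance(out, StandardizedRecord)
        rec37 = _sub_record(model, 10, assembly="GRCh37")
        out37 = standardize(rec37, chains, model)
        assert out.key == out37.key

    def test_hgvs_only_record_gets_coordinates(self, model, chains):
        rec = SourceRecord(
            source="S", record_id="h1", hgvs_c="c.8" + model.base_at_cds(8) + ">" +
            ("A" if model.base_at_cds(8) != "A" else "C"),
        )
        out = standardize(rec, chains, model)
        assert isinstance(out, StandardizedRecord)
        from ctcf_catalog.transcript import CdnaCoordinate

        assert out.pos == model.cdna_to_genomic(CdnaCoordinate("cds", 8))

    def test_reference_mismatch_excluded(self, model, chains):
        ref = model.base_at_cds(5)
        wrong = "A" if ref != "A" else "C"
        rec = SourceRecord(source="S", record_id="x", hgvs_c=f"c.5{wrong}>G")
        out = standardize(rec, chains, model)
        assert isinstance(out, Exclusion)
        assert out.reason == "reference-mismatch"

    def test_unsupported_kind_excluded(self, model, chains):
        rec = SourceRecord(source="S", record_id="inv", hgvs_c="c.4_10inv")
        out = standardize(rec, chains, model)
        assert isinstance(out, Exclusion)
        assert out.reason == "unsupported-kind"

    def test_same_variant_both_representations_share_key(self, model, chains):
        coord_rec = _sub_record(model, 12)
        hgvs = f"c.12{coord_rec.ref}>{coord_rec.alt}"
        hgvs_rec = SourceRecord(source="T", record_id="h", hgvs_c=hgvs)
        a = standardize(coord_rec, chains, model)
        b = standardize(hgvs_rec, chains, model)
        assert a.key == b.key


class TestDeduplicate:
    def test_two_sources_one_variant(self, model, chains):
        a = standardize(_sub_record(model, 10, source="A"), chains, model)
        b = standardize(_sub_record(model, 10, source="B"), chains, model)
        catalog, stats = deduplicate([a, b])
        assert len(catalog) == 1
        assert set(catalog[0].provenance) == {"A", "B"}
        assert stats["n_in_multiple_sources"] == 1
        assert stats["n_duplicate_records"] == 1

    def test_empty_input(self):
        catalog, stats = deduplicate([])
        assert catalog == []
        assert stats["n_distinct"] == 0

    def test_conservation_and_order_invariance(self, model, chains):
        rng = np.random.default_rng(3)
        std = []
        for i in range(60):
            cds_pos = int(rng.integers(4, 80))
            src = str(rng.choice(["A", "B", "C"]))
            std.append(standardize(_sub_record(model, cds_pos, source=src), chains, model))
        c1, s1 = deduplicate(std)
        shuffled = [std[i] for i in rng.permutation(len(std))]
        c2, s2 = deduplicate(shuffled)
        assert s1 == s2
        assert [c.key for c in c1] == [c.key for c in c2]
        assert s1["n_records"] == s1["n_distinct"] + s1["n_duplicate_records"]
        # provenance multiset conservation
        assert sum(c.n_records for c in c1) == s1["n_records"]

    def test_conflicting_attributes_surface(self, model, chains):
        a = _sub_record(model, 10, source="A", reported_pathogenicity="Pathogenic")
        b = _sub_record(model, 10, source="B", reported_pathogenicity="Benign")
        catalog, _ = deduplicate(
            [standardize(a, chains, model), standardize(b, chains, model)]
        )
        assert catalog[0].conflicting


class TestOverlapTable:
    def test_disjoint_sources_fully_exclusive(self, model, chains):
        a = standardize(_sub_record(model, 10, source="A"), chains, model)
        b = standardize(_sub_record(model, 20, source="B"), chains, model)
        _, stats = deduplicate([a, b])
        table = source_overlap_table(stats).set_index("source")
        assert table.loc["A", "share_exclusive"] == 1.0
        assert table.loc["B", "share_exclusive"] == 1.0

    def test_full_overlap_zero_exclusive(self, model, chains):
        a = standardize(_sub_record(model, 10, source="A"), chains, model)
        b = standardize(_sub_record(model, 10, source="B"), chains, model)
        _, stats = deduplicate([a, b])
        table = source_overlap_table(stats).set_index("source")
        assert table.loc["A", "share_exclusive"] == 0.0
        assert table.loc["total", "all_entries"] == 2
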