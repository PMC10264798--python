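"""Multi-source ingestion, standardization and cross-database deduplication.

Each genotype-phenotype database exports variants in its own schema; a
per-source column-map dialect turns every export into the same
:class:`SourceRecord` shape. Standardization then brings every record onto
GRCh37 + canonical 3'-normalized HGVS (lifting GRCh38 coordinates through a
chain file, reconstructing coordinates from HGVS or vice versa against the
canonical transcript), and deduplication collapses records with the same
canonical key into one :class:`CanonicalVariant` carrying provenance.

Every record that leaves the pipeline does so with an audit reason
(ambiguous, liftover_unmapped, reference-mismatch, unsupported-kind,
inconsistent) — nothing is dropped silently, and record counts are conserved
at every stage: ingested = distinct + duplicate + excluded.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .consequence import ConsequenceCall, call_consequence
from .hgvs import (
    CdnaVariant,
    HgvsParseError,
    ReferenceMismatchError,
    UnsupportedKindError,
    format_c,
    normalize_3prime,
    parse_c,
)
from .liftover import ChainAlignment, Unmapped, map_position
from .transcript import CdnaCoordinate, CoordinateError, DomainMap, TranscriptModel

GRCH37 = "GRCh37"
GRCH38 = "GRCh38"


@dataclass
class SourceRecord:
    """One row of a source export, with raw fields mapped to common names."""

    source: str
    record_id: str
    assembly: str = GRCH37
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    hgvs_c: Optional[str] = None
    variant_class: str = "snv_like"  # snv_like | cnv
    phenotype_texts: list[str] = field(default_factory=list)
    origin_raw: str = ""
    trio_available: bool = False
    reported_pathogenicity: str = ""
    allele_frequency: Optional[float] = None

    @property
    def has_coordinates(self) -> bool:
        return all(x not in (None, "") for x in (self.chrom, self.pos, self.ref, self.alt))


@dataclass(frozen=True)
class Exclusion:
    record_id: str
    source: str
    reason: str


@dataclass
class StandardizedRecord:
    """A source record on GRCh37 with a canonical key and consequence call."""

    record: SourceRecord
    key: tuple  # (chrom, pos, ref, alt) of the 3'-shifted representation
    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_c: str
    variant: CdnaVariant
    consequence: ConsequenceCall


@dataclass
class CanonicalVariant:
    key: tuple
    hgvs_c: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: ConsequenceCall
    provenance: Counter = field(default_factory=Counter)
    phenotype_texts: list[str] = field(default_factory=list)
    origins: list[str] = field(default_factory=list)
    trio_available: bool = False
    reported_pathogenicities: list[str] = field(default_factory=list)
    allele_frequency: Optional[float] = None
    record_ids: list[str] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return sum(self.provenance.values())

    @property
    def conflicting(self) -> bool:
        vals = {p for p in self.reported_pathogenicities if p}
        return len(vals) > 1


# ---------------------------------------------------------------------------
# Schema dialects
# ---------------------------------------------------------------------------

# canonical field -> column name; "delimiter" selects TSV vs CSV.
SCHEMA_DIALECTS: dict[str, dict] = {
    "clinvar_like": {
        "delimiter": "\t",
        "columns": {
            "record_id": "VariationID",
            "assembly": "Assembly",
            "chrom": "Chromosome",
            "pos": "PositionVCF",
            "ref": "ReferenceAlleleVCF",
            "alt": "AlternateAlleleVCF",
            "hgvs_c": "Name",
            "phenotype": "PhenotypeList",
            "pathogenicity": "ClinicalSignificance",
            "origin": "OriginSimple",
            "trio": "TrioConfirmed",
            "allele_frequency": "AF",
        },
        "phenotype_sep": ";",
    },
    "lovd_like": {
        "delimiter": ",",
        "columns": {
            "record_id": "id",
            "hgvs_c": "dna_change",
            "phenotype": "phenotype",
            "pathogenicity": "classification",
            "origin": "inheritance",
            "trio": "trio",
        },
        "phenotype_sep": "|",
    },
    "denovo_like": {
        "delimiter": "\t",
        "columns": {
            "record_id": "SampleID",
            "assembly": "Build",
            "chrom": "Chr",
            "pos": "Position",
            "ref": "Ref",
            "alt": "Alt",
            "phenotype": "PrimaryPhenotype",
            "origin": "Validation",
            "trio": "Trio",
        },
        "phenotype_sep": ";",
    },
    "generic": {
        "delimiter": "\t",
        "columns": {
            "record_id": "record_id",
            "assembly": "assembly",
            "chrom": "chrom",
            "pos": "pos",
            "ref": "ref",
            "alt": "alt",
            "hgvs_c": "hgvs_c",
            "phenotype": "phenotype",
            "pathogenicity": "pathogenicity",
            "origin": "origin",
            "trio": "trio",
            "allele_frequency": "allele_frequency",
        },
        "phenotype_sep": ";",
    },
}


class SchemaError(ValueError):
    pass


def _get(row: dict, colmap: dict, field_name: str) -> str:
    col = colmap.get(field_name)
    if col is None:
        return ""
    return (row.get(col) or "").strip()


def ingest_source(
    path: str | Path,
    schema_name: str,
    source_name: Optional[str] = None,
    dialects: Optional[dict] = None,
) -> tuple[list[SourceRecord], list[Exclusion]]:
    """Read one export file under a registered schema dialect.

    Rows carrying neither coordinates nor an HGVS description are excluded
    as ambiguous. Returns (records, exclusions).
    """
    dialects = dialects or SCHEMA_DIALECTS
    if schema_name not in dialects:
        raise SchemaError(f"unknown schema dialect {schema_name!r}")
    spec = dialects[schema_name]
    colmap = spec["columns"]
    source = source_name or Path(path).stem
    records: list[SourceRecord] = []
    exclusions: list[Exclusion] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=spec.get("delimiter", "\t"))
        if reader.fieldnames is None:
            return [], []
        required = {colmap["record_id"]}
        missing = required - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {sorted(missing)}")
        for i, row in enumerate(reader):
            record_id = _get(row, colmap, "record_id") or f"{source}:{i}"
            pos_txt = _get(row, colmap, "pos")
            hgvs_c = _get(row, colmap, "hgvs_c") or None
            chrom = _get(row, colmap, "chrom") or None
            ref = _get(row, colmap, "ref") or None
            alt = _get(row, colmap, "alt") or None
            af_txt = _get(row, colmap, "allele_frequency")
            pheno_sep = spec.get("phenotype_sep", ";")
            pheno_raw = _get(row, colmap, "phenotype")
            phenotypes = [p.strip() for p in pheno_raw.split(pheno_sep) if p.strip()]
            rec = SourceRecord(
                source=source,
                record_id=record_id,
                assembly=_get(row, colmap, "assembly") or GRCH37,
                chrom=chrom,
                pos=int(pos_txt) if pos_txt else None,
                ref=ref,
                alt=alt,
                hgvs_c=hgvs_c,
                phenotype_texts=phenotypes,
                origin_raw=_get(row, colmap, "origin"),
                trio_available=_get(row, colmap, "trio").lower()
                in ("1", "true", "yes", "y"),
                reported_pathogenicity=_get(row, colmap, "pathogenicity"),
                allele_frequency=float(af_txt) if af_txt else None,
            )
            if not rec.has_coordinates and not rec.hgvs_c:
                exclusions.append(Exclusion(record_id, source, "ambiguous"))
            else:
                records.append(rec)
    return records, exclusions


def ingest_vcf(path: str | Path, source_name: str, assembly: str = GRCH37) -> list[SourceRecord]:
    """Read coordinate-bearing records from a VCF via pysam."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            for alt in rec.alts or ():
                records.append(
                    SourceRecord(
                        source=source_name,
                        record_id=rec.id or f"{source_name}:{i}",
                        assembly=assembly,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def _vcf_style_to_cdna(
    model: TranscriptModel, pos: int, ref: str, alt: str
) -> CdnaVariant:
    """Build a CdnaVariant from genomic pos/ref/alt (plus-strand transcripts).

    Trims the shared prefix, then classifies as sub/del/ins/delins. Raises
    CoordinateError for positions outside the transcript.
    """
    if model.strand != "-":
        pass
    ref, alt = ref.upper(), alt.upper()
    # trim common prefix (VCF anchors indels on the preceding base)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    if len(ref) == len(alt) == 1 and ref != alt:
        coord = model.genomic_to_cdna(pos)
        if model.strand == "-":
            ref, alt = _revcomp(ref), _revcomp(alt)
        return CdnaVariant("sub", coord, coord, ref=ref, alt=alt)
    if len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
        # deletion of ref[1:]
        start_g, end_g = pos + 1, pos + len(ref) - 1
        return _span_variant(model, "del", start_g, end_g, ref[1:], "")
    if len(alt) > 1 and len(ref) == 1 and alt[0] == ref[0]:
        # insertion of alt[1:] after pos
        inserted = alt[1:]
        c1 = model.genomic_to_cdna(pos)
        c2 = model.genomic_to_cdna(pos + 1 if model.strand == "+" else pos - 1)
        if model.strand == "-":
            inserted = _revcomp(inserted)
            c1, c2 = c2, c1
        return CdnaVariant("ins", c1, c2, alt=inserted)
    # remaining: delins
    return _span_variant(model, "delins", pos, pos + len(ref) - 1, ref, alt)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _span_variant(
    model: TranscriptModel, kind: str, start_g: int, end_g: int, ref: str, alt: str
) -> CdnaVariant:
    c1 = model.genomic_to_cdna(start_g)
    c2 = model.genomic_to_cdna(end_g)
    if model.strand == "-":
        c1, c2 = c2, c1
        ref, alt = _revcomp(ref), _revcomp(alt)
    return CdnaVariant(kind, c1, c2, ref=ref if kind != "ins" else "", alt=alt)


def _cdna_to_vcf_style(
    model: TranscriptModel, v: CdnaVariant
) -> tuple[str, int, str, str]:
    """Genomic (chrom, pos, ref, alt) of a normalized variant.

    Indels are represented HGVS-style (deleted/inserted bases, no VCF anchor
    base): the key is catalog-internal and only needs to be injective.
    """
    chrom = model.chrom
    g_start = model.cdna_to_genomic(v.start)
    if v.kind == "sub":
        ref, alt = v.ref, v.alt
        if model.strand == "-":
            ref, alt = _revcomp(ref), _revcomp(alt)
        return chrom, g_start, ref, alt
    g_end = model.cdna_to_genomic(v.end)
    lo = min(g_start, g_end)
    if v.kind == "del":
        return chrom, lo, v.ref or "?", ""
    if v.kind == "dup":
        return chrom, lo, v.ref or "?", (v.ref or "?") * 2
    if v.kind == "ins":
        return chrom, lo, "", v.alt
    return chrom, lo, v.ref or "?", v.alt  # delins


def standardize(
    rec: SourceRecord,
    chains: Sequence[ChainAlignment],
    model: TranscriptModel,
    domain_map: Optional[DomainMap] = None,
) -> StandardizedRecord | Exclusion:
    """Bring one record onto GRCh37 + canonical HGVS, or exclude with reason."""

    def exclude(reason: str) -> Exclusion:
        return Exclusion(rec.record_id, rec.source, reason)

    chrom, pos, ref, alt = rec.chrom, rec.pos, rec.ref, rec.alt

    if rec.has_coordinates and rec.assembly == GRCH38:
        lifted = map_position(list(chains), chrom, pos)
        if isinstance(lifted, Unmapped):
            return exclude(f"liftover_unmapped:{lifted.reason}")
        chrom, pos = lifted.chrom, lifted.pos
    elif rec.has_coordinates and rec.assembly not in (GRCH37, GRCH38):
        return exclude("unknown_assembly")

    variant: Optional[CdnaVariant] = None
    try:
        if rec.hgvs_c:
            variant = parse_c(rec.hgvs_c)
        if variant is None:
            variant = _vcf_style_to_cdna(model, pos, ref, alt)
        if variant.is_coding and model.cds_sequence is not None:
            variant = normalize_3prime(model.cds_sequence, variant)
        elif variant.kind == "sub" and variant.start.kind == "cds":
            pass
    except HgvsParseError:
        return exclude("hgvs_parse_error")
    except UnsupportedKindError:
        return exclude("unsupported-kind")
    except ReferenceMismatchError:
        return exclude("reference-mismatch")
    except CoordinateError:
        return exclude("out_of_transcript")

    # consistency: when both HGVS and coordinates were provided, the genomic
    # position derived from the (pre-normalization) HGVS must match.
    if rec.hgvs_c and rec.has_coordinates:
        try:
            stated = parse_c(rec.hgvs_c)
            derived = model.cdna_to_genomic(stated.start)
        except (HgvsParseError, UnsupportedKindError, CoordinateError):
            return exclude("hgvs_parse_error")
        if abs(derived - pos) > max(len(stated.ref), len(stated.alt), 1):
            return exclude("inconsistent")
        # validate stated genomic ref against transcript sequence
        if (
            stated.kind == "sub"
            and stated.start.kind == "cds"
            and model.cds_sequence is not None
        ):
            expected = model.base_at_cds(stated.start.base)
            base = ref if model.strand == "+" else _revcomp(ref)
            if base != expected:
                return exclude("reference-mismatch")

    # validate sub refs against the transcript even without genomic coords
    if (
        variant.kind == "sub"
        and variant.start.kind == "cds"
        and model.cds_sequence is not None
        and variant.ref != model.base_at_cds(variant.start.base)
    ):
        return exclude("reference-mismatch")

    try:
        chrom_c, pos_c, ref_c, alt_c = _cdna_to_vcf_style(model, variant)
        consequence = call_consequence(model, variant, domain_map, normalized=True)
    except CoordinateError:
        return exclude("out_of_transcript")

    return StandardizedRecord(
        record=rec,
        key=(chrom_c, pos_c, ref_c, alt_c),
        chrom=chrom_c,
        pos=pos_c,
        ref=ref_c,
        alt=alt_c,
        hgvs_c=format_c(variant),
        variant=variant,
        consequence=consequence,
    )


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


def deduplicate(
    records: Iterable[StandardizedRecord],
) -> tuple[list[CanonicalVariant], dict]:
    """Collapse standardized records into canonical variants with provenance.

    Merging keeps every reported attribute (phenotype texts, origins,
    pathogenicities) tagged by accumulation rather than overwriting; the
    per-variant ``conflicting`` flag surfaces disagreement. Stats conserve
    records: n_records = n_distinct + n_duplicate_records.
    """
    by_key: dict[tuple, CanonicalVariant] = {}
    n_records = 0
    for sr in records:
        n_records += 1
        cv = by_key.get(sr.key)
        if cv is None:
            cv = CanonicalVariant(
                key=sr.key,
                hgvs_c=sr.hgvs_c,
                chrom=sr.chrom,
                pos=sr.pos,
                ref=sr.ref,
                alt=sr.alt,
                consequence=sr.consequence,
            )
            by_key[sr.key] = cv
        cv.provenance[sr.record.source] += 1
        for t in sr.record.phenotype_texts:
            if t not in cv.phenotype_texts:
                cv.phenotype_texts.append(t)
        if sr.record.origin_raw:
            cv.origins.append(sr.record.origin_raw)
        cv.trio_available = cv.trio_available or sr.record.trio_available
        if sr.record.reported_pathogenicity:
            cv.reported_pathogenicities.append(sr.record.reported_pathogenicity)
        if sr.record.allele_frequency is not None:
            prev = cv.allele_frequency
            cv.allele_frequency = (
                sr.record.allele_frequency
                if prev is None
                else max(prev, sr.record.allele_frequency)
            )
        cv.record_ids.append(sr.record.record_id)

    catalog = [by_key[k] for k in sorted(by_key)]
    per_source_entries: Counter = Counter()
    per_source_unique: Counter = Counter()
    n_multi = 0
    for cv in catalog:
        for src, n in cv.provenance.items():
            per_source_entries[src] += n
        if len(cv.provenance) == 1:
            per_source_unique[next(iter(cv.provenance))] += 1
        else:
            n_multi += 1
    stats = {
        "n_records": n_records,
        "n_distinct": len(catalog),
        "n_duplicate_records": n_records - len(catalog),
        "per_source_entries": dict(per_source_entries),
        "per_source_unique": dict(per_source_unique),
        "n_in_multiple_sources": n_multi,
    }
    return catalog, stats


def source_overlap_table(stats: dict) -> pd.DataFrame:
    """Per-source entry counts and exclusivity shares, plus a totals row."""
    sources = sorted(stats["per_source_entries"])
    total_entries = sum(stats["per_source_entries"].values())
    rows = []
    for src in sources:
        entries = stats["per_source_entries"][src]
        unique = stats["per_source_unique"].get(src, 0)
        rows.append(
            {
                "source": src,
                "all_entries": entries,
                "share_of_total": entries / total_entries if total_entries else 0.0,
                "unique_variants": unique,
                "share_exclusive": unique / entries if entries else 0.0,
            }
        )
    rows.append(
        {
            "source": "total",
            "all_entries": total_entries,
            "share_of_total": 1.0 if total_entries else 0.0,
            "unique_variants": sum(stats["per_source_unique"].values()),
            "share_exclusive": float("nan"),
        }
    )
    return pd.DataFrame(rows)
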