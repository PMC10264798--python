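"""Synthetic multi-source variant exports with a ground-truth ledger.

No variant data were deposited with the study this pipeline reconstructs,
so every stage is exercised against generated data whose true structure is
known exactly. The generator builds a toy transcript, draws distinct
variants whose consequence class is verified by the consequence engine at
generation time, assigns phenotype/origin/pathogenicity attributes, and
emits per-source export files in heterogeneous schema dialects — a fraction
of records on GRCh38 with a matching synthetic chain file — together with a
:class:`TruthLedger` recording what the pipeline must recover.

The paper-aligned presets reproduce the printed record-level structure of
the aggregated CTCF dataset: 538 SNV records of which 227 are duplicates of
earlier records (311 distinct), 225 exonic variants of which 149 carry
NDD-qualifying phenotype terminology, and 73 CNV records containing 11
exact-coordinate duplicates (62 distinct, 27 gains / 35 losses).

All randomness flows from a single integer seed; equal seeds give
byte-identical output files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .consequence import call_consequence
from .harmonize import SCHEMA_DIALECTS, _cdna_to_vcf_style
from .hgvs import CdnaVariant, format_c, normalize_3prime
from .liftover import constant_offset_chain, format_chain
from .phenotype import NO_PHENOTYPE_DATA
from .transcript import (
    CdnaCoordinate,
    GenomicInterval,
    TranscriptModel,
    dump_transcript_config,
)

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

GRCH38_OFFSET = 5_000  # toy GRCh38 = toy GRCh37 + offset


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Toy transcript
# ---------------------------------------------------------------------------


def generate_transcript(
    seed: int,
    n_exons: int = 4,
    cds_codons: int = 120,
    utr5_len: int = 20,
    utr3_len: int = 60,
    intron_len: int = 40,
    chrom: str = "chrT",
    gene_start: int = 100_001,
) -> TranscriptModel:
    """A valid plus-strand toy transcript with UTRs and introns.

    The CDS starts with ATG, ends with a single terminal stop and contains
    no internal stop. Deterministic per seed.
    """
    if cds_codons < 2:
        raise GenerationError("cds_codons must be >= 2 (start plus stop)")
    if n_exons < 1:
        raise GenerationError("need at least one exon")
    rng = np.random.default_rng(seed)
    coding = "".join(rng.choice(_NON_STOP_CODONS) for _ in range(cds_codons - 2))
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    cds_seq = "ATG" + coding + stop
    mrna_len = utr5_len + len(cds_seq) + utr3_len

    # split the mRNA across exons (each nonempty, deterministic)
    if n_exons == 1:
        cuts: list[int] = []
    else:
        cuts = sorted(
            int(x) for x in rng.choice(np.arange(1, mrna_len), size=n_exons - 1, replace=False)
        )
    bounds = [0, *cuts, mrna_len]
    exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]

    exons = []
    g = gene_start
    for length in exon_lens:
        exons.append(GenomicInterval(chrom, g, g + length - 1))
        g += length + intron_len
    # CDS genomic span: transcript positions utr5_len+1 .. utr5_len+len(cds)
    def genomic_of(tpos: int) -> int:
        offset = 0
        for exon in exons:
            if tpos <= offset + len(exon):
                return exon.start + (tpos - offset - 1)
            offset += len(exon)
        raise GenerationError("transcript position beyond mRNA")

    cds_start_g = genomic_of(utr5_len + 1)
    cds_end_g = genomic_of(utr5_len + len(cds_seq))
    return TranscriptModel(
        transcript_id=f"TOY_{seed}",
        gene_symbol="TOY",
        strand="+",
        exons=exons,
        cds_genomic=GenomicInterval(chrom, cds_start_g, cds_end_g),
        assembly="GRCh37",
        cds_sequence=cds_seq,
    )


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------


@dataclass
class TruthVariant:
    index: int
    variant: CdnaVariant  # normalized
    hgvs_c: str
    key: tuple
    region: str  # exonic_cds | utr3 | intronic
    klass: str  # consequence class (noncoding for non-exonic)
    phenotype_category: str  # truth category, NON_NDD, CONTROL or NO_PHENOTYPE_DATA
    phenotype_texts: list[str] = field(default_factory=list)
    origin_raw: str = ""
    trio: bool = False
    reported_pathogenicity: str = ""


@dataclass
class TruthRecord:
    record_id: str
    variant_index: int
    source: str
    assembly: str
    with_coords: bool
    with_hgvs: bool


@dataclass
class TruthLedger:
    model: TranscriptModel
    variants: list[TruthVariant]
    records: list[TruthRecord] = field(default_factory=list)
    expected: dict = field(default_factory=dict)

    def variant_by_index(self, idx: int) -> TruthVariant:
        return self.variants[idx]


@dataclass
class CatalogParams:
    """Composition of the synthetic distinct-variant catalog."""

    # distinct variant counts by consequence class
    exonic_classes: dict = field(
        default_factory=lambda: {
            "missense": 117,
            "frameshift": 44,
            "nonsense": 18,
            "inframe_del": 5,
            "synonymous": 41,
        }
    )
    n_utr3: int = 40
    n_intronic: int = 46
    # phenotype composition of the exonic variants
    exonic_ndd_mix: dict = field(
        default_factory=lambda: {
            "CRD": 54, "ASD": 41, "IGD": 29, "DD": 18, "EP": 3, "ID": 2, "ANS": 2,
        }
    )
    n_exonic_non_ndd: int = 7
    n_exonic_no_phenotype: int = 69
    # noncoding phenotype composition
    noncoding_mix: dict = field(
        default_factory=lambda: {"ASD": 24, "CRD": 6, "ANS": 1, "CONTROL": 9}
    )
    # origin among exonic NDD variants
    n_de_novo: int = 128
    n_inherited: int = 6

    @property
    def n_exonic(self) -> int:
        return sum(self.exonic_classes.values())

    @property
    def n_distinct(self) -> int:
        return self.n_exonic + self.n_utr3 + self.n_intronic

    def validate(self) -> None:
        n_ndd = sum(self.exonic_ndd_mix.values())
        if n_ndd + self.n_exonic_non_ndd + self.n_exonic_no_phenotype != self.n_exonic:
            raise GenerationError("exonic phenotype mix does not sum to n_exonic")
        if sum(self.noncoding_mix.values()) > self.n_utr3 + self.n_intronic:
            raise GenerationError("noncoding phenotype mix exceeds noncoding count")
        if self.n_de_novo + self.n_inherited > n_ndd:
            raise GenerationError("origin mix exceeds NDD variant count")


def paper_aligned_params() -> CatalogParams:
    """311 distinct SNVs: 225 exonic (149 NDD / 7 non-NDD / 69 without
    phenotype data), 86 noncoding. Defaults above mirror the printed
    aggregate structure."""
    return CatalogParams()


# phenotype wording pools, deliberately messy to exercise the normalizer
PHENOTYPE_POOLS: dict[str, list[str]] = {
    "CRD": [
        "CTCF-related neurodevelopmental disorder",
        "Mental retardation, autosomal dominant 21",
        "MRD21",
        "ctcf related disorder",
        "Intellectual disability-feeding difficulties-developmental delay-microcephaly syndrome",
    ],
    "ASD": ["Autism spectrum disorder", "AUTISM", "autistic behavior", "Autism;"],
    "ID": ["Intellectual disability", "intellectual DISABILITY"],
    "DD": ["Developmental disorder", "global developmental delay", "Developmental delay,"],
    "IGD": ["Inborn genetic diseases", "inborn genetic disease"],
    "EP": ["Epilepsy", "recurrent seizures", "SEIZURE disorder"],
    "ANS": ["Abnormality of the nervous system", "congenital nervous system disorder"],
    "NON_NDD": [
        "Mammary neoplasms",
        "breast cancer",
        "Acute megakaryoblastic leukemia",
        "congenital diaphragmatic hernia",
    ],
    "CONTROL": ["detected in controls", "healthy control"],
}

_PATHOGENICITY_TEXTS = {
    "P": "Pathogenic",
    "LP": "Likely pathogenic",
    "VUS": "Uncertain significance",
    "LB": "Likely benign",
    "B": "Benign",
}


def _draw_sub(rng, model: TranscriptModel, lo: int, hi: int) -> CdnaVariant:
    pos = int(rng.integers(lo, hi + 1))
    ref = model.base_at_cds(pos)
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    c = CdnaCoordinate("cds", pos)
    return CdnaVariant("sub", c, c, ref=ref, alt=alt)


def _make_coding_variant(
    rng, model: TranscriptModel, klass: str, max_tries: int = 400
) -> CdnaVariant:
    """Draw a coding variant whose engine-verified class equals `klass`."""
    cds = model.cds_sequence
    assert cds is not None
    n = len(cds)
    for _ in range(max_tries):
        if klass in ("missense", "synonymous", "nonsense"):
            v = _draw_sub(rng, model, 4, n - 3)
        elif klass == "frameshift":
            pos = int(rng.integers(4, n - 6))
            c = CdnaCoordinate("cds", pos)
            kind = "del" if rng.random() < 0.5 else "dup"
            v = CdnaVariant(kind, c, c, ref=cds[pos - 1])
        elif klass == "inframe_del":
            codon = int(rng.integers(2, n // 3 - 1))
            s, e = 3 * (codon - 1) + 1, 3 * codon
            v = CdnaVariant(
                "del",
                CdnaCoordinate("cds", s),
                CdnaCoordinate("cds", e),
                ref=cds[s - 1 : e],
            )
        else:
            raise GenerationError(f"unknown coding class {klass!r}")
        v = normalize_3prime(cds, v)
        call = call_consequence(model, v, normalized=True)
        if call.klass == klass:
            if klass == "frameshift" and call.protein_change.fs_term_offset is None:
                continue
            return v
    raise GenerationError(f"could not realize class {klass} on this transcript")


def _make_noncoding_variant(rng, model: TranscriptModel, region: str) -> CdnaVariant:
    if region == "utr3":
        utr3_len = model.mrna_length - model.cds_end_t
        base = int(rng.integers(1, utr3_len + 1))
        c = CdnaCoordinate("utr3", base)
    elif region == "intronic":
        # pick an intron and a position strictly inside it
        introns = []
        for a, b in zip(model.exons, model.exons[1:]):
            introns.append((a.end + 1, b.start - 1))
        lo, hi = introns[int(rng.integers(0, len(introns)))]
        pos = int(rng.integers(lo, hi + 1))
        c = model.genomic_to_cdna(pos)
    else:
        raise GenerationError(f"unknown noncoding region {region!r}")
    ref = str(rng.choice(list("ACGT")))
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return CdnaVariant("sub", c, c, ref=ref, alt=alt)


def _spread(rng, categories: dict[str, int]) -> list[str]:
    out = [cat for cat, n in categories.items() for _ in range(n)]
    rng.shuffle(out)
    return out


def generate_catalog_truth(
    seed: int,
    params: Optional[CatalogParams] = None,
    model: Optional[TranscriptModel] = None,
) -> TruthLedger:
    """Draw the distinct-variant catalog with engine-verified classes."""
    params = params or paper_aligned_params()
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    model = model or generate_transcript(seed)

    variants: list[TruthVariant] = []
    seen_keys: set = set()

    def add(variant: CdnaVariant, region: str, klass: str) -> bool:
        key = _cdna_to_vcf_style(model, variant)
        if key in seen_keys:
            return False
        seen_keys.add(key)
        variants.append(
            TruthVariant(
                index=len(variants),
                variant=variant,
                hgvs_c=format_c(variant),
                key=key,
                region=region,
                klass=klass,
                phenotype_category=NO_PHENOTYPE_DATA,
            )
        )
        return True

    for klass, count in params.exonic_classes.items():
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > 200 * count + 200:
                raise GenerationError(
                    f"transcript too small to host {count} distinct {klass} variants"
                )
            v = _make_coding_variant(rng, model, klass)
            if add(v, "exonic_cds", klass):
                made += 1
    exonic = list(variants)

    for region, count in (("utr3", params.n_utr3), ("intronic", params.n_intronic)):
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > 200 * count + 200:
                raise GenerationError(f"cannot place {count} {region} variants")
            v = _make_noncoding_variant(rng, model, region)
            if add(v, region, "noncoding"):
                made += 1
    noncoding = variants[len(exonic) :]

    # phenotype assignment — exonic
    exonic_labels = _spread(
        rng,
        {
            **params.exonic_ndd_mix,
            "NON_NDD": params.n_exonic_non_ndd,
            NO_PHENOTYPE_DATA: params.n_exonic_no_phenotype,
        },
    )
    for tv, label in zip(exonic, exonic_labels):
        tv.phenotype_category = label
        if label != NO_PHENOTYPE_DATA:
            pool = PHENOTYPE_POOLS[label]
            tv.phenotype_texts = [str(rng.choice(pool))]

    # phenotype assignment — noncoding
    nc_mix = dict(params.noncoding_mix)
    nc_mix[NO_PHENOTYPE_DATA] = (
        params.n_utr3 + params.n_intronic - sum(nc_mix.values())
    )
    for tv, label in zip(noncoding, _spread(rng, nc_mix)):
        tv.phenotype_category = label
        if label != NO_PHENOTYPE_DATA:
            tv.phenotype_texts = [str(rng.choice(PHENOTYPE_POOLS[label]))]

    # origin among exonic NDD variants
    ndd_exonic = [tv for tv in exonic if tv.phenotype_category in params.exonic_ndd_mix]
    order = list(rng.permutation(len(ndd_exonic)))
    for i in order[: params.n_de_novo]:
        ndd_exonic[i].origin_raw = "de novo"
        ndd_exonic[i].trio = True
    for i in order[params.n_de_novo : params.n_de_novo + params.n_inherited]:
        ndd_exonic[i].origin_raw = str(rng.choice(["maternal", "paternal"]))
        ndd_exonic[i].trio = True

    # reported pathogenicity: nonsynonymous exonic variants get a class text
    # with catalog-like weights; synonymous lean benign; some left blank
    for tv in exonic:
        if tv.klass == "synonymous":
            tv.reported_pathogenicity = str(rng.choice(["Likely benign", "Benign"]))
        elif rng.random() < 0.85:
            label = str(
                rng.choice(["P", "LP", "VUS", "LB", "B"], p=[0.3, 0.3, 0.25, 0.1, 0.05])
            )
            tv.reported_pathogenicity = _PATHOGENICITY_TEXTS[label]

    expected = {
        "n_distinct": len(variants),
        "n_exonic": len(exonic),
        "n_noncoding": len(noncoding),
        "class_counts": {
            k: sum(tv.klass == k for tv in variants)
            for k in (*params.exonic_classes, "noncoding")
        },
        "phenotype_counts": {
            cat: sum(tv.phenotype_category == cat for tv in variants)
            for cat in set(tv.phenotype_category for tv in variants)
        },
        "n_exonic_ndd": len(ndd_exonic),
        "n_de_novo": params.n_de_novo,
        "n_inherited": params.n_inherited,
        "pct_exonic_ndd": round(100 * len(ndd_exonic) / len(exonic))
        if exonic
        else 0,
    }
    return TruthLedger(model=model, variants=variants, expected=expected)


# ---------------------------------------------------------------------------
# Source export emission
# ---------------------------------------------------------------------------

DEFAULT_SOURCES: list[tuple[str, str, float]] = [
    # (source name, schema dialect, sampling weight ~ published entry shares)
    ("ClinVar", "clinvar_like", 0.34),
    ("AutDB", "generic", 0.12),
    ("Gene4denovo", "denovo_like", 0.11),
    ("SFARI", "generic", 0.11),
    ("LOVD", "lovd_like", 0.10),
    ("DECIPHER", "generic", 0.08),
    ("VariCarta", "generic", 0.06),
    ("Denovo-DB", "denovo_like", 0.04),
    ("DisGeNET", "lovd_like", 0.02),
    ("EGIdb", "generic", 0.01),
    ("DBD", "generic", 0.01),
]


def emit_source_exports(
    ledger: TruthLedger,
    out_dir: str | Path,
    seed: int,
    n_duplicate_records: int = 227,
    grch38_fraction: float = 0.3,
    sources: Optional[list[tuple[str, str, float]]] = None,
) -> dict:
    """Write per-source export files, the chain file and the truth tables.

    Every distinct variant is reported once; ``n_duplicate_records`` extra
    records re-report variants sampled with replacement, so the emitted
    record count is n_distinct + n_duplicate_records and a later
    coordinate-level dedup must recover exactly n_distinct. A
    ``grch38_fraction`` of coordinate-bearing records is shifted onto the
    toy GRCh38 and must round-trip through the emitted chain file.

    Returns a manifest: file paths, per-source dialects and expected counts.
    """
    sources = sources or DEFAULT_SOURCES
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = ledger.model

    weights = np.array([w for _, _, w in sources], dtype=float)
    weights /= weights.sum()
    dialect_of = {name: dial for name, dial, _ in sources}

    # record plan: one primary record per variant + sampled duplicates
    plan: list[int] = list(range(len(ledger.variants)))
    plan += [
        int(i)
        for i in rng.integers(0, len(ledger.variants), size=n_duplicate_records)
    ]
    rng.shuffle(plan)

    records: list[TruthRecord] = []
    rows_by_source: dict[str, list[dict]] = {name: [] for name, _, _ in sources}
    for serial, var_idx in enumerate(plan):
        tv = ledger.variants[var_idx]
        src = str(rng.choice([name for name, _, _ in sources], p=weights))
        dialect = dialect_of[src]
        # hgvs-free dialects can only carry substitutions; reroute indels
        if dialect == "denovo_like" and tv.variant.kind != "sub":
            src = "ClinVar"
            dialect = "clinvar_like"
        with_hgvs = dialect != "denovo_like"
        with_coords = dialect in ("clinvar_like", "denovo_like", "generic") and (
            tv.variant.kind == "sub"
        )
        assembly = (
            "GRCh38"
            if with_coords and rng.random() < grch38_fraction
            else "GRCh37"
        )
        record_id = f"{src[:3].upper()}{serial:05d}"
        records.append(
            TruthRecord(record_id, var_idx, src, assembly, with_coords, with_hgvs)
        )
        rows_by_source[src].append(
            _render_row(model, tv, record_id, dialect, assembly, with_coords, with_hgvs)
        )

    files: dict[str, str] = {}
    for name, dialect, _ in sources:
        spec = SCHEMA_DIALECTS[dialect]
        suffix = ".csv" if spec["delimiter"] == "," else ".tsv"
        path = out / f"{name}{suffix}"
        fieldnames = _dialect_fieldnames(dialect)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=fieldnames, delimiter=spec["delimiter"]
            )
            writer.writeheader()
            for row in rows_by_source[name]:
                writer.writerow(row)
        files[name] = str(path)

    # chain file: toy GRCh38 -> GRCh37 (constant negative offset)
    span_start = model.gene_span.start - 1_000 + GRCH38_OFFSET
    span_end = model.gene_span.end + 1_000 + GRCH38_OFFSET
    chain = constant_offset_chain(
        model.chrom,
        model.chrom,
        (span_start - 1, span_end),
        -GRCH38_OFFSET,
    )
    chain_path = out / "toy_hg38_to_hg19.chain"
    chain_path.write_text(format_chain(chain))

    transcript_path = out / "transcript.yaml"
    dump_transcript_config(model, transcript_path)

    ledger.records = records
    per_source = {name: len(rows_by_source[name]) for name, _, _ in sources}
    ledger.expected.update(
        {
            "n_records": len(records),
            "n_duplicate_records": len(records) - ledger.expected["n_distinct"],
            "per_source_records": per_source,
        }
    )

    _write_truth_tables(ledger, out)

    manifest = {
        "files": files,
        "dialects": dialect_of,
        "chain": str(chain_path),
        "transcript": str(transcript_path),
        "expected": ledger.expected,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _dialect_fieldnames(dialect: str) -> list[str]:
    spec = SCHEMA_DIALECTS[dialect]
    return list(dict.fromkeys(spec["columns"].values()))


def _render_row(
    model: TranscriptModel,
    tv: TruthVariant,
    record_id: str,
    dialect: str,
    assembly: str,
    with_coords: bool,
    with_hgvs: bool,
) -> dict:
    spec = SCHEMA_DIALECTS[dialect]
    colmap = spec["columns"]
    sep = spec.get("phenotype_sep", ";")
    values = {
        "record_id": record_id,
        "assembly": assembly if with_coords else "",
        "hgvs_c": tv.hgvs_c if with_hgvs else "",
        "phenotype": sep.join(tv.phenotype_texts),
        "pathogenicity": tv.reported_pathogenicity,
        "origin": tv.origin_raw,
        "trio": "yes" if tv.trio else "no",
        "allele_frequency": "",
        "chrom": "",
        "pos": "",
        "ref": "",
        "alt": "",
    }
    if with_coords:
        chrom, pos, ref, alt = tv.key
        if assembly == "GRCh38":
            pos += GRCH38_OFFSET
        values.update({"chrom": chrom, "pos": str(pos), "ref": ref, "alt": alt})
    row = {}
    for field_name, col in colmap.items():
        row[col] = values.get(field_name, "")
    return row


def _write_truth_tables(ledger: TruthLedger, out: Path) -> None:
    with open(out / "truth_variants.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [
                "index", "hgvs_c", "chrom", "pos", "ref", "alt", "region",
                "class", "phenotype_category", "origin", "trio",
                "reported_pathogenicity",
            ]
        )
        for tv in ledger.variants:
            chrom, pos, ref, alt = tv.key
            writer.writerow(
                [
                    tv.index, tv.hgvs_c, chrom, pos, ref, alt, tv.region,
                    tv.klass, tv.phenotype_category, tv.origin_raw,
                    "yes" if tv.trio else "no", tv.reported_pathogenicity,
                ]
            )
    with open(out / "truth_records.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["record_id", "variant_index", "source", "assembly"])
        for r in ledger.records:
            writer.writerow([r.record_id, r.variant_index, r.source, r.assembly])
    (out / "expected_counts.json").write_text(
        json.dumps(ledger.expected, indent=2, sort_keys=True)
    )


# ---------------------------------------------------------------------------
# CNV exports
# ---------------------------------------------------------------------------


@dataclass
class CnvParams:
    n_records: int = 73
    n_coordinate_duplicates: int = 11
    n_gains: int = 27  # distinct
    n_losses: int = 35  # distinct
    gain_size_range: tuple[int, int] = (5_000_000, 90_000_000)
    loss_size_range: tuple[int, int] = (1_400, 44_000_000)
    n_ndd: int = 36
    n_de_novo: int = 21
    n_lp_p: int = 32
    n_vus: int = 2
    gene: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chr16", 67_596_310, 67_673_088)
    )

    @property
    def n_distinct(self) -> int:
        return self.n_gains + self.n_losses

    def validate(self) -> None:
        if self.n_records != self.n_distinct + self.n_coordinate_duplicates:
            raise GenerationError(
                "n_records must equal distinct CNVs plus coordinate duplicates"
            )
        if self.n_ndd > self.n_distinct or self.n_de_novo > self.n_ndd:
            raise GenerationError("inconsistent CNV phenotype/origin counts")
        if self.n_lp_p + self.n_vus > self.n_ndd:
            raise GenerationError("pathogenicity counts exceed NDD CNVs")


def generate_cnv_exports(
    seed: int,
    params: Optional[CnvParams] = None,
    out_path: Optional[str | Path] = None,
) -> tuple[list[dict], dict]:
    """Generate CNV records overlapping the gene, with a truth ledger.

    Returns (rows, expected). Rows are plain dicts (chrom, start, end,
    dosage, origin, trio, pathogenicity, phenotype, source, record_id);
    written as TSV when ``out_path`` is given. The expected dict records the
    distinct count the dedup stage must recover.
    """
    params = params or CnvParams()
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    gene = params.gene

    def draw_interval(size_range: tuple[int, int]) -> tuple[int, int]:
        lo, hi = size_range
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if size >= len(gene):
            start_lo = max(1, gene.end - size + 1)
            start = int(rng.integers(start_lo, gene.start + 1))
        else:
            start = int(rng.integers(gene.start, gene.end - size + 2))
        return start, start + size - 1

    distinct: list[dict] = []
    seen: set = set()
    dosage_plan = ["gain"] * params.n_gains + ["loss"] * params.n_losses
    for dosage in dosage_plan:
        rng_range = (
            params.gain_size_range if dosage == "gain" else params.loss_size_range
        )
        while True:
            start, end = draw_interval(rng_range)
            if (start, end, dosage) not in seen:
                seen.add((start, end, dosage))
                break
        distinct.append(
            {
                "chrom": gene.chrom,
                "start": start,
                "end": end,
                "dosage": dosage,
                "origin": "",
                "trio": "no",
                "pathogenicity": "",
                "phenotype": "",
            }
        )

    # phenotype / origin / pathogenicity over distinct CNVs
    order = list(rng.permutation(params.n_distinct))
    ndd_idx = order[: params.n_ndd]
    n_non_ndd = min(6, params.n_distinct - params.n_ndd)
    non_ndd_idx = order[params.n_ndd : params.n_ndd + n_non_ndd]
    for i in ndd_idx:
        cat = str(rng.choice(["CRD", "DD"]))
        distinct[i]["phenotype"] = str(rng.choice(PHENOTYPE_POOLS[cat]))
    for i in non_ndd_idx:
        distinct[i]["phenotype"] = str(rng.choice(PHENOTYPE_POOLS["NON_NDD"]))
    for i in ndd_idx[: params.n_de_novo]:
        distinct[i]["origin"] = "de novo"
        distinct[i]["trio"] = "yes"
    patho = ["P"] * (params.n_lp_p // 2) + ["LP"] * (
        params.n_lp_p - params.n_lp_p // 2
    ) + ["VUS"] * params.n_vus
    for i, cls in zip(ndd_idx, patho):
        distinct[i]["pathogenicity"] = _PATHOGENICITY_TEXTS[cls]

    # duplicate records: exact-coordinate copies of earlier records
    dup_targets = rng.integers(0, params.n_distinct, size=params.n_coordinate_duplicates)
    rows = [dict(d) for d in distinct]
    rows += [dict(distinct[int(i)]) for i in dup_targets]
    perm = rng.permutation(len(rows))
    rows = [rows[int(i)] for i in perm]
    source_names = ["ClinVar", "DECIPHER", "LOVD"]
    for serial, row in enumerate(rows):
        row["source"] = str(rng.choice(source_names))
        row["record_id"] = f"CNV{serial:04d}"

    expected = {
        "n_records": len(rows),
        "n_distinct": params.n_distinct,
        "n_duplicates": params.n_coordinate_duplicates,
        "n_gains": params.n_gains,
        "n_losses": params.n_losses,
        "n_ndd": params.n_ndd,
        "n_de_novo": params.n_de_novo,
        "n_lp_p": params.n_lp_p,
        "n_vus": params.n_vus,
    }
    if out_path is not None:
        fieldnames = [
            "record_id", "source", "chrom", "start", "end", "dosage",
            "origin", "trio", "pathogenicity", "phenotype",
        ]
        with open(out_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t")
            writer.writeheader()
            for row in rows:
                writer.writerow(row)
    return rows, expected
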