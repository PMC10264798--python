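"""Copy-number variant curation: dedup, dosage, size and gene overlap.

CNV records are exact-coordinate entities: without patient identifiers,
records sharing (chrom, start, end, dosage) are indistinguishable reports of
the same event and are collapsed, keeping provenance. Dosage (gain/loss) is
part of the identity — a gain and a loss over the same interval are distinct
events. The catalog is gene-centric: records not overlapping the configured
gene are excluded with a reason. Translocations are unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pandas as pd

from .phenotype import NO_PHENOTYPE_DATA, is_ndd
from .transcript import GenomicInterval

DOSAGES = ("gain", "loss")


@dataclass(frozen=True)
class CnvRecord:
    interval: GenomicInterval  # GRCh37, 1-based closed
    dosage: str
    origin: str = "unknown"
    pathogenicity: Optional[str] = None
    phenotype_category: str = NO_PHENOTYPE_DATA
    provenance: tuple[str, ...] = ()
    record_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dosage not in DOSAGES:
            raise ValueError(f"dosage must be gain/loss, got {self.dosage!r}")

    @property
    def key(self) -> tuple:
        iv = self.interval
        return (iv.chrom, iv.start, iv.end, self.dosage)


def dedup_cnv(records: Iterable[CnvRecord]) -> tuple[list[CnvRecord], dict]:
    """Collapse records sharing exact coordinates and dosage.

    Returns the distinct records (first occurrence wins, provenance merged,
    in key order for determinism) and stats {n_records, n_duplicates,
    n_distinct} satisfying n_records = n_distinct + n_duplicates.
    """
    by_key: dict[tuple, CnvRecord] = {}
    n_records = 0
    for rec in records:
        n_records += 1
        if rec.key in by_key:
            kept = by_key[rec.key]
            merged = tuple(sorted(set(kept.provenance) | set(rec.provenance)))
            by_key[rec.key] = replace(kept, provenance=merged)
        else:
            by_key[rec.key] = rec
    distinct = [by_key[k] for k in sorted(by_key)]
    stats = {
        "n_records": n_records,
        "n_distinct": len(distinct),
        "n_duplicates": n_records - len(distinct),
    }
    return distinct, stats


def cnv_size(rec: CnvRecord) -> tuple[int, str]:
    """Size in bp plus a human-readable figure (24.8 Mb / 1.4 kb / 500 bp)."""
    bp = len(rec.interval)
    return bp, format_size(bp)


def format_size(bp: int) -> str:
    if bp >= 1_000_000:
        return f"{bp / 1_000_000:.1f} Mb"
    if bp >= 1_000:
        return f"{bp / 1_000:.1f} kb"
    return f"{bp} bp"


def parse_size_text(text: str) -> float:
    """Inverse of :func:`format_size` up to rounding, in bp."""
    value, unit = text.split()
    scale = {"bp": 1, "kb": 1_000, "Mb": 1_000_000}[unit]
    return float(value) * scale


def gene_overlap(rec: CnvRecord, gene: GenomicInterval) -> str:
    """contains_gene / partial / none relative to the gene interval."""
    iv = rec.interval
    if iv.chrom != gene.chrom:
        return "none"
    if iv.contains_interval(gene):
        return "contains_gene"
    if iv.overlaps(gene):
        return "partial"
    return "none"


def _phenotype_group(category: str) -> str:
    if is_ndd(category):
        return "NDD"
    if category == NO_PHENOTYPE_DATA:
        return "no_data"
    return "non_NDD"


def summarize_cnvs(records: Iterable[CnvRecord]) -> pd.DataFrame:
    """Counts and size ranges by dosage x phenotype group.

    One row per (dosage, phenotype_group) including zero rows, with count,
    min/max size in bp and human text, de novo count, and LP/P count.
    """
    records = list(records)
    groups = ["NDD", "non_NDD", "no_data"]
    rows = []
    for dosage in DOSAGES:
        for group in groups:
            members = [
                r
                for r in records
                if r.dosage == dosage and _phenotype_group(r.phenotype_category) == group
            ]
            sizes = [len(r.interval) for r in members]
            rows.append(
                {
                    "dosage": dosage,
                    "phenotype_group": group,
                    "count": len(members),
                    "min_size_bp": min(sizes) if sizes else 0,
                    "max_size_bp": max(sizes) if sizes else 0,
                    "min_size": format_size(min(sizes)) if sizes else "",
                    "max_size": format_size(max(sizes)) if sizes else "",
                    "n_de_novo": sum(r.origin == "de_novo" for r in members),
                    "n_lp_p": sum(r.pathogenicity in ("LP", "P") for r in members),
                    "n_vus": sum(r.pathogenicity == "VUS" for r in members),
                }
            )
    return pd.DataFrame(rows)


def read_cnv_table(path, assembly: str = "GRCh37") -> list[CnvRecord]:
    """Read a CNV TSV (chrom, start, end, dosage, [origin, pathogenicity,
    phenotype, source, record_id]); 1-based closed coordinates."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        records.append(
            CnvRecord(
                interval=GenomicInterval(
                    str(row["chrom"]), int(row["start"]), int(row["end"]), assembly
                ),
                dosage=str(row["dosage"]),
                origin=str(row.get("origin", "unknown") or "unknown"),
                pathogenicity=(row.get("pathogenicity") or None),
                phenotype_category=str(
                    row.get("phenotype_category", NO_PHENOTYPE_DATA)
                    or NO_PHENOTYPE_DATA
                ),
                provenance=tuple([row["source"]] if "source" in row and pd.notna(row["source"]) else []),
                record_id=row.get("record_id"),
            )
        )
    return records


def read_cnv_bed(path, assembly: str = "GRCh37") -> list[CnvRecord]:
    """BED-like reader: 0-based half-open converted to 1-based closed.

    Columns: chrom, start, end, dosage (in the BED name slot).
    """
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, dosage, *_ = line.split("\t")
            records.append(
                CnvRecord(
                    interval=GenomicInterval(chrom, int(start) + 1, int(end), assembly),
                    dosage=dosage,
                )
            )
    return records
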