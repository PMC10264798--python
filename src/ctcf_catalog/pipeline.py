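"""End-to-end drivers tying the stages together.

These functions are what the numbered analysis scripts, the test suite and
the acceptance checks call: generate or load exports, harmonize, curate,
and assemble the catalog bundle.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from .cnv import CnvRecord, dedup_cnv
from .curation import parse_reported_pathogenicity
from .harmonize import (
    CanonicalVariant,
    Exclusion,
    StandardizedRecord,
    deduplicate,
    ingest_source,
    standardize,
)
from .liftover import load_chain_file
from .phenotype import NO_PHENOTYPE_DATA, UNKNOWN, RuleSet, classify, load_rules
from .report import CatalogBundle, build_catalog
from .transcript import DomainMap, GenomicInterval, TranscriptModel, load_transcript_config


def harmonize_export_dir(
    export_dir: str | Path,
    model: Optional[TranscriptModel] = None,
    domain_map: Optional[DomainMap] = None,
) -> tuple[list[CanonicalVariant], dict, list[Exclusion]]:
    """Ingest + standardize + deduplicate a directory of source exports.

    The directory is expected to hold a manifest.json (as written by
    emit_source_exports, or hand-written to the same shape: files,
    dialects, chain, transcript).
    """
    export_dir = Path(export_dir)
    manifest = json.loads((export_dir / "manifest.json").read_text())
    chains = load_chain_file(manifest["chain"])
    if model is None:
        model = load_transcript_config(manifest["transcript"])
    records, exclusions = [], []
    for name in sorted(manifest["files"]):
        recs, excl = ingest_source(
            manifest["files"][name], manifest["dialects"][name], name
        )
        records.extend(recs)
        exclusions.extend(excl)
    standardized: list[StandardizedRecord] = []
    for rec in records:
        result = standardize(rec, chains, model, domain_map)
        if isinstance(result, Exclusion):
            exclusions.append(result)
        else:
            standardized.append(result)
    catalog, stats = deduplicate(standardized)
    stats["n_excluded"] = len(exclusions)
    stats["n_ingested"] = len(records) + sum(
        1 for e in exclusions if e.reason == "ambiguous"
    )
    return catalog, stats, exclusions


def curate_snv_catalog(
    catalog: list[CanonicalVariant],
    stats: dict,
    exclusions: list[Exclusion],
    rules: Optional[RuleSet] = None,
    cnvs: Optional[list[CnvRecord]] = None,
) -> CatalogBundle:
    rules = rules or load_rules()
    return build_catalog(catalog, rules, exclusions, stats, cnvs)


def curate_cnv_rows(
    rows: list[dict],
    rules: Optional[RuleSet] = None,
    gene: Optional[GenomicInterval] = None,
) -> tuple[list[CnvRecord], dict]:
    """Classify phenotype text, build CNV records and deduplicate.

    Rows are dicts with chrom/start/end/dosage/phenotype/origin/trio/
    pathogenicity/source keys (the synthetic export format, equally
    producible from any real-source column mapping).
    """
    rules = rules or load_rules()
    records = []
    for row in rows:
        category, _ = classify([row.get("phenotype", "")], rules)
        if category == UNKNOWN:
            category = NO_PHENOTYPE_DATA
        trio = str(row.get("trio", "")).lower() in ("1", "true", "yes", "y")
        origin = "de_novo" if (trio and str(row.get("origin", "")).strip().lower()
                               in ("de novo", "denovo")) else "unknown"
        records.append(
            CnvRecord(
                interval=GenomicInterval(
                    str(row["chrom"]), int(row["start"]), int(row["end"])
                ),
                dosage=str(row["dosage"]),
                origin=origin,
                pathogenicity=parse_reported_pathogenicity(
                    row.get("pathogenicity") or None
                ),
                phenotype_category=category,
                provenance=tuple([row["source"]]) if row.get("source") else (),
                record_id=row.get("record_id"),
            )
        )
    return dedup_cnv(records)
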