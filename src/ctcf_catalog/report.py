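"""Catalog assembly and tidy summary tables.

Takes every upstream stage's output and produces the final artifact: an
exonic NDD-associated SNV catalog (plus its unfiltered companion), the
noncoding SNV table, the CNV catalog, summary tables (phenotype proportions,
consequence classes, origin, pathogenicity, per-domain burden, per-residue
lollipop data) and an audit trail in which every ingested record is
accounted for exactly once.

Integer percentages use round-half-away-from-zero; raw fractions are always
emitted alongside, since published summaries round inconsistently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .cnv import CnvRecord, cnv_size
from .curation import (
    EXCLUDED,
    assign_origin,
    parse_reported_pathogenicity,
    reclassify_pathogenicity,
)
from .harmonize import CanonicalVariant, Exclusion
from .hgvs import format_p
from .phenotype import RuleSet, classify, is_ndd


def pct(numerator: int, denominator: int) -> int:
    """Integer percentage, rounding half away from zero (149/225 -> 66)."""
    if denominator == 0:
        return 0
    value = 100.0 * numerator / denominator
    return int(value + 0.5) if value >= 0 else -int(-value + 0.5)


def format_pct(numerator: int, denominator: int) -> str:
    return f"{pct(numerator, denominator)}%"


@dataclass
class CuratedVariant:
    variant: CanonicalVariant
    phenotype_category: str
    matched_patterns: list[str]
    origin: str
    pathogenicity: str  # recurated class or EXCLUDED
    reported_pathogenicity: Optional[str]
    decisions: list


@dataclass
class CatalogBundle:
    exonic_ndd: list[CuratedVariant]
    exonic_all: list[CuratedVariant]
    noncoding: list[CuratedVariant]
    cnvs: list[CnvRecord]
    exclusions: list[Exclusion]
    dedup_stats: dict
    filter_counts: dict  # ordered pipeline counts

    def accounted(self) -> int:
        return (
            self.dedup_stats.get("n_records", 0)
            + len(self.exclusions)
        )


def curate_variant(cv: CanonicalVariant, rules: RuleSet) -> CuratedVariant:
    category, patterns = classify(cv.phenotype_texts, rules)
    origin_raw = cv.origins[0] if cv.origins else ""
    origin = assign_origin(origin_raw, cv.trio_available)
    reported = None
    for text in cv.reported_pathogenicities:
        parsed = parse_reported_pathogenicity(text)
        if parsed is not None:
            reported = parsed
            break
    role = cv.consequence.residue_role
    klass = cv.consequence.klass
    new_class, decisions = reclassify_pathogenicity(klass, role, category, reported)
    return CuratedVariant(
        variant=cv,
        phenotype_category=category,
        matched_patterns=patterns,
        origin=origin,
        pathogenicity=new_class,
        reported_pathogenicity=reported,
        decisions=decisions,
    )


def build_catalog(
    catalog: list[CanonicalVariant],
    rules: RuleSet,
    exclusions: list[Exclusion],
    dedup_stats: dict,
    cnvs: Optional[list[CnvRecord]] = None,
) -> CatalogBundle:
    """Apply phenotype + curation rules and split the catalog into tables."""
    curated = [curate_variant(cv, rules) for cv in catalog]
    exonic_all = [c for c in curated if c.variant.consequence.region == "exonic_cds"]
    noncoding = [c for c in curated if c.variant.consequence.region != "exonic_cds"]
    # the NDD-association share is assessed over all exonic variants; the
    # synonymous exclusion (rule R1) then trims the pathogenic spectrum
    ndd_associated = [c for c in exonic_all if is_ndd(c.phenotype_category)]
    exonic_ndd = [c for c in ndd_associated if c.pathogenicity != EXCLUDED]
    filter_counts = {
        "distinct_variants": len(curated),
        "exonic": len(exonic_all),
        "exonic_ndd_associated": len(ndd_associated),
        "exonic_ndd_nonsynonymous": len(exonic_ndd),
        "pct_exonic_ndd": pct(len(ndd_associated), len(exonic_all)),
    }
    return CatalogBundle(
        exonic_ndd=exonic_ndd,
        exonic_all=exonic_all,
        noncoding=noncoding,
        cnvs=cnvs or [],
        exclusions=exclusions,
        dedup_stats=dedup_stats,
        filter_counts=filter_counts,
    )


# ---------------------------------------------------------------------------
# Tidy tables
# ---------------------------------------------------------------------------


def _proportion_table(labels: Iterable[str], label_name: str) -> pd.DataFrame:
    counts = pd.Series(list(labels), dtype=object).value_counts()
    total = int(counts.sum())
    df = pd.DataFrame(
        {
            label_name: counts.index,
            "count": counts.to_numpy(),
            "fraction": counts.to_numpy() / total if total else 0.0,
        }
    )
    df["percent"] = [pct(int(c), total) for c in df["count"]]
    return df.sort_values([label_name]).reset_index(drop=True)


def phenotype_table(variants: list[CuratedVariant]) -> pd.DataFrame:
    return _proportion_table(
        (v.phenotype_category for v in variants), "phenotype_category"
    )


def consequence_table(variants: list[CuratedVariant]) -> pd.DataFrame:
    return _proportion_table(
        (v.variant.consequence.klass for v in variants), "consequence_class"
    )


def origin_table(variants: list[CuratedVariant]) -> pd.DataFrame:
    return _proportion_table((v.origin for v in variants), "origin")


def pathogenicity_table(variants: list[CuratedVariant]) -> pd.DataFrame:
    return _proportion_table((v.pathogenicity for v in variants), "pathogenicity")


def domain_burden_table(variants: list[CuratedVariant]) -> pd.DataFrame:
    labels = []
    for v in variants:
        label = v.variant.consequence.domain_label
        labels.append(label if label else "unassigned")
    return _proportion_table(labels, "domain")


def lollipop_table(variants: list[CuratedVariant]) -> pd.DataFrame:
    """Per-residue plotting table for protein-level figures."""
    rows = []
    for v in variants:
        pc = v.variant.consequence.protein_change
        if pc is None:
            continue
        rows.append(
            {
                "residue": pc.first_residue,
                "protein_change": format_p(pc),
                "consequence_class": v.variant.consequence.klass,
                "domain": v.variant.consequence.domain_label or "",
                "residue_role": v.variant.consequence.residue_role or "",
                "pathogenicity": v.pathogenicity,
                "phenotype_category": v.phenotype_category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "residue", "protein_change", "consequence_class", "domain",
            "residue_role", "pathogenicity", "phenotype_category",
        ],
    ).sort_values(["residue", "protein_change"]).reset_index(drop=True)


def summarize(bundle: CatalogBundle) -> dict[str, pd.DataFrame]:
    ndd = bundle.exonic_ndd
    return {
        "phenotype": phenotype_table(ndd),
        "consequence": consequence_table(ndd),
        "origin": origin_table(ndd),
        "pathogenicity": pathogenicity_table(ndd),
        "domain_burden": domain_burden_table(ndd),
        "lollipop": lollipop_table(ndd),
    }


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------


def catalog_frame(variants: list[CuratedVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        cv = v.variant
        pc = cv.consequence.protein_change
        rows.append(
            {
                "chrom": cv.chrom,
                "pos": cv.pos,
                "ref": cv.ref,
                "alt": cv.alt,
                "hgvs_c": cv.hgvs_c,
                "hgvs_p": format_p(pc) if pc else "",
                "region": cv.consequence.region,
                "consequence_class": cv.consequence.klass,
                "domain": cv.consequence.domain_label or "",
                "residue_role": cv.consequence.residue_role or "",
                "phenotype_category": v.phenotype_category,
                "matched_patterns": "|".join(v.matched_patterns),
                "origin": v.origin,
                "reported_pathogenicity": v.reported_pathogenicity or "",
                "pathogenicity": v.pathogenicity,
                "n_records": cv.n_records,
                "sources": "|".join(sorted(cv.provenance)),
                "conflicting": cv.conflicting,
            }
        )
    cols = [
        "chrom", "pos", "ref", "alt", "hgvs_c", "hgvs_p", "region",
        "consequence_class", "domain", "residue_role", "phenotype_category",
        "matched_patterns", "origin", "reported_pathogenicity",
        "pathogenicity", "n_records", "sources", "conflicting",
    ]
    return pd.DataFrame(rows, columns=cols)


def cnv_frame(records: list[CnvRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        bp, human = cnv_size(r)
        rows.append(
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "dosage": r.dosage,
                "size_bp": bp,
                "size": human,
                "origin": r.origin,
                "pathogenicity": r.pathogenicity or "",
                "phenotype_category": r.phenotype_category,
                "sources": "|".join(r.provenance),
            }
        )
    cols = [
        "chrom", "start", "end", "dosage", "size_bp", "size",
        "origin", "pathogenicity", "phenotype_category", "sources",
    ]
    return pd.DataFrame(rows, columns=cols)


def audit_frame(exclusions: list[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"record_id": e.record_id, "source": e.source, "reason": e.reason}
            for e in exclusions
        ],
        columns=["record_id", "source", "reason"],
    )


def write_bundle(
    bundle: CatalogBundle,
    out_dir: str | Path,
    manifest: Optional[dict] = None,
) -> None:
    """Write the catalog bundle as deterministic TSVs plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog_frame(bundle.exonic_ndd).to_csv(
        out / "exonic_ndd_catalog.tsv", sep="\t", index=False
    )
    catalog_frame(bundle.exonic_all).to_csv(
        out / "exonic_full_catalog.tsv", sep="\t", index=False
    )
    catalog_frame(bundle.noncoding).to_csv(
        out / "noncoding_snv_table.tsv", sep="\t", index=False
    )
    cnv_frame(bundle.cnvs).to_csv(out / "cnv_catalog.tsv", sep="\t", index=False)
    audit_frame(bundle.exclusions).to_csv(out / "audit_log.tsv", sep="\t", index=False)
    for name, df in summarize(bundle).items():
        df.to_csv(out / f"summary_{name}.tsv", sep="\t", index=False)
    decisions = []
    for v in bundle.exonic_all + bundle.noncoding:
        for d in v.decisions:
            decisions.append(
                {
                    "hgvs_c": v.variant.hgvs_c,
                    "field": d.field,
                    "before": d.before,
                    "after": d.after,
                    "rule_id": d.rule_id,
                    "rationale": d.rationale,
                }
            )
    pd.DataFrame(
        decisions,
        columns=["hgvs_c", "field", "before", "after", "rule_id", "rationale"],
    ).to_csv(out / "decisions.tsv", sep="\t", index=False)
    info = {"filter_counts": bundle.filter_counts, "dedup_stats": bundle.dedup_stats}
    if manifest:
        info["manifest"] = manifest
    (out / "run_manifest.json").write_text(json.dumps(info, indent=2, sort_keys=True))
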