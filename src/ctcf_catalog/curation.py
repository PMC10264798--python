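"""Explicit recuration rules: origin, pathogenicity, allele-frequency class.

This is deliberately not an ACMG engine. The rule set encodes the specific,
auditable decisions applied when recurating the catalog:

    R1  synonymous variants are excluded from the pathogenic spectrum
        (a synonymous CTCF change being causal is considered implausible);
    R2  missense changes at zinc-coordinating Cys/His residues are rated at
        least likely pathogenic (loss of zinc coordination abolishes DNA
        binding); an already-reported P is retained;
    R3  missense variants reported benign/likely-benign yet associated with
        an NDD phenotype are reset to VUS;
    R4  variants with no reported class default to VUS (unless R2 applied).

Rules are ordered, idempotent, and never downgrade a reported P/LP
(severity order P > LP > VUS > LB > B). Every change is logged as a
:class:`CurationDecision` row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .phenotype import is_ndd

PATHOGENICITY_CLASSES = ("B", "LB", "VUS", "LP", "P")
EXCLUDED = "EXCLUDED"

_SEVERITY = {c: i for i, c in enumerate(PATHOGENICITY_CLASSES)}

_REPORTED_SYNONYMS = {
    "pathogenic": "P",
    "p": "P",
    "likely pathogenic": "LP",
    "lp": "LP",
    "pathogenic/likely pathogenic": "LP",
    "uncertain significance": "VUS",
    "vus": "VUS",
    "variant of unknown significance": "VUS",
    "uncertain": "VUS",
    "likely benign": "LB",
    "lb": "LB",
    "benign": "B",
    "b": "B",
    "benign/likely benign": "LB",
}

_DE_NOVO_TERMS = {"de novo", "denovo", "dn", "germline de novo", "de-novo"}
_INHERITED_TERMS = {
    "inherited", "maternal", "paternal", "maternally inherited",
    "paternally inherited", "transmitted", "familial",
}


@dataclass(frozen=True)
class CurationDecision:
    field: str  # origin | pathogenicity | af_class | catalog_membership
    before: str
    after: str
    rule_id: str
    rationale: str


def parse_reported_pathogenicity(text: Optional[str]) -> Optional[str]:
    """Map free-text reported significance onto {B, LB, VUS, LP, P} or None."""
    if text is None or not text.strip():
        return None
    key = text.strip().lower().replace("_", " ")
    return _REPORTED_SYNONYMS.get(key)


def assign_origin(origin_raw: Optional[str], trio_available: bool) -> str:
    """De novo / inherited only with a source statement plus trio confirmation."""
    text = (origin_raw or "").strip().lower()
    if not text or not trio_available:
        return "unknown"
    if text in _DE_NOVO_TERMS:
        return "de_novo"
    if text in _INHERITED_TERMS:
        return "inherited"
    return "unknown"


def classify_af(af: float) -> str:
    """Rare iff allele frequency < 0.05; the boundary itself is common."""
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    return "rare" if af < 0.05 else "common"


def reclassify_pathogenicity(
    klass: str,
    residue_role: Optional[str],
    phenotype_category: str,
    reported: Optional[str],
) -> tuple[str, list[CurationDecision]]:
    """Apply rules R1-R4 to one variant.

    Parameters are the consequence class, the residue role from the domain
    map, the phenotype category, and the parsed reported class (or None).
    Returns the recurated class (or EXCLUDED) plus the decision log.
    """
    decisions: list[CurationDecision] = []
    before = reported or "none"

    if klass == "synonymous":
        decisions.append(
            CurationDecision(
                "pathogenicity", before, EXCLUDED, "R1",
                "synonymous variant removed from pathogenic spectrum",
            )
        )
        return EXCLUDED, decisions

    current = reported
    r2_applied = False
    if klass == "missense" and residue_role in (
        "zinc_coordinating_cys",
        "zinc_coordinating_his",
    ):
        if current is None or _SEVERITY[current] < _SEVERITY["LP"]:
            decisions.append(
                CurationDecision(
                    "pathogenicity", before, "LP", "R2",
                    "missense at zinc-coordinating residue rated at least LP",
                )
            )
            current = "LP"
        r2_applied = True

    if (
        not r2_applied
        and klass == "missense"
        and current in ("LB", "B")
        and is_ndd(phenotype_category)
    ):
        decisions.append(
            CurationDecision(
                "pathogenicity", before, "VUS", "R3",
                "benign-reported missense with NDD phenotype reset to VUS",
            )
        )
        current = "VUS"

    if current is None:
        decisions.append(
            CurationDecision(
                "pathogenicity", before, "VUS", "R4",
                "no reported class; defaulted to VUS",
            )
        )
        current = "VUS"

    return current, decisions
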