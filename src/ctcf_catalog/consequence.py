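"""Apply a cDNA variant to the coding sequence and call its protein effect.

The classifier compares the wild-type and mutant open reading frames and
assigns one of: synonymous, missense, nonsense, frameshift (with the fs*N
termination offset), inframe_del, inframe_ins, start_lost, stop_lost. It
runs after 3' normalization, so events inside repeats are reported at their
3'-most position — which is why a duplication like CTCF c.604dup reports the
threonine codon it finally lands in rather than the first repeat copy.

UTR and intronic variants receive a region label only (class "noncoding");
splice-effect prediction is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Data.CodonTable import standard_dna_table

from .hgvs import CdnaVariant, ProteinChange, ReferenceMismatchError, normalize_3prime
from .transcript import DomainMap, TranscriptModel, codon_of

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


class ConfigurationError(RuntimeError):
    """A coding call was requested on a model without a CDS sequence."""


def translate(seq: str) -> tuple[str, bool]:
    """Translate successive codons until a stop codon or sequence end.

    Returns (amino-acid string excluding the stop, stop_reached). A trailing
    partial codon is ignored. Non-ACGT characters raise ValueError.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT character in sequence")
    protein = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = _CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            return "".join(protein), True
        protein.append(aa)
    return "".join(protein), False


def apply_variant(cds_seq: str, v: CdnaVariant) -> str:
    """Edited CDS string after applying a coding variant."""
    cds_seq = cds_seq.upper()
    if not v.is_coding:
        raise ValueError("apply_variant edits coding positions only")
    s, e = v.span()
    # an insertion may sit between the last base and the sequence end
    limit = s if v.kind == "ins" else e
    if limit > len(cds_seq):
        raise ReferenceMismatchError(f"span {s}-{e} beyond CDS length {len(cds_seq)}")
    if v.kind == "sub":
        if cds_seq[s - 1] != v.ref:
            raise ReferenceMismatchError(
                f"stated ref {v.ref} != transcript {cds_seq[s - 1]} at c.{s}"
            )
        return cds_seq[: s - 1] + v.alt + cds_seq[s:]
    if v.kind in ("del", "dup", "delins") and v.ref:
        if cds_seq[s - 1 : e] != v.ref:
            raise ReferenceMismatchError(
                f"stated ref {v.ref} != transcript {cds_seq[s - 1:e]} at c.{s}"
            )
    if v.kind == "del":
        return cds_seq[: s - 1] + cds_seq[e:]
    if v.kind == "dup":
        return cds_seq[:e] + cds_seq[s - 1 : e] + cds_seq[e:]
    if v.kind == "ins":
        return cds_seq[:s] + v.alt + cds_seq[s:]
    return cds_seq[: s - 1] + v.alt + cds_seq[e:]  # delins


@dataclass(frozen=True)
class ConsequenceCall:
    region: str  # exonic_cds | utr5 | utr3 | intronic
    klass: str  # synonymous | missense | nonsense | frameshift | inframe_del
    #           | inframe_ins | start_lost | stop_lost | noncoding
    protein_change: Optional[ProteinChange] = None
    domain_label: Optional[str] = None
    residue_role: Optional[str] = None

    def __post_init__(self) -> None:
        coding = self.region == "exonic_cds"
        if coding != (self.protein_change is not None) and self.klass not in (
            "start_lost",
            "stop_lost",
        ):
            raise ValueError("protein_change present iff region is exonic_cds")
        if (self.klass == "noncoding") != (not coding):
            raise ValueError("klass noncoding iff region is not exonic_cds")


def _region_of(v: CdnaVariant) -> str:
    if v.start.kind == "intronic" or v.end.kind == "intronic":
        return "intronic"
    if v.is_coding:
        return "exonic_cds"
    return v.start.kind  # utr5 / utr3


def call_consequence(
    model: TranscriptModel,
    v: CdnaVariant,
    domain_map: Optional[DomainMap] = None,
    normalized: bool = False,
) -> ConsequenceCall:
    """Classify a parsed cDNA variant against the transcript model."""
    region = _region_of(v)
    if region != "exonic_cds":
        return ConsequenceCall(region=region, klass="noncoding")
    if model.cds_sequence is None:
        raise ConfigurationError(
            f"coding variant on {model.transcript_id} but no CDS sequence configured"
        )
    cds = model.cds_sequence
    if not normalized:
        v = normalize_3prime(cds, v)
    mutant = apply_variant(cds, v)
    pc = _diff_proteins(cds, mutant, v)
    domain_label = role = None
    if domain_map is not None and pc.kind not in ("no_protein",):
        residue = min(pc.first_residue, domain_map.protein_length)
        domain_label = domain_map.domain_of(residue)
        role = domain_map.residue_role(residue)
    return ConsequenceCall(
        region="exonic_cds",
        klass=pc.kind if pc.kind != "no_protein" else "start_lost",
        protein_change=pc,
        domain_label=domain_label,
        residue_role=role,
    )


def _diff_proteins(cds: str, mutant: str, v: CdnaVariant) -> ProteinChange:
    wt, wt_stop = translate(cds)
    mt, mt_stop = translate(mutant)
    length_change = len(mutant) - len(cds)

    if not mutant.startswith("ATG"):
        return ProteinChange("start_lost", 1, ref_aa="M")

    if mt == wt and mt_stop:
        # identical protein: synonymous at the (first) affected codon
        s, _ = v.span()
        residue, _ = codon_of(s)
        residue = min(residue, len(wt))
        ref = wt[residue - 1] if residue <= len(wt) else "*"
        return ProteinChange("synonymous", residue, ref_aa=ref)

    # first differing residue (0-based) over the aligned prefix
    i = 0
    while i < min(len(wt), len(mt)) and wt[i] == mt[i]:
        i += 1

    if length_change % 3 != 0:
        # frame change; an immediate stop at the first affected codon is a
        # nonsense call (HGVS reports substitutions-to-Ter, not fs*1)
        if i == len(mt) and mt_stop:
            return ProteinChange("nonsense", i + 1, ref_aa=wt[i], alt_aa="*")
        if i == len(wt):
            # frameshift starting at the stop codon extends the protein
            alt = mt[i] if i < len(mt) else "?"
            return ProteinChange("stop_lost", len(wt) + 1, ref_aa="*", alt_aa=alt)
        if i >= len(mt) and not mt_stop:
            # ran off the end without a new residue or stop
            return ProteinChange(
                "frameshift", i + 1, ref_aa=wt[i], alt_aa="?", fs_term_offset=None
            )
        offset = len(mt) - i + 1 if mt_stop else None
        return ProteinChange(
            "frameshift", i + 1, ref_aa=wt[i], alt_aa=mt[i], fs_term_offset=offset
        )

    # frame preserved
    if not mt_stop and wt_stop:
        alt = mt[i] if i < len(mt) else ""
        return ProteinChange("stop_lost", len(wt) + 1, ref_aa="*", alt_aa=alt)
    if len(mt) == len(wt):
        if i == len(mt):
            return ProteinChange("synonymous", max(i, 1), ref_aa=wt[-1] if wt else "M")
        if mt[i] == "*":
            return ProteinChange("nonsense", i + 1, ref_aa=wt[i], alt_aa="*")
        # single or multiple substituted residues; report the first
        return ProteinChange("missense", i + 1, ref_aa=wt[i], alt_aa=mt[i])
    if len(mt) < len(wt):
        k = len(wt) - len(mt)
        clean_deletion = length_change < 0 and k == -length_change // 3
        if i == len(mt) and not clean_deletion:
            # truncation by an early stop with frame intact
            return ProteinChange("nonsense", i + 1, ref_aa=wt[i], alt_aa="*")
        # residues deleted: block of k starting at the 3'-most equivalent j
        j = i
        while j + k < len(wt) and wt[j] == wt[j + k]:
            j += 1
        deleted = wt[j : j + k]
        return ProteinChange(
            "inframe_del",
            j + 1,
            ref_aa=deleted,
            last_residue=j + k if k > 1 else None,
        )
    # len(mt) > len(wt): in-frame insertion/duplication
    k = len(mt) - len(wt)
    if i == len(wt) and not wt_stop:
        return ProteinChange("stop_lost", len(wt) + 1, ref_aa="*", alt_aa=mt[i])
    # 3'-most equivalent placement of the inserted block
    j = i
    while j < len(wt) and mt[j] == mt[j + k]:
        j += 1
    inserted = mt[j : j + k]
    return ProteinChange(
        "inframe_ins",
        j,  # residue preceding the insertion (0 = before residue 1)
        ref_aa=wt[j - 1] if j >= 1 else "",
        alt_aa=inserted,
        last_residue=j + 1,
    )
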