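"""HGVS coding-DNA and protein descriptions: parse, normalize, format.

Covers the subset of the nomenclature that occurs in curated CTCF catalogs:
substitutions, deletions, duplications, insertions and deletion-insertions
at the c. level, with UTR (c.-N / c.*N) and intronic (c.N+M / c.N-M)
addressing, and 3-letter-code protein descriptions including frameshifts
(p.Thr204Asnfs*25 style). Deliberately out of scope: g./n. descriptions,
inversions, repeat notation and uncertainty brackets — records using them
are excluded upstream with an audit reason.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .transcript import CdnaCoordinate


class HgvsParseError(ValueError):
    """Malformed HGVS text; the message names the offending token."""


class UnsupportedKindError(ValueError):
    """Syntactically valid HGVS of a kind outside the supported subset."""


class ReferenceMismatchError(ValueError):
    """Stated reference bases disagree with the transcript sequence."""


_NT = re.compile(r"^[ACGT]*$")


@dataclass(frozen=True)
class CdnaVariant:
    """A parsed c. description.

    ``ref`` holds the stated reference bases ("" when not given, as in bare
    "c.804_805del"); ``alt`` holds inserted/substituted bases ("" for
    del/dup).
    """

    kind: str  # sub | del | dup | ins | delins
    start: CdnaCoordinate
    end: CdnaCoordinate
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("sub", "del", "dup", "ins", "delins"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if not _NT.match(self.ref) or not _NT.match(self.alt):
            raise ValueError("ref/alt must be ACGT strings")
        if self.start.sort_key() > self.end.sort_key():
            raise ValueError("start after end in transcript order")
        if self.kind == "sub" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("substitution requires single ref and alt bases")
        if self.kind == "ins":
            if not self.alt:
                raise ValueError("insertion requires inserted bases")
            adjacent = (
                self.start.kind == self.end.kind == "cds"
                and self.end.base == self.start.base + 1
            )
            if self.start.kind == "cds" and not adjacent:
                raise ValueError("insertion flanks must be adjacent positions")
        if self.kind in ("del", "dup") and self.alt:
            raise ValueError(f"{self.kind} carries no alt bases")
        if self.kind == "delins" and not self.alt:
            raise ValueError("delins requires inserted bases")

    @property
    def is_coding(self) -> bool:
        return self.start.kind == "cds" and self.end.kind == "cds"

    def span(self) -> tuple[int, int]:
        """CDS start/end base (coding variants only)."""
        if not self.is_coding:
            raise ValueError("span() applies to coding variants")
        return self.start.base, self.end.base


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_POS = r"(?:[-*]?\d+(?:[+-]\d+)?)"
_SUB_RE = re.compile(rf"^c\.({_POS})([ACGT])>([ACGT])$")
_INDEL_RE = re.compile(
    rf"^c\.({_POS})(?:_({_POS}))?(delins|del|dup|ins)([ACGT]*)$"
)
_UNSUPPORTED_RE = re.compile(rf"^c\.({_POS})(?:_({_POS}))?(inv|con|\[\d+\])")


def _parse_pos(text: str) -> CdnaCoordinate:
    m = re.match(r"^([-*]?)(\d+)([+-]\d+)?$", text)
    if not m:
        raise HgvsParseError(f"bad cDNA position {text!r}")
    prefix, base, off = m.groups()
    kind = {"-": "utr5", "*": "utr3", "": "cds"}[prefix]
    if off:
        return CdnaCoordinate("intronic", int(base), int(off), anchor=kind)
    return CdnaCoordinate(kind, int(base))


def parse_c(text: str) -> CdnaVariant:
    """Parse an HGVS c. description into a :class:`CdnaVariant`."""
    text = text.strip()
    if not text.startswith("c."):
        raise HgvsParseError(f"not a c. description: {text!r}")
    m = _SUB_RE.match(text)
    if m:
        pos = _parse_pos(m.group(1))
        return CdnaVariant("sub", pos, pos, ref=m.group(2), alt=m.group(3))
    if _UNSUPPORTED_RE.match(text):
        raise UnsupportedKindError(f"unsupported variant kind in {text!r}")
    m = _INDEL_RE.match(text)
    if m:
        start_txt, end_txt, op, seq = m.groups()
        start = _parse_pos(start_txt)
        end = _parse_pos(end_txt) if end_txt else start
        if op == "ins":
            if not seq:
                raise HgvsParseError(f"insertion without bases in {text!r}")
            if end_txt is None:
                raise HgvsParseError(f"insertion needs flanking positions: {text!r}")
            return CdnaVariant("ins", start, end, alt=seq)
        if op == "delins":
            if not seq:
                raise HgvsParseError(f"delins without inserted bases in {text!r}")
            return CdnaVariant("delins", start, end, alt=seq)
        # del / dup; trailing bases, if any, state the ref
        if seq and end_txt:
            expected = _span_length(start, end)
            if expected is not None and expected != len(seq):
                raise HgvsParseError(
                    f"ref length {len(seq)} does not match span in {text!r}"
                )
        return CdnaVariant(op, start, end, ref=seq)
    raise HgvsParseError(f"cannot parse HGVS description {text!r}")


def _span_length(start: CdnaCoordinate, end: CdnaCoordinate) -> Optional[int]:
    if start.kind == end.kind == "cds":
        return end.base - start.base + 1
    if start.kind == end.kind == "utr3":
        return end.base - start.base + 1
    if start.kind == end.kind == "utr5":
        return start.base - end.base + 1
    return None


# ---------------------------------------------------------------------------
# Formatting
# ---------------------------------------------------------------------------


def format_c(v: CdnaVariant) -> str:
    """Canonical c. string. Ref bases are kept when known (c.604dupA)."""
    s, e = str(v.start), str(v.end)
    rng = s if (v.start == v.end and v.kind != "ins") else f"{s}_{e}"
    if v.kind == "sub":
        return f"c.{s}{v.ref}>{v.alt}"
    if v.kind in ("del", "dup"):
        return f"c.{rng}{v.kind}{v.ref}"
    if v.kind == "ins":
        return f"c.{s}_{e}ins{v.alt}"
    return f"c.{rng}delins{v.alt}"


# ---------------------------------------------------------------------------
# 3' normalization
# ---------------------------------------------------------------------------


def normalize_3prime(cds_seq: str, v: CdnaVariant) -> CdnaVariant:
    """Shift del/dup/ins to their most 3' equivalent representation.

    Two descriptions are equivalent when applying them to ``cds_seq`` yields
    the same mutated string; HGVS mandates reporting the 3'-most one.
    Substitutions and delins never shift. Idempotent. Raises
    :class:`ReferenceMismatchError` when stated ref bases disagree with the
    sequence.
    """
    cds_seq = cds_seq.upper()
    if v.kind in ("sub", "delins"):
        _check_ref(cds_seq, v)
        return v
    if not v.is_coding:
        return v  # UTR/intronic: no transcript sequence to shift against
    n = len(cds_seq)
    if v.kind in ("del", "dup"):
        s, e = v.span()
        if e > n:
            raise ReferenceMismatchError(f"span {s}-{e} beyond CDS length {n}")
        if v.ref and cds_seq[s - 1 : e] != v.ref:
            raise ReferenceMismatchError(
                f"stated ref {v.ref} != transcript {cds_seq[s - 1:e]} at c.{s}"
            )
        while e < n and cds_seq[s - 1] == cds_seq[e]:
            s += 1
            e += 1
        return CdnaVariant(
            v.kind,
            CdnaCoordinate("cds", s),
            CdnaCoordinate("cds", e),
            ref=cds_seq[s - 1 : e],
        )
    # insertion between s and s+1
    s = v.start.base
    alt = v.alt
    while s < n and alt[0] == cds_seq[s]:
        alt = alt[1:] + alt[0]
        s += 1
    k = len(alt)
    if s >= k and cds_seq[s - k : s] == alt:
        # insertion of a copy of the immediately preceding bases is a dup
        return CdnaVariant(
            "dup",
            CdnaCoordinate("cds", s - k + 1),
            CdnaCoordinate("cds", s),
            ref=alt,
        )
    return CdnaVariant(
        "ins", CdnaCoordinate("cds", s), CdnaCoordinate("cds", s + 1), alt=alt
    )


def _check_ref(cds_seq: str, v: CdnaVariant) -> None:
    if not v.is_coding or not v.ref:
        return
    s, e = v.span()
    if e > len(cds_seq):
        raise ReferenceMismatchError(f"span {s}-{e} beyond CDS length {len(cds_seq)}")
    if cds_seq[s - 1 : e] != v.ref:
        raise ReferenceMismatchError(
            f"stated ref {v.ref} != transcript {cds_seq[s - 1:e]} at c.{s}"
        )


# ---------------------------------------------------------------------------
# Protein change
# ---------------------------------------------------------------------------

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}
AA1 = {three: one for one, three in AA3.items()}


def aa3(one_letter: str) -> str:
    return "".join(AA3[c] for c in one_letter)


@dataclass(frozen=True)
class ProteinChange:
    """A protein-level consequence in HGVS p. terms."""

    kind: str  # missense | synonymous | nonsense | frameshift | inframe_del
    #          | inframe_ins | start_lost | stop_lost | no_protein
    first_residue: int
    ref_aa: str = ""  # 1-letter; may span several residues for inframe events
    alt_aa: str = ""
    fs_term_offset: Optional[int] = None  # the N of fs*N; None = no stop found
    last_residue: Optional[int] = None  # for multi-residue inframe events

    def __post_init__(self) -> None:
        if self.fs_term_offset is not None:
            if self.kind != "frameshift":
                raise ValueError("fs_term_offset only applies to frameshifts")
            if self.fs_term_offset < 2:
                raise ValueError(
                    "a frameshift stopping at the changed residue is a nonsense call"
                )


def format_p(pc: ProteinChange) -> str:
    """Render a ProteinChange in the 3-letter-code style used in catalogs."""
    r = pc.first_residue
    if pc.kind == "synonymous":
        return f"p.{aa3(pc.ref_aa)}{r}="
    if pc.kind == "missense":
        return f"p.{aa3(pc.ref_aa)}{r}{aa3(pc.alt_aa)}"
    if pc.kind == "nonsense":
        return f"p.{aa3(pc.ref_aa)}{r}Ter"
    if pc.kind == "frameshift":
        n = str(pc.fs_term_offset) if pc.fs_term_offset is not None else "?"
        return f"p.{aa3(pc.ref_aa[0])}{r}{aa3(pc.alt_aa[0])}fs*{n}"
    if pc.kind == "inframe_del":
        if pc.last_residue is None or pc.last_residue == r:
            return f"p.{aa3(pc.ref_aa[0])}{r}del"
        return f"p.{aa3(pc.ref_aa[0])}{r}_{aa3(pc.ref_aa[-1])}{pc.last_residue}del"
    if pc.kind == "inframe_ins":
        if pc.last_residue is None:
            return f"p.{aa3(pc.ref_aa)}{r}ins{aa3(pc.alt_aa)}"
        return (
            f"p.{aa3(pc.ref_aa[0])}{r}_{aa3(pc.ref_aa[-1])}{pc.last_residue}"
            f"ins{aa3(pc.alt_aa)}"
        )
    if pc.kind == "start_lost":
        return "p.Met1?"
    if pc.kind == "stop_lost":
        return f"p.Ter{r}{aa3(pc.alt_aa)}ext*?"
    return "p.0"  # no_protein


_P_SUB_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)(=|Ter|[A-Z][a-z]{2})$")
_P_FS_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})fs\*(\d+|\?)$")


def parse_p(text: str) -> ProteinChange:
    """Parse the simple p. forms the formatter emits (sub/syn/ter/fs)."""
    text = text.strip()
    m = _P_FS_RE.match(text)
    if m:
        ref, pos, alt, n = m.groups()
        return ProteinChange(
            "frameshift",
            int(pos),
            ref_aa=AA1[ref],
            alt_aa=AA1[alt],
            fs_term_offset=None if n == "?" else int(n),
        )
    m = _P_SUB_RE.match(text)
    if m:
        ref, pos, alt = m.groups()
        if alt == "=":
            return ProteinChange("synonymous", int(pos), ref_aa=AA1[ref])
        if alt == "Ter":
            return ProteinChange("nonsense", int(pos), ref_aa=AA1[ref], alt_aa="*")
        return ProteinChange("missense", int(pos), ref_aa=AA1[ref], alt_aa=AA1[alt])
    raise HgvsParseError(f"cannot parse protein description {text!r}")
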