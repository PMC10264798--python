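"""Transcript geometry: genomic <-> cDNA coordinate mapping and domain annotation.

The transcript model is the coordinate oracle for the whole pipeline: every
variant is ultimately described against a single canonical transcript (for
CTCF, RefSeq NM_006565.4 / Ensembl ENST00000264010.4 on GRCh37). Genomic
coordinates are 1-based and fully closed everywhere in the data model —
the convention under which the printed CTCF gene span
chr16:67,596,310-67,673,088 measures 76,779 bp. Conversion to 0-based
half-open systems happens only inside file readers/writers (chain, BED).

cDNA ("c.") addresses follow HGVS: c.N for coding bases, c.-N counting back
from the base before c.1 (5'UTR), c.*N counting forward from the base after
the stop codon (3'UTR), and c.N+M / c.N-M for intronic bases anchored to the
nearest exon edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

GRCH37 = "GRCh37"
GRCH38 = "GRCh38"


class CoordinateError(ValueError):
    """Raised for invalid intervals or positions outside the transcript."""


# ---------------------------------------------------------------------------
# Genomic intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully-closed genomic interval on a named assembly."""

    chrom: str
    start: int
    end: int
    assembly: str = GRCH37

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.start < 1:
            raise CoordinateError("genomic coordinates are 1-based; start < 1")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a 1-based closed interval (end - start + 1)."""
    return len(iv)


# ---------------------------------------------------------------------------
# cDNA coordinates
# ---------------------------------------------------------------------------

_KINDS = ("cds", "utr5", "utr3", "intronic")


@dataclass(frozen=True)
class CdnaCoordinate:
    """An HGVS coding-DNA address.

    ``kind`` is where the base lies; ``base`` is the positive integer of the
    address (N of c.N, c.-N or c.*N; for intronic bases it is the address of
    the anchoring exonic base). ``offset`` is the signed intronic offset
    (c.N+M / c.N-M) and is zero for exonic addresses. ``anchor`` records, for
    intronic coordinates, which compartment the anchoring exon base belongs
    to (cds for c.N+M, utr5 for c.-N+M, utr3 for c.*N+M).
    """

    kind: str
    base: int
    offset: int = 0
    anchor: str = "cds"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown cDNA coordinate kind {self.kind!r}")
        if self.base < 1:
            raise ValueError("cDNA base addresses are positive integers")
        if self.kind != "intronic" and self.offset != 0:
            raise ValueError("offset must be zero for exonic coordinates")
        if self.kind == "intronic" and self.offset == 0:
            raise ValueError("intronic coordinates require a nonzero offset")

    def sort_key(self) -> tuple:
        """Orders addresses in transcript (5'->3') direction."""
        kind = self.anchor if self.kind == "intronic" else self.kind
        rank = {"utr5": 0, "cds": 1, "utr3": 2}[kind]
        base = -self.base if kind == "utr5" else self.base
        return (rank, base, self.offset)

    def __str__(self) -> str:
        kind = self.anchor if self.kind == "intronic" else self.kind
        prefix = {"utr5": "-", "cds": "", "utr3": "*"}[kind]
        text = f"{prefix}{self.base}"
        if self.offset:
            text += f"{self.offset:+d}"
        return text


# ---------------------------------------------------------------------------
# Transcript model
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptModel:
    """Gene/transcript geometry plus (optionally) the coding sequence.

    Exons are stored in transcript order: ascending genomic position on the
    plus strand, descending on the minus strand. ``cds_genomic`` spans from
    the first to the last coding base in genomic coordinates.
    """

    transcript_id: str
    gene_symbol: str
    strand: str
    exons: list[GenomicInterval]
    cds_genomic: GenomicInterval
    assembly: str = GRCH37
    cds_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        genomic_sorted = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic_sorted, genomic_sorted[1:]):
            if a.end >= b.start:
                raise ValueError("exons overlap")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if list(self.exons) != expected:
            raise ValueError("exons must be ordered in transcript direction")
        for endpoint in (self.cds_genomic.start, self.cds_genomic.end):
            if not any(e.contains(endpoint) for e in self.exons):
                raise ValueError("CDS endpoint falls outside all exons")
        if self.cds_sequence is not None:
            self._validate_cds_sequence()

    # -- derived geometry ---------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def gene_span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, lo, hi, self.assembly)

    @property
    def mrna_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def _tpos(self, pos: int) -> Optional[int]:
        """1-based position within the mRNA, or None if intronic/outside."""
        offset = 0
        for exon in self.exons:
            if exon.contains(pos):
                if self.strand == "+":
                    return offset + (pos - exon.start) + 1
                return offset + (exon.end - pos) + 1
            offset += len(exon)
        return None

    def _genomic_of_tpos(self, tpos: int) -> int:
        if not 1 <= tpos <= self.mrna_length:
            raise CoordinateError(f"transcript position {tpos} outside mRNA")
        offset = 0
        for exon in self.exons:
            if tpos <= offset + len(exon):
                within = tpos - offset - 1
                return exon.start + within if self.strand == "+" else exon.end - within
            offset += len(exon)
        raise AssertionError("unreachable")

    @property
    def cds_start_t(self) -> int:
        start = self.cds_genomic.start if self.strand == "+" else self.cds_genomic.end
        t = self._tpos(start)
        assert t is not None
        return t

    @property
    def cds_end_t(self) -> int:
        end = self.cds_genomic.end if self.strand == "+" else self.cds_genomic.start
        t = self._tpos(end)
        assert t is not None
        return t

    @property
    def cds_length(self) -> int:
        return self.cds_end_t - self.cds_start_t + 1

    def _validate_cds_sequence(self) -> None:
        seq = self.cds_sequence
        assert seq is not None
        seq = seq.upper()
        if len(seq) != self.cds_length:
            raise ValueError(
                f"cds_sequence length {len(seq)} != exonic CDS extent {self.cds_length}"
            )
        if len(seq) % 3:
            raise ValueError("cds_sequence length is not a multiple of 3")
        if not seq.startswith("ATG"):
            raise ValueError("cds_sequence does not start with ATG")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons[-1] not in _STOPS:
            raise ValueError("cds_sequence does not end with a stop codon")
        if any(c in _STOPS for c in codons[:-1]):
            raise ValueError("cds_sequence contains an internal stop codon")
        self.cds_sequence = seq

    # -- coordinate conversion ----------------------------------------------

    def genomic_to_cdna(self, pos: int) -> CdnaCoordinate:
        """Map a genomic position within the gene span to its c. address."""
        span = self.gene_span
        if not span.contains(pos):
            raise CoordinateError(
                f"position {self.chrom}:{pos} outside gene span "
                f"{span.start}-{span.end}"
            )
        tpos = self._tpos(pos)
        if tpos is not None:
            return self._tpos_to_cdna(tpos)
        # Intronic: anchor to the nearer flanking exon edge (5' exon on ties,
        # per HGVS convention).
        upstream, downstream = self._flanking_edges(pos)
        up_t, up_g = upstream
        down_t, down_g = downstream
        dist_up = abs(pos - up_g)
        dist_down = abs(pos - down_g)
        if dist_up <= dist_down:
            anchor_t, signed = up_t, dist_up
        else:
            anchor_t, signed = down_t, -dist_down
        anchor = self._tpos_to_cdna(anchor_t)
        return CdnaCoordinate("intronic", anchor.base, signed, anchor.kind)

    def _flanking_edges(self, pos: int) -> tuple[tuple[int, int], tuple[int, int]]:
        """(tpos, genomic) of the exon edges flanking an intronic position,
        as (upstream-in-transcript, downstream-in-transcript)."""
        for i, exon in enumerate(self.exons[:-1]):
            nxt = self.exons[i + 1]
            if self.strand == "+":
                in_between = exon.end < pos < nxt.start
                edges = (exon.end, nxt.start)
            else:
                in_between = nxt.end < pos < exon.start
                edges = (exon.start, nxt.end)
            if in_between:
                up_g, down_g = edges
                up_t, down_t = self._tpos(up_g), self._tpos(down_g)
                assert up_t is not None and down_t is not None
                return (up_t, up_g), (down_t, down_g)
        raise CoordinateError(f"position {pos} not intronic")

    def _tpos_to_cdna(self, tpos: int) -> CdnaCoordinate:
        if tpos < self.cds_start_t:
            return CdnaCoordinate("utr5", self.cds_start_t - tpos)
        if tpos > self.cds_end_t:
            return CdnaCoordinate("utr3", tpos - self.cds_end_t)
        return CdnaCoordinate("cds", tpos - self.cds_start_t + 1)

    def _cdna_to_tpos(self, coord: CdnaCoordinate) -> int:
        kind = coord.anchor if coord.kind == "intronic" else coord.kind
        if kind == "cds":
            t = self.cds_start_t + coord.base - 1
            if coord.offset == 0 and not self.cds_start_t <= t <= self.cds_end_t:
                raise CoordinateError(f"c.{coord.base} beyond CDS length {self.cds_length}")
        elif kind == "utr5":
            t = self.cds_start_t - coord.base
        else:
            t = self.cds_end_t + coord.base
        if not 1 <= t <= self.mrna_length:
            raise CoordinateError(f"cDNA coordinate {coord} beyond transcript extent")
        return t

    def cdna_to_genomic(self, coord: CdnaCoordinate) -> int:
        """Exact inverse of :meth:`genomic_to_cdna` on its image."""
        anchor_g = self._genomic_of_tpos(self._cdna_to_tpos(coord))
        if coord.kind != "intronic":
            return anchor_g
        step = 1 if self.strand == "+" else -1
        return anchor_g + step * coord.offset

    def annotate_position(self, pos: int) -> str:
        """Region label for a genomic position: exonic_cds / utr5 / utr3 / intronic."""
        coord = self.genomic_to_cdna(pos)
        return "exonic_cds" if coord.kind == "cds" else coord.kind

    def base_at_cds(self, cds_pos: int) -> str:
        if self.cds_sequence is None:
            raise CoordinateError("transcript model has no CDS sequence")
        if not 1 <= cds_pos <= len(self.cds_sequence):
            raise CoordinateError(f"CDS position {cds_pos} out of range")
        return self.cds_sequence[cds_pos - 1]


def codon_of(cds_pos: int, cds_length: Optional[int] = None) -> tuple[int, int]:
    """Residue index and within-codon offset (1..3) of a CDS position.

    residue = ceil(pos/3); e.g. CDS position 1456 lies in codon 486
    (the glutamine changed by the nonsense variant p.Gln486Ter).
    """
    if cds_pos < 1:
        raise CoordinateError("CDS positions are 1-based")
    if cds_length is not None and cds_pos > cds_length:
        raise CoordinateError(f"CDS position {cds_pos} > CDS length {cds_length}")
    residue = (cds_pos + 2) // 3
    offset = (cds_pos - 1) % 3 + 1
    return residue, offset


# ---------------------------------------------------------------------------
# Protein domain map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainEntry:
    label: str
    aa_start: int
    aa_end: int
    category: str  # n_term | zinc_finger | c_term | motif
    # zinc-finger extras; meaningful only for category == zinc_finger
    cys: tuple[int, ...] = ()
    his: tuple[int, ...] = ()
    helix_anchor: Optional[int] = None  # residue at helix position +1
    rbd: bool = False
    verified: bool = True

    def __post_init__(self) -> None:
        if self.aa_start > self.aa_end:
            raise ValueError(f"domain {self.label}: aa_start > aa_end")
        if self.category == "zinc_finger":
            inside = lambda r: self.aa_start <= r <= self.aa_end
            if self.cys or self.his:
                if len(self.cys) != 2 or len(self.his) != 2:
                    raise ValueError(
                        f"{self.label}: C2H2 fingers carry exactly 2 Cys + 2 His"
                    )
                if not all(map(inside, self.cys + self.his)):
                    raise ValueError(f"{self.label}: coordinating residues outside span")


# DNA-contact positions relative to the recognition-helix +1 residue.
DNA_CONTACT_OFFSETS = (-1, 2, 3, 6)


@dataclass
class DomainMap:
    """Protein domain annotation: labelled spans plus per-finger key residues."""

    entries: list[DomainEntry]
    protein_length: int

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.aa_end > self.protein_length:
                raise ValueError(f"domain {e.label} exceeds protein length")

    def _covering(self, residue: int) -> Optional[DomainEntry]:
        # motifs (most specific) win over broad term spans
        hits = [e for e in self.entries if e.aa_start <= residue <= e.aa_end]
        if not hits:
            return None
        order = {"motif": 0, "zinc_finger": 1, "n_term": 2, "c_term": 2}
        return sorted(hits, key=lambda e: order.get(e.category, 3))[0]

    def domain_of(self, residue: int) -> str:
        self._check(residue)
        hit = self._covering(residue)
        if hit is not None:
            return hit.label
        return "linker" if self._in_zf_region(residue) else "none"

    def residue_role(self, residue: int) -> str:
        self._check(residue)
        fingers = [
            e
            for e in self.entries
            if e.category == "zinc_finger" and e.aa_start <= residue <= e.aa_end
        ]
        for zf in fingers:
            if residue in zf.cys:
                return "zinc_coordinating_cys"
            if residue in zf.his:
                return "zinc_coordinating_his"
            if zf.helix_anchor is not None and (
                residue - zf.helix_anchor in DNA_CONTACT_OFFSETS
            ):
                return "dna_contact"
        for zf in fingers:
            if zf.rbd:
                return "rbd"
        hit = self._covering(residue)
        if hit is not None and hit.label.upper() == "YDF":
            return "ydf"
        if hit is None and self._in_zf_region(residue):
            return "linker"
        return "none"

    def _in_zf_region(self, residue: int) -> bool:
        fingers = [e for e in self.entries if e.category == "zinc_finger"]
        if not fingers:
            return False
        lo = min(e.aa_start for e in fingers)
        hi = max(e.aa_end for e in fingers)
        return lo <= residue <= hi

    def _check(self, residue: int) -> None:
        if not 1 <= residue <= self.protein_length:
            raise CoordinateError(
                f"residue {residue} outside protein (length {self.protein_length})"
            )


def ctcf_domain_map() -> DomainMap:
    """Default CTCF domain map (726-aa protein, NM_006565.4).

    Carries only spans with published coordinates: the cohesin-retaining YDF
    motif (226-228), ZF1 (264-275) and ZF10 (536-544) which harbour
    RNA-binding regions, and the flanking N/C termini derived from those
    boundaries. Remaining fingers (ZF2-ZF9, ZF11) and helix anchors must be
    supplied by user config; they are deliberately not guessed.
    """
    entries = [
        DomainEntry("N-term", 1, 263, "n_term"),
        DomainEntry("YDF", 226, 228, "motif"),
        DomainEntry("ZF1", 264, 275, "zinc_finger", rbd=True),
        DomainEntry("ZF10", 536, 544, "zinc_finger", rbd=True),
        DomainEntry("C-term", 545, 726, "c_term"),
    ]
    return DomainMap(entries, protein_length=726)


# ---------------------------------------------------------------------------
# Config IO
# ---------------------------------------------------------------------------


def load_transcript_config(path: str | Path) -> TranscriptModel:
    """Read a transcript model from a YAML config.

    Schema::

        transcript_id: NM_XXXX.1
        gene_symbol: GENE
        assembly: GRCh37
        chrom: chr16
        strand: "+"
        exons: [[start, end], ...]      # genomic, 1-based closed
        cds: [start, end]
        cds_sequence: ATG...TAA          # optional; or cds_fasta: file.fa
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    chrom = str(cfg["chrom"])
    assembly = cfg.get("assembly", GRCH37)
    exons = [GenomicInterval(chrom, int(s), int(e), assembly) for s, e in cfg["exons"]]
    if cfg.get("strand", "+") == "-":
        exons = sorted(exons, key=lambda e: e.start, reverse=True)
    else:
        exons = sorted(exons, key=lambda e: e.start)
    cds = GenomicInterval(chrom, int(cfg["cds"][0]), int(cfg["cds"][1]), assembly)
    seq = cfg.get("cds_sequence")
    if seq is None and "cds_fasta" in cfg:
        from Bio import SeqIO

        record = next(SeqIO.parse(path.parent / cfg["cds_fasta"], "fasta"))
        seq = str(record.seq)
    return TranscriptModel(
        transcript_id=str(cfg["transcript_id"]),
        gene_symbol=str(cfg.get("gene_symbol", "")),
        strand=cfg.get("strand", "+"),
        exons=exons,
        cds_genomic=cds,
        assembly=assembly,
        cds_sequence=seq,
    )


def dump_transcript_config(model: TranscriptModel, path: str | Path) -> None:
    cfg = {
        "transcript_id": model.transcript_id,
        "gene_symbol": model.gene_symbol,
        "assembly": model.assembly,
        "chrom": model.chrom,
        "strand": model.strand,
        "exons": [[e.start, e.end] for e in model.exons],
        "cds": [model.cds_genomic.start, model.cds_genomic.end],
    }
    if model.cds_sequence is not None:
        cfg["cds_sequence"] = model.cds_sequence
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


# Printed GRCh37 reference geometry for the CTCF locus.
CTCF_GENE_GRCH37 = GenomicInterval("chr16", 67_596_310, 67_673_088, GRCH37)
CTCF_CDS_GRCH37 = GenomicInterval("chr16", 67_644_736, 67_671_775, GRCH37)
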