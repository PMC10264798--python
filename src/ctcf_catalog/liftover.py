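"""Assembly liftover via UCSC chain files.

Implements the block-walk coordinate mapping of the UCSC LiftOver tool for
single positions and (strictly) for intervals. Chain files are 0-based
half-open; the pipeline's 1-based closed coordinates are converted at this
boundary and nowhere else. When several chains cover a position, only the
highest-scoring one is used, mirroring common liftover practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Optional, Union

from .transcript import GenomicInterval


class ChainParseError(ValueError):
    """Malformed or inconsistent chain file; message carries the line number."""


@dataclass(frozen=True)
class ChainSide:
    name: str
    size: int
    strand: str
    start: int  # 0-based half-open, on `strand`
    end: int


@dataclass(frozen=True)
class ChainAlignment:
    score: float
    source: ChainSide  # "target" side of the UCSC header (tName...)
    target: ChainSide  # "query" side (qName...)
    blocks: tuple[tuple[int, int, int], ...]  # (size, source_gap, target_gap)
    chain_id: Optional[str] = None

    def validate(self) -> None:
        src_extent = sum(b[0] + b[1] for b in self.blocks)
        tgt_extent = sum(b[0] + b[2] for b in self.blocks)
        if src_extent != self.source.end - self.source.start:
            raise ChainParseError(
                f"chain {self.chain_id}: blocks span {src_extent} source bases, "
                f"header declares {self.source.end - self.source.start}"
            )
        if tgt_extent != self.target.end - self.target.start:
            raise ChainParseError(
                f"chain {self.chain_id}: blocks span {tgt_extent} target bases, "
                f"header declares {self.target.end - self.target.start}"
            )


@dataclass(frozen=True)
class Mapped:
    chrom: str
    pos: int  # 1-based
    strand: str


@dataclass(frozen=True)
class Unmapped:
    reason: str  # no_chain | in_gap | split


LiftResult = Union[Mapped, Unmapped]


def parse_chain(stream: Union[IO[str], Iterable[str]]) -> list[ChainAlignment]:
    """Parse a UCSC chain file into validated alignments."""
    chains: list[ChainAlignment] = []
    header: Optional[list[str]] = None
    blocks: list[tuple[int, int, int]] = []

    def finish(line_no: int) -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] or blocks[-1][2]:
            raise ChainParseError(
                f"line {line_no}: chain ends without a bare final block"
            )
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, *rest) = header
        chain = ChainAlignment(
            score=float(score),
            source=ChainSide(t_name, int(t_size), t_strand, int(t_start), int(t_end)),
            target=ChainSide(q_name, int(q_size), q_strand, int(q_start), int(q_end)),
            blocks=tuple(blocks),
            chain_id=rest[0] if rest else None,
        )
        chain.validate()
        chains.append(chain)
        header, blocks = None, []

    line_no = 0
    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] == "chain":
            finish(line_no)
            if len(fields) not in (13, 14):
                raise ChainParseError(f"line {line_no}: bad chain header")
            header = fields
        else:
            if header is None:
                raise ChainParseError(f"line {line_no}: block outside a chain")
            try:
                nums = [int(x) for x in fields]
            except ValueError:
                raise ChainParseError(f"line {line_no}: non-integer block field")
            if len(nums) == 1:
                blocks.append((nums[0], 0, 0))
            elif len(nums) == 3:
                if nums[1] < 0 or nums[2] < 0:
                    raise ChainParseError(f"line {line_no}: negative gap")
                blocks.append((nums[0], nums[1], nums[2]))
            else:
                raise ChainParseError(f"line {line_no}: bad block line")
    finish(line_no + 1)
    return chains


def load_chain_file(path) -> list[ChainAlignment]:
    with open(path) as fh:
        return parse_chain(fh)


def map_position(
    chains: list[ChainAlignment], chrom: str, pos: int
) -> LiftResult:
    """Map a 1-based position through the best covering chain."""
    pos0 = pos - 1
    covering = [
        c
        for c in chains
        if c.source.name == chrom and c.source.start <= pos0 < c.source.end
    ]
    if not covering:
        return Unmapped("no_chain")
    chain = max(covering, key=lambda c: c.score)
    return _map_in_chain(chain, pos0)


def _map_in_chain(chain: ChainAlignment, pos0: int) -> LiftResult:
    cur_s = chain.source.start
    cur_t = chain.target.start
    for size, gap_s, gap_t in chain.blocks:
        if pos0 < cur_s + size:
            t0 = cur_t + (pos0 - cur_s)
            if chain.target.strand == "-":
                t0 = chain.target.size - 1 - t0
            return Mapped(chain.target.name, t0 + 1, chain.target.strand)
        cur_s += size + gap_s
        cur_t += size + gap_t
        if pos0 < cur_s:
            return Unmapped("in_gap")
    return Unmapped("in_gap")


def map_interval(
    chains: list[ChainAlignment],
    iv: GenomicInterval,
    policy: str = "strict",
    target_assembly: str = "GRCh37",
) -> Union[GenomicInterval, Unmapped]:
    """Lift both endpoints of an interval through a single chain.

    Strict policy: both endpoints must map, via the same chain, on the same
    strand, preserving order; otherwise the interval is unmapped with reason
    in_gap / no_chain / split.
    """
    if policy != "strict":
        raise ValueError(f"unknown interval policy {policy!r}")
    results = []
    for pos in (iv.start, iv.end):
        pos0 = pos - 1
        covering = [
            c
            for c in chains
            if c.source.name == iv.chrom and c.source.start <= pos0 < c.source.end
        ]
        if not covering:
            return Unmapped("no_chain")
        chain = max(covering, key=lambda c: c.score)
        res = _map_in_chain(chain, pos0)
        if isinstance(res, Unmapped):
            return res
        results.append((chain, res))
    (chain_a, a), (chain_b, b) = results
    if chain_a is not chain_b or a.chrom != b.chrom or a.strand != b.strand:
        return Unmapped("split")
    lo, hi = sorted((a.pos, b.pos))
    return GenomicInterval(a.chrom, lo, hi, target_assembly)


def reciprocal(chain: ChainAlignment) -> ChainAlignment:
    """Swap source and target (valid for plus-strand targets)."""
    if chain.target.strand != "+" or chain.source.strand != "+":
        raise ValueError("reciprocal swap implemented for plus-strand chains only")
    return ChainAlignment(
        score=chain.score,
        source=chain.target,
        target=chain.source,
        blocks=tuple((size, gq, gs) for size, gs, gq in chain.blocks),
        chain_id=chain.chain_id,
    )


def constant_offset_chain(
    chrom_src: str,
    chrom_tgt: str,
    span: tuple[int, int],
    offset: int,
    src_size: int = 500_000_000,
    tgt_size: int = 500_000_000,
    score: float = 1000.0,
) -> ChainAlignment:
    """A gapless synthetic chain shifting `span` (0-based half-open) by `offset`."""
    start, end = span
    chain = ChainAlignment(
        score=score,
        source=ChainSide(chrom_src, src_size, "+", start, end),
        target=ChainSide(chrom_tgt, tgt_size, "+", start + offset, end + offset),
        blocks=((end - start, 0, 0),),
        chain_id="1",
    )
    chain.validate()
    return chain


def format_chain(chain: ChainAlignment) -> str:
    """Serialize an alignment back to chain-file text."""
    s, t = chain.source, chain.target
    head = (
        f"chain {chain.score:g} {s.name} {s.size} {s.strand} {s.start} {s.end} "
        f"{t.name} {t.size} {t.strand} {t.start} {t.end} {chain.chain_id or 1}"
    )
    lines = [head]
    for i, (size, gs, gt) in enumerate(chain.blocks):
        if i == len(chain.blocks) - 1:
            lines.append(f"{size}")
        else:
            lines.append(f"{size} {gs} {gt}")
    return "\n".join(lines) + "\n\n"
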