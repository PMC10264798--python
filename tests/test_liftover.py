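"""Chain parsing and block-walk coordinate mapping."""

import io

import numpy as np
import pytest

from ctcf_catalog.liftover import (
    ChainAlignment,
    ChainParseError,
    ChainSide,
    Mapped,
    Unmapped,
    constant_offset_chain,
    format_chain,
    map_interval,
    map_position,
    parse_chain,
    reciprocal,
)
from ctcf_catalog.transcript import GenomicInterval

MINIMAL = "chain 100 chrT 1000 + 0 100 chrU 2000 + 500 600 1\n100\n"


class TestParseChain:
    def test_minimal_single_chain(self):
        chains = parse_chain(io.StringIO(MINIMAL))
        assert len(chains) == 1
        c = chains[0]
        assert c.source.name == "chrT"
        assert c.target == ChainSide("chrU", 2000, "+", 500, 600)
        assert c.blocks == ((100, 0, 0),)

    def test_extent_mismatch_rejected(self):
        bad = "chain 100 chrT 1000 + 0 100 chrU 2000 + 500 600 1\n90\n"
        with pytest.raises(ChainParseError):
            parse_chain(io.StringIO(bad))

    def test_empty_file(self):
        assert parse_chain(io.StringIO("")) == []

    def test_malformed_block_reports_line(self):
        bad = "chain 100 chrT 1000 + 0 100 chrU 2000 + 500 600 1\nfoo\n"
        with pytest.raises(ChainParseError, match="line 2"):
            parse_chain(io.StringIO(bad))

    def test_format_round_trip(self):
        chain = ChainAlignment(
            score=7.0,
            source=ChainSide("chrT", 1000, "+", 0, 250),
            target=ChainSide("chrU", 2000, "+", 100, 330),
            blocks=((100, 50, 30), (100, 0, 0)),
            chain_id="9",
        )
        chain.validate()
        assert parse_chain(io.StringIO(format_chain(chain)))[0] == chain


class TestMapPosition:
    def test_constant_offset(self):
        chain = ChainAlignment(
            score=1,
            source=ChainSide("chrT", 10_000, "+", 0, 1000),
            target=ChainSide("chrU", 10_000, "+", 5000, 6000),
            blocks=((1000, 0, 0),),
        )
        assert map_position([chain], "chrT", 101) == Mapped("chrU", 5101, "+")

    def test_gap_position_unmapped(self):
        chain = ChainAlignment(
            score=1,
            source=ChainSide("chrT", 10_000, "+", 0, 250),
            target=ChainSide("chrU", 10_000, "+", 5000, 5200),
            blocks=((100, 50, 0), (100, 0, 0)),
        )
        chain.validate()
        # 0-based 119 falls in the source gap between blocks
        assert map_position([chain], "chrT", 120) == Unmapped("in_gap")

    def test_absent_chromosome(self):
        chain = constant_offset_chain("chrT", "chrU", (0, 100), 10)
        assert map_position([chain], "chrZ", 5) == Unmapped("no_chain")

    def test_agrees_with_per_base_expansion(self):
        """Block walk equals a brute-force per-base expansion of the chain."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            blocks = []
            n_blocks = int(rng.integers(1, 5))
            for i in range(n_blocks):
                size = int(rng.integers(1, 30))
                if i == n_blocks - 1:
                    blocks.append((size, 0, 0))
                else:
                    blocks.append(
                        (size, int(rng.integers(0, 10)), int(rng.integers(0, 10)))
                    )
            s_start = int(rng.integers(0, 50))
            t_start = int(rng.integers(0, 50))
            s_len = sum(b[0] + b[1] for b in blocks)
            t_len = sum(b[0] + b[2] for b in blocks)
            chain = ChainAlignment(
                score=1,
                source=ChainSide("chrT", 10_000, "+", s_start, s_start + s_len),
                target=ChainSide("chrU", 10_000, "+", t_start, t_start + t_len),
                blocks=tuple(blocks),
            )
            chain.validate()
            # brute-force expansion: walk every base of every block
            expansion = {}
            cs, ct = s_start, t_start
            for size, gs, gt in blocks:
                for k in range(size):
                    expansion[cs + k] = ct + k
                cs += size + gs
                ct += size + gt
            for pos0 in range(s_start, s_start + s_len):
                got = map_position([chain], "chrT", pos0 + 1)
                if pos0 in expansion:
                    assert got == Mapped("chrU", expansion[pos0] + 1, "+")
                else:
                    assert got == Unmapped("in_gap")

    def test_reciprocal_round_trip(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            size1, gap, size2 = (
                int(rng.integers(5, 40)),
                int(rng.integers(1, 10)),
                int(rng.integers(5, 40)),
            )
            blocks = ((size1, gap, int(rng.integers(0, 8))), (size2, 0, 0))
            s_start, t_start = int(rng.integers(0, 100)), int(rng.integers(0, 100))
            chain = ChainAlignment(
                score=1,
                source=ChainSide(
                    "chrT", 10_000, "+", s_start,
                    s_start + sum(b[0] + b[1] for b in blocks),
                ),
                target=ChainSide(
                    "chrU", 10_000, "+", t_start,
                    t_start + sum(b[0] + b[2] for b in blocks),
                ),
                blocks=blocks,
            )
            chain.validate()
            back = reciprocal(chain)
            for pos in range(s_start + 1, s_start + size1 + gap + size2 + 1):
                fwd = map_position([chain], "chrT", pos)
                if isinstance(fwd, Mapped):
                    rev = map_position([back], fwd.chrom, fwd.pos)
                    assert rev == Mapped("chrT", pos, "+")

    def test_minus_strand_target_reflected(self):
        chain = ChainAlignment(
            score=1,
            source=ChainSide("chrT", 1000, "+", 0, 100),
            target=ChainSide("chrU", 1000, "-", 0, 100),
            blocks=((100, 0, 0),),
        )
        got = map_position([chain], "chrT", 1)
        assert got == Mapped("chrU", 1000, "-")

    def test_highest_score_chain_wins(self):
        low = constant_offset_chain("chrT", "chrU", (0, 100), 10, score=5)
        high = constant_offset_chain("chrT", "chrV", (0, 100), 50, score=50)
        assert map_position([low, high], "chrT", 10).chrom == "chrV"


class TestMapInterval:
    def test_constant_offset(self):
        chain = constant_offset_chain("chrT", "chrU", (0, 1000), 5000)
        iv = GenomicInterval("chrT", 101, 200, "GRCh38")
        got = map_interval([chain], iv)
        assert got == GenomicInterval("chrU", 5101, 5200, "GRCh37")

    def test_endpoint_in_gap(self):
        chain = ChainAlignment(
            score=1,
            source=ChainSide("chrT", 10_000, "+", 0, 250),
            target=ChainSide("chrU", 10_000, "+", 0, 200),
            blocks=((100, 50, 0), (100, 0, 0)),
        )
        chain.validate()
        assert map_interval([chain], GenomicInterval("chrT", 50, 120)) == Unmapped(
            "in_gap"
        )

    def test_endpoints_on_different_chains(self):
        a = constant_offset_chain("chrT", "chrU", (0, 100), 10)
        b = constant_offset_chain("chrT", "chrV", (200, 300), 50)
        got = map_interval([a, b], GenomicInterval("chrT", 50, 250))
        assert got == Unmapped("split")
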