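"""Consequence calling: worked examples plus brute-force oracle equivalence.

The oracle used here is independent of the classifier: it edits the CDS with
its own string operations, translates both alleles with Bio.Seq, and
classifies from the protein diff by first principles.
"""

import numpy as np
import pytest
from Bio.Seq import Seq

from ctcf_catalog.consequence import (
    ConfigurationError,
    apply_variant,
    call_consequence,
    translate,
)
from ctcf_catalog.hgvs import CdnaVariant, format_p, normalize_3prime, parse_c
from ctcf_catalog.synthetic import generate_transcript
from ctcf_catalog.transcript import CdnaCoordinate, GenomicInterval, TranscriptModel


class TestApplyVariant:
    SEQ = "ATGGACTTGAGCTAA"

    @pytest.mark.parametrize(
        "hgvs,expected",
        [
            ("c.4G>A", "ATGAACTTGAGCTAA"),
            ("c.5del", "ATGGCTTGAGCTAA"),
            ("c.4_6del", "ATGTTGAGCTAA"),
            ("c.4dupG", "ATGGGACTTGAGCTAA"),
            ("c.3_4insTT", "ATGTTGACTTGAGCTAA"),
        ],
    )
    def test_edits(self, hgvs, expected):
        assert apply_variant(self.SEQ, parse_c(hgvs)) == expected

    def test_length_change(self):
        for hgvs, delta in [("c.5del", -1), ("c.4_6del", -3), ("c.4dupG", 1)]:
            out = apply_variant(self.SEQ, parse_c(hgvs))
            assert len(out) - len(self.SEQ) == delta


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,protein,stop",
        [
            ("ATGGACTTGAGCTAA", "MDLS", True),
            ("ATG", "M", False),
            ("TAA", "", True),
            ("ATGGA", "M", False),  # trailing partial codon ignored
        ],
    )
    def test_examples(self, seq, protein, stop):
        assert translate(seq) == (protein, stop)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            translate("ATGNNN")

    def test_agrees_with_biopython(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 30)) * 3
            seq = "".join(rng.choice(list("ACGT"), size=n))
            mine, _ = translate(seq)
            ref = str(Seq(seq).translate()).split("*")[0]
            assert mine == ref


class TestCallConsequence:
    @pytest.mark.parametrize(
        "hgvs,klass,p_text",
        [
            ("c.4G>A", "missense", "p.Asp2Asn"),
            ("c.6C>T", "synonymous", "p.Asp2="),
            ("c.8T>A", "nonsense", "p.Leu3Ter"),
            ("c.5del", "frameshift", "p.Asp2Alafs*2"),
            ("c.4_6del", "inframe_del", "p.Asp2del"),
        ],
    )
    def test_worked_examples(self, mini_cds_model, hgvs, klass, p_text):
        call = call_consequence(mini_cds_model, parse_c(hgvs))
        assert call.klass == klass
        assert format_p(call.protein_change) == p_text

    def test_noncoding_regions(self, mini_cds_model):
        call = call_consequence(mini_cds_model, parse_c("c.*5T>G"))
        assert (call.region, call.klass) == ("utr3", "noncoding")
        assert call.protein_change is None

    def test_start_lost(self, mini_cds_model):
        call = call_consequence(mini_cds_model, parse_c("c.2T>C"))
        assert call.klass == "start_lost"

    def test_missing_cds_sequence_raises(self, t1_model):
        with pytest.raises(ConfigurationError):
            call_consequence(t1_model, parse_c("c.10A>T"))

    def test_dup_in_repeat_reports_3prime_residue(self):
        # poly-A run spanning codons 2-3: the duplicated base lands 3'
        model = TranscriptModel(
            "R1", "TOY", "+",
            [GenomicInterval("chrT", 1, 15)],
            GenomicInterval("chrT", 1, 15),
            cds_sequence="ATGAAAAAACGTTAA",
        )
        call = call_consequence(model, parse_c("c.4dupA"))
        assert call.klass == "frameshift"
        # normalization shifts the dup to c.9; first changed codon is 4
        assert call.protein_change.first_residue >= 3


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _oracle_edit(seq, v):
    s, e = v.start.base, v.end.base
    if v.kind == "sub":
        return seq[: s - 1] + v.alt + seq[s:]
    if v.kind == "del":
        return seq[: s - 1] + seq[e:]
    if v.kind == "dup":
        return seq[:e] + seq[s - 1 : e] + seq[e:]
    if v.kind == "ins":
        return seq[:s] + v.alt + seq[s:]
    return seq[: s - 1] + v.alt + seq[e:]


def _oracle_translate(seq):
    trimmed = seq[: len(seq) - len(seq) % 3]
    aa = str(Seq(trimmed).translate())
    stop = "*" in aa
    return aa.split("*")[0], stop


def _oracle_class(seq, v):
    """Independent classification by full translate-and-diff."""
    mutant = _oracle_edit(seq, v)
    wt, _ = _oracle_translate(seq)
    mt, mt_stop = _oracle_translate(mutant)
    if not mutant.startswith("ATG"):
        return "start_lost", None
    if mt == wt and mt_stop:
        return "synonymous", None
    i = 0
    while i < min(len(wt), len(mt)) and wt[i] == mt[i]:
        i += 1
    frame_broken = (len(mutant) - len(seq)) % 3 != 0
    if frame_broken:
        if i == len(mt) and mt_stop:
            return "nonsense", None
        if i == len(wt):
            return "stop_lost", None
        offset = len(mt) - i + 1 if mt_stop else None
        return "frameshift", offset
    if not mt_stop:
        return "stop_lost", None
    if len(mt) == len(wt):
        return ("nonsense" if i == len(mt) else
                "nonsense" if mt[i] == "*" else "missense"), None
    if len(mt) < len(wt):
        k = len(wt) - len(mt)
        if i == len(mt) and k != (len(seq) - len(mutant)) // 3:
            return "nonsense", None
        return "inframe_del", None
    return "inframe_ins", None


def _random_coding_variant(rng, seq):
    n = len(seq)
    kind = rng.choice(["sub", "del", "dup", "ins", "del_span"])
    if kind == "sub":
        s = int(rng.integers(1, n + 1))
        ref = seq[s - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        c = CdnaCoordinate("cds", s)
        return CdnaVariant("sub", c, c, ref=ref, alt=alt)
    if kind in ("del", "dup"):
        s = int(rng.integers(1, n + 1))
        c = CdnaCoordinate("cds", s)
        return CdnaVariant(kind, c, c, ref=seq[s - 1])
    if kind == "ins":
        s = int(rng.integers(1, n))
        alt = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 5))))
        return CdnaVariant(
            "ins", CdnaCoordinate("cds", s), CdnaCoordinate("cds", s + 1), alt=alt
        )
    span = int(rng.integers(2, 7))
    s = int(rng.integers(1, n - span + 1))
    e = s + span - 1
    return CdnaVariant(
        "del", CdnaCoordinate("cds", s), CdnaCoordinate("cds", e), ref=seq[s - 1 : e]
    )


class TestOracleEquivalence:
    def test_classifier_matches_brute_force(self):
        """Classifier klass (and fs offset) equals the translate-and-diff
        oracle over >=10^4 random variants on random toy CDSs."""
        rng = np.random.default_rng(123)
        models = [generate_transcript(s, n_exons=2, cds_codons=25) for s in range(8)]
        checked = 0
        for round_ in range(10_500):
            model = models[round_ % len(models)]
            seq = model.cds_sequence
            v = _random_coding_variant(rng, seq)
            nv = normalize_3prime(seq, v)
            call = call_consequence(model, nv, normalized=True)
            # the oracle classifies the *normalized* variant: both routes see
            # the identical edit, the classification logic is independent
            oracle_klass, oracle_offset = _oracle_class(seq, nv)
            assert call.klass == oracle_klass, (format := (seq, nv, call))
            if call.klass == "frameshift":
                assert call.protein_change.fs_term_offset == oracle_offset
            checked += 1
        assert checked >= 10_000

    def test_frame_rule_for_pure_indels(self):
        """Length change divisible by 3 <=> not frameshift, away from edges."""
        rng = np.random.default_rng(9)
        model = generate_transcript(11, n_exons=1, cds_codons=40)
        seq = model.cds_sequence
        n = len(seq)
        for _ in range(2000):
            span = int(rng.integers(1, 7))
            s = int(rng.integers(4, n - span - 3))
            v = CdnaVariant(
                "del",
                CdnaCoordinate("cds", s),
                CdnaCoordinate("cds", s + span - 1),
                ref=seq[s - 1 : s + span - 1],
            )
            call = call_consequence(model, v)
            if call.klass in ("frameshift", "nonsense", "stop_lost"):
                if call.klass == "frameshift":
                    assert span % 3 != 0
            elif call.klass in ("inframe_del", "synonymous", "missense"):
                assert span % 3 == 0

    def test_synonymous_iff_identical_protein(self):
        rng = np.random.default_rng(21)
        model = generate_transcript(13, n_exons=1, cds_codons=30)
        seq = model.cds_sequence
        for _ in range(2000):
            v = _random_coding_variant(rng, seq)
            nv = normalize_3prime(seq, v)
            call = call_consequence(model, nv, normalized=True)
            wt, _ = _oracle_translate(seq)
            mt, mt_stop = _oracle_translate(_oracle_edit(seq, nv))
            assert (call.klass == "synonymous") == (
                mt == wt and mt_stop and _oracle_edit(seq, nv).startswith("ATG")
            )
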