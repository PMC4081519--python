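import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rgkscan import motif_engine as me
from rgkscan.errors import NoDomainError, PatternSyntaxError, UsageError
from rgkscan.seqio import AMINO_ACIDS, ProteinRecord

from conftest import plant


class TestCompilePattern:
    def test_rgk_signature_structure(self, signature):
        assert signature.length == 11
        assert signature.positions[4] == frozenset("C")  # position 5, 1-based
        assert signature.positions[8] == frozenset(AMINO_ACIDS)  # position 9
        assert signature.singleton_positions("C") == (4,)

    def test_wildcard_only(self):
        pat = me.compile_pattern("x")
        assert pat.length == 1 and pat.positions[0] == frozenset(AMINO_ACIDS)

    def test_unbalanced_bracket(self):
        with pytest.raises(PatternSyntaxError) as err:
            me.compile_pattern("[KR")
        assert err.value.offset == 0

    def test_empty_class(self):
        with pytest.raises(PatternSyntaxError):
            me.compile_pattern("A[]B")

    def test_illegal_character(self):
        with pytest.raises(PatternSyntaxError):
            me.compile_pattern("A1B")

    @settings(max_examples=100, derandomize=True)
    @given(
        classes=st.lists(
            st.one_of(
                st.just("x"),
                st.sampled_from(list(AMINO_ACIDS)),
                st.sets(st.sampled_from(list(AMINO_ACIDS)), min_size=2, max_size=5).map(
                    lambda s: "[" + "".join(sorted(s)) + "]"
                ),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_compile_render_round_trip(self, classes):
        text = "".join(classes)
        pat = me.compile_pattern(text)
        assert me.compile_pattern(pat.render()).positions == pat.positions


class TestMatchAt:
    def test_exact_signature_match(self, signature):
        hit = me.match_at("KSKHCHDLSVL", signature, 0)
        assert hit is not None and hit.n_mismatches == 0
        assert hit.matched_text == "KSKHCHDLSVL"

    def test_cysteine_violation_absent_at_zero_tolerance(self, signature):
        assert me.match_at("KSKHSHDLSVL", signature, 0) is None

    def test_cysteine_violation_tolerated_at_one(self, signature):
        hit = me.match_at("KSKHSHDLSVL", signature, 0, max_mismatches=1)
        assert hit is not None and hit.n_mismatches == 1

    def test_out_of_range_offset(self, signature):
        with pytest.raises(UsageError):
            me.match_at("KSKHCHDLSVL", signature, 1)


class TestScanCTerminus:
    def test_anchored_hit_at_terminal_window(self, signature):
        rec = ProteinRecord("r", "M" * 30 + "RSKHCHDMAVL")
        hit = me.scan_c_terminus(rec, signature)
        assert hit is not None and hit.start == 30 and hit.end == 41

    def test_short_sequence_absent(self, signature):
        assert me.scan_c_terminus(ProteinRecord("r", "MKVAC"), signature) is None

    def test_internal_hit_requires_anywhere_mode(self, signature):
        rec = ProteinRecord("r", "M" * 10 + "KSKHCHDLSVL" + "G" * 20)
        assert me.scan_c_terminus(rec, signature) is None
        hits = me.scan_c_terminus(rec, signature, anchored=False)
        assert [h.start for h in hits] == [10]


class TestFindGMotifs:
    def test_g1_found(self, catalog):
        hits = me.find_g_motifs("MM" + "GDSGVGKS" + "MM", catalog)
        assert [(h.motif_name, h.start) for h in hits] == [("G1", 2)]

    def test_g5_found(self, catalog):
        hits = me.find_g_motifs("MMETSAMM", catalog)
        assert [(h.motif_name, h.start) for h in hits] == [("G5", 2)]

    def test_no_motifs_in_homopolymer(self, catalog):
        assert me.find_g_motifs("AAAAAAAAAA", catalog) == []

    def test_tolerant_mode_flags_single_mismatch(self, catalog):
        # G1 with K->R at fixed position 6
        hits = me.find_g_motifs("GDSGVGRS", catalog, tolerant=True)
        g1 = [h for h in hits if h.motif_name == "G1"]
        assert len(g1) == 1 and g1[0].n_mismatches == 1
        assert me.find_g_motifs("GDSGVGRS", catalog, tolerant=False) == []

    def test_empty_catalog_rejected(self):
        with pytest.raises(UsageError):
            me.find_g_motifs("ACDE", {})


def _domain_sequence(g1_at=76, g5_at=219, length=260):
    seq = list("M" * length)
    seq[g1_at : g1_at + 8] = "GDSGVGKS"
    seq[g5_at : g5_at + 4] = "ETSA"
    return ProteinRecord("t", "".join(seq))


class TestExtractGDomain:
    def test_default_convention_interval(self):
        gd = me.extract_g_domain(_domain_sequence())
        assert (gd.start, gd.end, gd.length) == (70, 249, 179)
        assert not gd.truncated_flag

    def test_start_clamped_with_flag(self):
        gd = me.extract_g_domain(_domain_sequence(g1_at=3, g5_at=150, length=200))
        assert gd.start == 0 and gd.truncated_flag

    def test_g5_end_convention(self):
        gd = me.extract_g_domain(_domain_sequence(), convention="g5-end+30")
        assert gd.end == 253

    def test_missing_motif_named(self):
        rec = ProteinRecord("t", plant("GDSGVGKS", 10, 60))
        with pytest.raises(NoDomainError, match="G5"):
            me.extract_g_domain(rec)

    def test_pairing_prefers_length_closest_to_175(self):
        # two G5 copies: separations 139 (length 175) and 80 (length 116)
        seq = list("M" * 300)
        seq[60:68] = "GDSGVGKS"
        seq[140:144] = "ETSA"
        seq[199:203] = "ETSA"
        gd = me.extract_g_domain(ProteinRecord("t", "".join(seq)))
        assert gd.g5_hit.start == 199 and gd.length == 175

    def test_end_convention_lengths_differ_by_g5_length(self, clean_rgk_records):
        records, _ = clean_rgk_records
        for rec in records:
            a = me.extract_g_domain(rec, "g5-start+30")
            b = me.extract_g_domain(rec, "g5-end+30")
            assert b.length - a.length == a.g5_hit.length == 4


class TestAnnotateCTerminus:
    def test_conforming_synthetic_tail(self):
        rec = ProteinRecord("t", "KRKKRSKTKRKKRRSNKRRSRSSRSKSKSCHDLSVL")
        f = me.annotate_c_terminus(rec)
        assert f.c7_cysteine and f.ser_minus8 and f.pdz_class1
        assert f.signature_hit is not None
        assert f.polybasic_fraction is not None and f.polybasic_fraction > 0.5

    def test_non_cysteine_at_minus7(self):
        rec = ProteinRecord("t", "M" * 30 + "AHDLSVL")
        assert not me.annotate_c_terminus(rec).c7_cysteine

    def test_short_record_polybasic_not_evaluable(self):
        rec = ProteinRecord("t", "KRKKRSKTKRKKRRSNKRRS")  # 20 residues
        assert me.annotate_c_terminus(rec).polybasic_fraction is None


def _naive_scan(seq, pattern, max_mismatches=0):
    """Independent all-offsets class-membership oracle."""
    hits = []
    for off in range(len(seq) - pattern.length + 1):
        nm = sum(
            1
            for i, cls in enumerate(pattern.positions)
            if cls != frozenset(AMINO_ACIDS) and seq[off + i] not in cls
        )
        if nm <= max_mismatches:
            hits.append((off, nm))
    return hits


def test_scanners_agree_with_brute_force_oracle(signature, catalog):
    """Anchored / anywhere scans match the naive oracle on 1,000 random
    sequence-pattern pairs."""
    rng = np.random.default_rng(2024)
    patterns = [signature] + [d.pattern for d in catalog.values()]
    aas = np.array(list(AMINO_ACIDS))
    for k in range(1000):
        pattern = patterns[k % len(patterns)]
        length = int(rng.integers(pattern.length, 60))
        seq = "".join(rng.choice(aas, size=length))
        # bias toward matches: sometimes plant a class-conforming word
        if rng.random() < 0.5:
            word = "".join(sorted(cls)[rng.integers(len(cls))] for cls in pattern.positions)
            at = int(rng.integers(0, length - pattern.length + 1))
            seq = seq[:at] + word + seq[at + pattern.length :]
        tol = int(rng.integers(0, 2))
        expected = _naive_scan(seq, pattern, tol)
        got = [(h.start, h.n_mismatches) for h in me.scan_all(seq, pattern, tol)]
        assert got == expected
        rec = ProteinRecord("r", seq)
        anchored = me.scan_c_terminus(rec, pattern, tol)
        tail_expected = [e for e in expected if e[0] == length - pattern.length]
        assert (anchored is not None) == bool(tail_expected)
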