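import json

import numpy as np
import pytest

from rgkscan import classify as cl
from rgkscan import synthetic_data as sd
from rgkscan.errors import UsageError
from rgkscan.seqio import AlignmentBlock, ProteinRecord, write_fasta


class TestDecisionLadder:
    def test_canonical_rgk(self, clean_rgk_records):
        records, _ = clean_rgk_records
        for rec in records:
            rep = cl.classify_record(rec)
            assert rep.verdict == "RGK-like"
            assert rep.g_domain_length_ok is True
            assert rep.interaction_residues is None  # no alignment supplied

    def test_decoy_is_ras_like(self):
        spec = sd.BenchmarkSpec(n_rgk=0, n_decoy=3, n_background=0, seed=2)
        decoys, _ = sd.generate_decoys(3, spec)
        for rec in decoys:
            assert cl.classify_record(rec).verdict == "Ras-like-non-RGK"

    def test_background_has_no_g_domain(self):
        for rec in sd.generate_background(5, (150, 250), seed=3):
            assert cl.classify_record(rec).verdict == "no-G-domain"

    def test_degenerate_input_does_not_raise(self):
        rep = cl.classify_record(ProteinRecord("tiny", "MK"))
        assert rep.verdict == "no-G-domain"
        assert any("shorter than the signature" in e for e in rep.evidence)

    def test_verdict_invariants_on_fuzzed_benchmark(self, small_benchmark):
        _, records, _ = small_benchmark
        for rep in cl.classify_records(records):
            if rep.verdict == "RGK-like":
                assert rep.signature_present and rep.g_domain is not None
            elif rep.verdict == "Ras-like-non-RGK":
                assert rep.g_domain is not None and not rep.signature_present
            elif rep.verdict == "no-G-domain":
                assert rep.g_domain is None

    def test_classification_invariant_to_record_order(self, small_benchmark):
        _, records, _ = small_benchmark
        rng = np.random.default_rng(0)
        shuffled = list(records)
        rng.shuffle(shuffled)
        forward = {r.record_id: r.verdict for r in cl.classify_records(records)}
        backward = {r.record_id: r.verdict for r in cl.classify_records(shuffled)}
        assert forward == backward


def _reference_alignment():
    """A 230-column gap-free alignment whose reference row has R at 196,
    V at 223 and H at 225 (mouse Gem numbering)."""
    ref = list("A" * 230)
    ref[195], ref[222], ref[224] = "R", "V", "H"
    ref = "".join(ref)
    ile = ref[:222] + "I" + ref[223:]          # I at the V223 column
    bad = ref[:195] + "D" + ref[196:]          # D at the R196 column
    gapped = ref[:224] + "-" + ref[225:]       # gap at the H225 column
    return AlignmentBlock(
        rows=(("ref", ref), ("ile", ile), ("bad", bad), ("gapped", gapped))
    )


class TestInteractionResidues:
    def test_reference_row_passes_everywhere(self):
        table = cl.check_interaction_residues(_reference_alignment(), "ref")
        assert table["ref"] == {"R196": "pass", "V223": "pass", "H225": "pass"}

    def test_isoleucine_accepted_at_v223(self):
        table = cl.check_interaction_residues(_reference_alignment(), "ref")
        assert table["ile"]["V223"] == "pass"

    def test_aspartate_fails_at_r196(self):
        table = cl.check_interaction_residues(_reference_alignment(), "ref")
        assert table["bad"]["R196"] == "fail"

    def test_gap_fails_with_gap_reason(self):
        table = cl.check_interaction_residues(_reference_alignment(), "ref")
        assert table["gapped"]["H225"] == "gap"

    def test_residue_beyond_reference_rejected(self):
        aln = AlignmentBlock(rows=(("ref", "ACD"), ("x", "ACD")))
        with pytest.raises(UsageError):
            cl.check_interaction_residues(aln, "ref")

    def test_default_refmap_contents(self):
        refmap = cl.ReferenceResidueMap()
        assert refmap.interaction["V223"] == frozenset("VLI")
        assert set(refmap.annotation_only) == {"W141", "C146", "N191", "K192", "E219", "S221"}
        assert refmap.partner_residues == ("D194", "D270", "D272")


class TestRunPipeline:
    @pytest.fixture()
    def benchmark_dir(self, tmp_path, small_benchmark):
        _, records, _ = small_benchmark
        db = tmp_path / "db.fasta"
        write_fasta(records, db)
        return tmp_path, db, records

    def test_report_rows_match_db_size(self, benchmark_dir):
        tmp_path, db, records = benchmark_dir
        manifest = cl.run_pipeline(db, None, tmp_path / "out", seed=1)
        assert manifest["n_records"] == len(records)
        tsv = (tmp_path / "out" / "classification.tsv").read_text().splitlines()
        assert len(tsv) == len(records) + 1
        assert sum(manifest["verdict_counts"].values()) == len(records)

    def test_rerun_byte_identical(self, benchmark_dir):
        tmp_path, db, _ = benchmark_dir
        cl.run_pipeline(db, None, tmp_path / "o1", seed=7)
        cl.run_pipeline(db, None, tmp_path / "o2", seed=7)
        for name in ("classification.tsv", "g_domains.fasta", "manifest.json"):
            assert (tmp_path / "o1" / name).read_bytes() == (tmp_path / "o2" / name).read_bytes()

    def test_failure_writes_stage_marker(self, tmp_path, benchmark_dir):
        _, db, _ = benchmark_dir
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("g5_convention: nonsense\n")
        with pytest.raises(UsageError):
            cl.run_pipeline(db, cfg, tmp_path / "out_fail", seed=1)
        marker = tmp_path / "out_fail" / "FAILED"
        assert marker.exists() and "setup" in marker.read_text()

    def test_optional_stages_from_config(self, tmp_path, small_benchmark):
        from rgkscan.seqio import write_alignment

        _, records, _ = small_benchmark
        db = tmp_path / "db.fasta"
        write_fasta(records, db)
        seed_aln = tmp_path / "seed.afa"
        write_alignment(sd.generate_seed_alignment(), seed_aln)
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "profile_search:\n"
            f"  seed_alignment: {seed_aln}\n"
            "conservation:\n"
            f"  alignment: {seed_aln}\n"
        )
        manifest = cl.run_pipeline(db, cfg, tmp_path / "out", seed=5)
        assert manifest["profile_search"]["n_included"] > 0
        assert manifest["conservation"]["n_columns"] == 40
        assert (tmp_path / "out" / "profile_search.tsv").exists()
        assert (tmp_path / "out" / "conservation.tsv").exists()


def test_parameter_recovery_on_default_benchmark():
    """On the default study conditions (200 RGK-like at tail noise 0.05,
    200 Ras-like decoys, 600 background, seed 42) the classifier recovers
    RGK-like records with sensitivity ≥ 0.95 and calls ≤ 1% of
    decoys + background RGK-like."""
    spec = sd.BenchmarkSpec()
    records, truth = sd.generate_benchmark(spec)
    verdicts = {r.record_id: r.verdict for r in cl.classify_records(records)}
    truth_by_id = {t.record_id: t for t in truth}
    rgk_ids = [t.record_id for t in truth if t.true_class == "RGK"]
    neg_ids = [t.record_id for t in truth if t.true_class != "RGK"]
    sensitivity = sum(verdicts[i] == "RGK-like" for i in rgk_ids) / len(rgk_ids)
    fpr = sum(verdicts[i] == "RGK-like" for i in neg_ids) / len(neg_ids)
    assert sensitivity >= 0.95
    assert fpr <= 0.01
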