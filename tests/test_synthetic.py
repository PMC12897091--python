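import shutil
import subprocess

import numpy as np
import pytest

from msquant.msi_metrics import MutationEvent, extract_mutations
from msquant.pipeline import score_reads
from msquant.refrecon import ReferenceWindow, reconstruct_reference
from msquant.sam_model import parse_sam_record, passes_filters, query_length
from msquant.synthetic import (
    CohortModel,
    MutationSpecError,
    demo_panel,
    locus_reference,
    make_read,
    plan_deletion,
    simulate_cohort,
    simulate_reads,
    simulate_sample,
    test_case_fixtures as functional_fixtures,
    write_sam,
)

from oracles import oracle_events, oracle_window_filter


class TestMakeRead:
    def test_empty_spec_is_identity_read(self, ref_a11):
        read = make_read(ref_a11)
        assert read.cigar == (("M", 31),)
        assert read.md == "31"
        assert read.nm == 0
        assert read.seq == ref_a11.seq

    def test_two_base_deletion_shape(self, ref_a11):
        read = make_read(ref_a11, [plan_deletion(ref_a11, 104, 2)])
        assert ("D", 2) in read.cigar
        assert "^AA" in read.md
        assert read.nm == 2

    def test_insertion_with_soft_clip_lengths(self, ref_a11):
        read = make_read(
            ref_a11, [MutationEvent(105, "insertion", 2, "AA")], soft_clip=(3, 0)
        )
        assert read.cigar[0] == ("S", 3)
        assert len(read.seq) == 3 + 31 + 2
        assert query_length(read.cigar) == len(read.seq)

    def test_round_trip_inverts_generation(self, ref_a11):
        events = [
            MutationEvent(96, "substitution", 1, "C"),
            plan_deletion(ref_a11, 103, 1),
            MutationEvent(108, "insertion", 1, "A"),
        ]
        read = make_read(ref_a11, events, soft_clip=(2, 2))
        assert reconstruct_reference(read).seq == ref_a11.seq

    def test_overlapping_events_rejected(self, ref_a11):
        with pytest.raises(MutationSpecError, match="overlap"):
            make_read(
                ref_a11,
                [plan_deletion(ref_a11, 104, 2),
                 MutationEvent(105, "substitution", 1, "C")],
            )

    def test_substitution_equal_to_reference_rejected(self, ref_a11):
        with pytest.raises(MutationSpecError, match="equals reference"):
            make_read(ref_a11, [MutationEvent(105, "substitution", 1, "A")])

    def test_deletion_bases_must_match_reference(self, ref_a11):
        with pytest.raises(MutationSpecError, match="do not match"):
            make_read(ref_a11, [MutationEvent(104, "deletion", 1, "G")])

    def test_insertion_anchor_outside_window_rejected(self, ref_a11):
        with pytest.raises(MutationSpecError, match="anchor"):
            make_read(ref_a11, [MutationEvent(88, "insertion", 1, "A")])

    def test_leading_insertion_at_window_start_minus_one(self, ref_a11):
        read = make_read(ref_a11, [MutationEvent(89, "insertion", 1, "G")])
        assert read.cigar[0] == ("I", 1)
        assert reconstruct_reference(read).seq == ref_a11.seq


class TestTestCaseFixtures:
    def test_expected_outputs(self):
        for bundle in functional_fixtures():
            for read in bundle.reads:
                got = extract_mutations(read, bundle.window)
                assert got == sorted(bundle.expected_events), bundle.name

    def test_against_independent_oracle(self):
        for bundle in functional_fixtures():
            for read in bundle.reads:
                expected = oracle_window_filter(
                    oracle_events(read.seq, read.cigar, read.md, read.pos),
                    *bundle.window,
                )
                got = [
                    (e.ref_pos, e.kind, e.length, e.bases)
                    for e in extract_mutations(read, bundle.window)
                ]
                assert sorted(got) == sorted(expected), bundle.name

    def test_case_shapes(self):
        case1, case2, case3 = functional_fixtures()
        assert case1.expected_events == ()
        assert len(case2.expected_events) == 3
        assert len(case3.expected_events) == 1
        assert case3.expected_events[0].ref_pos == case3.window[0] - 1


class TestDemoPanelAndReference:
    def test_demo_panel_shape(self):
        panel = demo_panel()
        assert len(panel) == 10
        assert len(panel.genes) == 5
        for locus in panel:
            assert len(locus.repeat_unit) == 1
            assert locus.length >= 10

    def test_locus_reference_is_deterministic_and_bounded(self):
        locus = demo_panel().get("ACVR2A_1")
        ref1 = locus_reference(locus)
        ref2 = locus_reference(locus)
        assert ref1 == ref2
        tract = ref1.slice(locus.start, locus.end).seq
        assert tract == locus.repeat_unit * locus.length
        # tract-adjacent flank bases differ from the repeat base
        assert ref1.seq[locus.start - 1 - ref1.start] != locus.repeat_unit
        assert ref1.seq[locus.end + 1 - ref1.start] != locus.repeat_unit


class TestSimulateSample:
    def test_noise_free_mss_sample_scores_zero(self, tmp_path):
        panel = demo_panel()
        model = CohortModel(
            n_msi=0, n_mss=1, reads_per_locus=10,
            indel_rate_mss=0.0, substitution_rate=0.0, seed=1,
        )
        reads = simulate_reads(panel, "MSS", model, "s", np.random.default_rng(1))
        result = score_reads(reads, panel, sample_id="s")
        assert result.score.mean_pct_mutated_reads == 0.0
        assert result.score.mean_pct_total_mutations == 0.0

    def test_msi_locus_rate_within_binomial_bound(self):
        panel = demo_panel()
        model = CohortModel(
            n_msi=1, n_mss=0, reads_per_locus=200,
            indel_rate_msi=0.6, substitution_rate=0.0, seed=2,
        )
        reads = simulate_reads(panel, "MSI", model, "s", np.random.default_rng(2))
        result = score_reads(reads, panel, sample_id="s")
        # 3-sigma binomial bound at p=0.6, n=200 per locus (tighter pooled)
        assert abs(result.score.mean_pct_mutated_reads - 60.0) < 10.0

    def test_same_seed_byte_identical(self, tmp_path):
        panel = demo_panel()
        model = CohortModel(n_msi=1, n_mss=0, reads_per_locus=15, seed=9)
        p1 = simulate_sample(panel, "MSI", model, "s", tmp_path / "a.sam",
                             np.random.default_rng(9))
        p2 = simulate_sample(panel, "MSI", model, "s", tmp_path / "b.sam",
                             np.random.default_rng(9))
        assert p1.read_bytes() == p2.read_bytes()

    def test_emitted_sam_parses_and_passes_filters(self, tmp_path):
        panel = demo_panel()
        model = CohortModel(n_msi=1, n_mss=0, reads_per_locus=5, seed=3)
        path = simulate_sample(panel, "MSI", model, "s", tmp_path / "s.sam")
        n = 0
        for line in path.read_text().splitlines():
            if line.startswith("@"):
                continue
            read = parse_sam_record(line)  # invariants checked in constructor
            assert passes_filters(read)
            n += 1
        assert n == 5 * len(panel)

    def test_unknown_class_rejected(self):
        model = CohortModel(n_msi=1, n_mss=1)
        with pytest.raises(ValueError):
            simulate_reads(demo_panel(), "MSI-L", model, "s", np.random.default_rng(0))

    @pytest.mark.skipif(shutil.which("samtools") is None, reason="samtools not on PATH")
    def test_samtools_accepts_emitted_sam(self, tmp_path):
        panel = demo_panel()
        model = CohortModel(n_msi=1, n_mss=0, reads_per_locus=5, seed=4)
        path = simulate_sample(panel, "MSI", model, "s", tmp_path / "s.sam")
        out = subprocess.run(
            ["samtools", "view", "-c", str(path)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        assert int(out.stdout.strip()) == 5 * len(panel)


class TestSimulateCohort:
    def test_separable_cohort_structure(self, tmp_path):
        panel = demo_panel()
        model = CohortModel(
            n_msi=3, n_mss=3, reads_per_locus=20,
            indel_rate_msi=0.6, indel_rate_mss=0.02, seed=11,
        )
        manifest = simulate_cohort(model, panel, tmp_path)
        rows = manifest["samples"]
        assert len(rows) == 6
        msi = [r["pct_mutated_reads"] for r in rows if r["label"] == "MSI"]
        mss = [r["pct_mutated_reads"] for r in rows if r["label"] == "MSS"]
        assert min(msi) > max(mss)
        assert (tmp_path / "scores.tsv").exists()
        assert (tmp_path / "cohort.json").exists()
        assert len(list((tmp_path / "sams").glob("*.sam"))) == 6

    def test_cohort_deterministic_under_seed(self, tmp_path):
        panel = demo_panel()
        model = CohortModel(n_msi=1, n_mss=1, reads_per_locus=10, seed=21)
        simulate_cohort(model, panel, tmp_path / "x")
        simulate_cohort(model, panel, tmp_path / "y")
        assert (tmp_path / "x/scores.tsv").read_bytes() == (
            tmp_path / "y/scores.tsv"
        ).read_bytes()
        for sam in (tmp_path / "x/sams").glob("*.sam"):
            assert sam.read_bytes() == (tmp_path / "y/sams" / sam.name).read_bytes()
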