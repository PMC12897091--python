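import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msquant.msi_metrics import (
    LocusMetrics,
    MutationEvent,
    compute_locus_metrics,
    compute_sample_score,
    extract_mutations,
)
from msquant.panel import MicrosatelliteLocus, Panel
from msquant.refrecon import ReferenceWindow
from msquant.synthetic import make_read, plan_deletion

from oracles import oracle_events, oracle_window_filter, random_mutation_plan

WINDOW = (100, 110)


@pytest.fixture
def ref(ref_a11):
    return ref_a11


def events_as_tuples(events):
    return [(e.ref_pos, e.kind, e.length, e.bases) for e in events]


class TestExtractMutations:
    def test_upstream_deletion_produces_no_window_events(self, ref):
        read = make_read(ref, [plan_deletion(ref, 95, 1)])
        assert extract_mutations(read, WINDOW) == []

    def test_upstream_insertion_produces_no_window_events(self, ref):
        read = make_read(ref, [MutationEvent(93, "insertion", 2, "GG")])
        assert extract_mutations(read, WINDOW) == []

    def test_two_independent_insertions_counted_separately(self, ref):
        planned = [
            MutationEvent(102, "insertion", 1, "A"),
            MutationEvent(106, "insertion", 1, "A"),
        ]
        read = make_read(ref, planned)
        got = extract_mutations(read, WINDOW)
        assert got == planned

    def test_insertion_anchored_before_first_repeat_base_is_in(self, ref):
        read = make_read(ref, [MutationEvent(99, "insertion", 1, "A")])
        got = extract_mutations(read, WINDOW)
        assert events_as_tuples(got) == [(99, "insertion", 1, "A")]

    def test_insertion_anchored_before_that_is_out(self, ref):
        read = make_read(ref, [MutationEvent(98, "insertion", 1, "A")])
        assert extract_mutations(read, WINDOW) == []

    def test_insertion_anchored_at_window_end_is_in(self, ref):
        read = make_read(ref, [MutationEvent(110, "insertion", 1, "A")])
        assert len(extract_mutations(read, WINDOW)) == 1

    def test_substitution_boundaries(self, ref):
        at_end = make_read(ref, [MutationEvent(110, "substitution", 1, "C")])
        assert len(extract_mutations(at_end, WINDOW)) == 1
        past_end = make_read(ref, [MutationEvent(111, "substitution", 1, "C")])
        assert extract_mutations(past_end, WINDOW) == []

    def test_deletion_spanning_window_edge_counts_once(self, ref):
        # deletion [98, 100] overlaps the window by one base
        read = make_read(ref, [plan_deletion(ref, 98, 3)])
        got = extract_mutations(read, WINDOW)
        assert events_as_tuples(got) == [(98, "deletion", 3, "CGA")]

    def test_deletion_ending_before_window_is_out(self, ref):
        read = make_read(ref, [plan_deletion(ref, 96, 3)])
        assert extract_mutations(read, WINDOW) == []

    def test_per_base_granularity_splits_runs(self, ref):
        read = make_read(ref, [plan_deletion(ref, 103, 2)])
        assert len(extract_mutations(read, WINDOW, granularity="run")) == 1
        per_base = extract_mutations(read, WINDOW, granularity="base")
        assert events_as_tuples(per_base) == [
            (103, "deletion", 1, "A"),
            (104, "deletion", 1, "A"),
        ]

    def test_unknown_granularity_rejected(self, ref):
        read = make_read(ref)
        with pytest.raises(ValueError):
            extract_mutations(read, WINDOW, granularity="codon")

    def test_invalid_window_rejected(self, ref):
        with pytest.raises(ValueError):
            extract_mutations(make_read(ref), (110, 100))

    @settings(max_examples=80, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_oracle_equivalence_on_random_plans(self, seed):
        rng = np.random.default_rng(seed)
        win = ReferenceWindow("chrT", 90, "CGTCGGATCG" + "A" * 11 + "GTCCGATGGC")
        plan = random_mutation_plan(rng, win.start, win.seq)
        read = make_read(win, [MutationEvent(*e) for e in plan],
                         soft_clip=(int(rng.integers(0, 3)), int(rng.integers(0, 3))))
        expected = oracle_window_filter(
            oracle_events(read.seq, read.cigar, read.md, read.pos), *WINDOW
        )
        got = events_as_tuples(extract_mutations(read, WINDOW))
        assert sorted(got) == sorted(expected)
        # and the oracle's own event walk agrees with the planned in-window set
        assert sorted(expected) == sorted(oracle_window_filter(plan, *WINDOW))

    def test_shift_invariance_under_upstream_indels(self, ref):
        in_window = [MutationEvent(104, "insertion", 1, "A")]
        plain = make_read(ref, in_window)
        shifted = make_read(ref, [plan_deletion(ref, 92, 2)] + in_window)
        also_shifted = make_read(ref, [MutationEvent(91, "insertion", 3, "TTT")] + in_window)
        baseline = extract_mutations(plain, WINDOW)
        assert extract_mutations(shifted, WINDOW) == baseline
        assert extract_mutations(also_shifted, WINDOW) == baseline


class TestLocusMetrics:
    def test_percentages(self):
        m = LocusMetrics("L", "G", n_total_reads=10, n_mutated_reads=4,
                         n_mutation_events=7)
        assert m.pct_mutated_reads == pytest.approx(40.0)
        assert m.pct_total_mutations == pytest.approx(70.0)

    def test_uncovered_flagged(self):
        m = LocusMetrics("L", "G", 0, 0, 0)
        assert not m.covered
        assert m.pct_mutated_reads is None
        assert m.pct_total_mutations is None

    def test_events_may_exceed_reads(self):
        m = LocusMetrics("L", "G", 5, 5, 30)
        assert m.pct_total_mutations == pytest.approx(600.0)

    def test_mutated_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            LocusMetrics("L", "G", 3, 4, 4)


class TestComputeLocusMetrics:
    def test_counts(self, ref, locus_a11):
        reads = [make_read(ref, qname=f"clean{i}") for i in range(6)]
        reads += [
            make_read(ref, [MutationEvent(102, "insertion", 1, "A"),
                            plan_deletion(ref, 106, 1)], qname="two_events"),
            make_read(ref, [plan_deletion(ref, 104, 1)], qname="one_event"),
        ]
        m = compute_locus_metrics(reads, locus_a11)
        assert (m.n_total_reads, m.n_mutated_reads, m.n_mutation_events) == (8, 2, 3)

    def test_upstream_event_does_not_mark_read_mutated(self, ref, locus_a11):
        reads = [make_read(ref, [plan_deletion(ref, 93, 1)], qname="up")]
        m = compute_locus_metrics(reads, locus_a11)
        assert m.n_mutated_reads == 0

    def test_zero_reads_flagged_uncovered(self, locus_a11):
        m = compute_locus_metrics([], locus_a11)
        assert not m.covered


def _metrics(locus_id, gene, total, mutated, events):
    return LocusMetrics(locus_id, gene, total, mutated, events)


class TestComputeSampleScore:
    def _panel(self, *loci):
        return Panel(loci=tuple(loci))

    def test_single_gene_single_locus(self):
        panel = self._panel(MicrosatelliteLocus("L1", "G1", "c", 100, 110, "A"))
        score = compute_sample_score([_metrics("L1", "G1", 10, 4, 7)], panel)
        assert score.mean_pct_mutated_reads == pytest.approx(40.0)
        assert score.mean_pct_total_mutations == pytest.approx(70.0)
        assert score.n_genes_used == 1

    def test_two_gene_mean(self):
        panel = self._panel(
            MicrosatelliteLocus("L1", "G1", "c", 100, 110, "A"),
            MicrosatelliteLocus("L2", "G2", "c", 200, 210, "A"),
        )
        score = compute_sample_score(
            [_metrics("L1", "G1", 10, 2, 2), _metrics("L2", "G2", 10, 6, 6)], panel
        )
        assert score.mean_pct_mutated_reads == pytest.approx(40.0)

    def test_uncovered_gene_excluded_from_mean(self):
        panel = self._panel(
            MicrosatelliteLocus("L1", "G1", "c", 100, 110, "A"),
            MicrosatelliteLocus("L2", "G2", "c", 200, 210, "A"),
        )
        score = compute_sample_score(
            [_metrics("L1", "G1", 10, 5, 5), _metrics("L2", "G2", 0, 0, 0)], panel
        )
        assert score.mean_pct_mutated_reads == pytest.approx(50.0)
        assert score.n_genes_used == 1

    def test_gene_pooling_before_cross_gene_mean(self):
        panel = self._panel(
            MicrosatelliteLocus("L1", "G1", "c", 100, 110, "A"),
            MicrosatelliteLocus("L2", "G1", "c", 200, 210, "A"),
        )
        metrics = [_metrics("L1", "G1", 10, 1, 1), _metrics("L2", "G1", 30, 9, 9)]
        pooled = compute_sample_score(metrics, panel, aggregation="pool")
        assert pooled.mean_pct_mutated_reads == pytest.approx(100 * 10 / 40)
        by_locus = compute_sample_score(metrics, panel, aggregation="mean_loci")
        assert by_locus.mean_pct_mutated_reads == pytest.approx((10.0 + 30.0) / 2)

    def test_no_covered_gene_raises(self):
        panel = self._panel(MicrosatelliteLocus("L1", "G1", "c", 100, 110, "A"))
        with pytest.raises(ValueError, match="no gene"):
            compute_sample_score([_metrics("L1", "G1", 0, 0, 0)], panel)

    def test_monotonicity_under_added_reads(self, ref, locus_a11):
        panel = Panel(loci=(locus_a11,))
        base_reads = [make_read(ref, qname=f"c{i}") for i in range(5)]
        base_reads.append(
            make_read(ref, [MutationEvent(103, "insertion", 1, "A")], qname="m")
        )

        def score_of(reads):
            return compute_sample_score(
                [compute_locus_metrics(reads, locus_a11)], panel
            )

        base = score_of(base_reads)
        # adding a mutated read never decreases the numerators
        m0 = compute_locus_metrics(base_reads, locus_a11)
        m1 = compute_locus_metrics(
            base_reads + [make_read(ref, [plan_deletion(ref, 105, 1)], qname="m2")],
            locus_a11,
        )
        assert m1.n_mutated_reads == m0.n_mutated_reads + 1
        assert m1.n_mutation_events == m0.n_mutation_events + 1
        # adding an event-free read never increases either percentage
        clean = score_of(base_reads + [make_read(ref, qname="c99")])
        assert clean.mean_pct_mutated_reads <= base.mean_pct_mutated_reads
        assert clean.mean_pct_total_mutations <= base.mean_pct_total_mutations
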