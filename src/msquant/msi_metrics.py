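"""Mutation-event extraction inside microsatellite windows and instability metrics.

Two sample-level dimensions are scored: the percentage of mutated reads per
locus, and the percentage of total mutation events relative to total reads.
The second may legitimately exceed 100% when reads carry several events.
Gene-level counts are pooled across a gene's covered loci before the
cross-gene mean (a mean-over-loci mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .panel import MicrosatelliteLocus, Panel, reads_for_locus
from .refrecon import MdCursor, ReconstructionError, parse_md
from .sam_model import AlignedRead

__all__ = [
    "MutationEvent",
    "LocusMetrics",
    "SampleScore",
    "Granularity",
    "Aggregation",
    "extract_mutations",
    "compute_locus_metrics",
    "compute_sample_score",
]

Granularity = Literal["run", "base"]
Aggregation = Literal["pool", "mean_loci"]

_KINDS = ("insertion", "deletion", "substitution")


@dataclass(frozen=True, order=True)
class MutationEvent:
    """One indel run or substituted base, anchored to reference coordinates.

    ``ref_pos`` is 1-based: for an insertion it is the reference base the
    inserted bases follow; for a deletion or substitution it is the first
    affected reference base. ``bases`` holds the inserted bases, the deleted
    reference bases, or the observed (read) base for a substitution.
    """

    ref_pos: int
    kind: str
    length: int
    bases: str

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if self.kind == "substitution" and self.length != 1:
            raise ValueError("substitution events have length exactly 1")
        if self.kind in ("insertion", "deletion") and len(self.bases) != self.length:
            raise ValueError("indel bases must match event length")


def _walk_read_events(read: AlignedRead) -> list[MutationEvent]:
    """All mutation events on a read, from a joint CIGAR/MD walk."""
    if not read.cigar:
        raise ReconstructionError(f"read {read.qname}: no CIGAR")
    if read.md is None:
        raise ReconstructionError(f"read {read.qname}: no MD tag")
    if read.seq is None:
        raise ReconstructionError(f"read {read.qname}: no SEQ")
    cursor = MdCursor(parse_md(read.md), source=read.md)
    events: list[MutationEvent] = []
    ref = read.pos  # next reference coordinate to consume
    qi = 0
    for op, length in read.cigar:
        if op in "M=X":
            for _ in range(length):
                mismatch = cursor.take_match()
                if mismatch is not None:
                    events.append(
                        MutationEvent(
                            ref_pos=ref,
                            kind="substitution",
                            length=1,
                            bases=read.seq[qi],
                        )
                    )
                ref += 1
                qi += 1
        elif op == "I":
            events.append(
                MutationEvent(
                    ref_pos=ref - 1,  # anchored to the base it follows
                    kind="insertion",
                    length=length,
                    bases=read.seq[qi : qi + length],
                )
            )
            qi += length
        elif op == "D":
            events.append(
                MutationEvent(
                    ref_pos=ref,
                    kind="deletion",
                    length=length,
                    bases=cursor.take_deletion(length),
                )
            )
            ref += length
        elif op == "S":
            qi += length
        elif op == "N":
            ref += length
        # H and P consume nothing
    cursor.finish()
    return events


def _split_per_base(events: list[MutationEvent]) -> list[MutationEvent]:
    out: list[MutationEvent] = []
    for ev in events:
        if ev.kind == "deletion" and ev.length > 1:
            out.extend(
                MutationEvent(ev.ref_pos + i, "deletion", 1, ev.bases[i])
                for i in range(ev.length)
            )
        elif ev.kind == "insertion" and ev.length > 1:
            # all inserted bases share the same anchor
            out.extend(
                MutationEvent(ev.ref_pos, "insertion", 1, b) for b in ev.bases
            )
        else:
            out.append(ev)
    return out


def extract_mutations(
    read: AlignedRead,
    window: tuple[int, int],
    granularity: Granularity = "run",
) -> list[MutationEvent]:
    """Mutation events whose anchor falls inside ``window`` (1-based inclusive).

    Windowing rules:

    * substitutions are in iff ``wstart <= ref_pos <= wend``;
    * deletions are in iff any deleted base overlaps the window;
    * insertions are in iff ``wstart - 1 <= ref_pos <= wend`` — an insertion
      anchored immediately before the first repeat base changes the tract
      length and is counted as part of the repeat.

    ``granularity="run"`` (default) emits one event per contiguous indel run;
    ``"base"`` splits runs into single-base events.
    """
    wstart, wend = window
    if wstart > wend:
        raise ValueError(f"invalid window [{wstart}, {wend}]")
    events = _walk_read_events(read)
    if granularity == "base":
        events = _split_per_base(events)
    elif granularity != "run":
        raise ValueError(f"unknown granularity {granularity!r}")
    kept: list[MutationEvent] = []
    for ev in events:
        if ev.kind == "substitution":
            if wstart <= ev.ref_pos <= wend:
                kept.append(ev)
        elif ev.kind == "deletion":
            if ev.ref_pos <= wend and ev.ref_pos + ev.length - 1 >= wstart:
                kept.append(ev)
        else:  # insertion
            if wstart - 1 <= ev.ref_pos <= wend:
                kept.append(ev)
    return kept


@dataclass(frozen=True)
class LocusMetrics:
    """Per-locus read and mutation-event counts with derived percentages."""

    locus_id: str
    gene: str
    n_total_reads: int
    n_mutated_reads: int
    n_mutation_events: int

    def __post_init__(self) -> None:
        if self.n_mutated_reads > self.n_total_reads:
            raise ValueError("n_mutated_reads cannot exceed n_total_reads")
        if min(self.n_total_reads, self.n_mutated_reads, self.n_mutation_events) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def covered(self) -> bool:
        return self.n_total_reads > 0

    @property
    def pct_mutated_reads(self) -> float | None:
        """Percentage of reads with at least one in-window event; None if uncovered."""
        if not self.covered:
            return None
        return 100.0 * self.n_mutated_reads / self.n_total_reads

    @property
    def pct_total_mutations(self) -> float | None:
        """Total in-window events per 100 reads; may exceed 100. None if uncovered."""
        if not self.covered:
            return None
        return 100.0 * self.n_mutation_events / self.n_total_reads


@dataclass(frozen=True)
class SampleScore:
    """Sample-level instability score: unweighted means over covered genes."""

    sample_id: str
    mean_pct_mutated_reads: float
    mean_pct_total_mutations: float
    n_genes_used: int
    locus_metrics: tuple[LocusMetrics, ...] = ()


def compute_locus_metrics(
    reads: Iterable[AlignedRead],
    locus: MicrosatelliteLocus,
    flank: int = 1,
    granularity: Granularity = "run",
) -> LocusMetrics:
    """Count covering reads, mutated reads and mutation events at one locus.

    The event window is the repeat tract ``[start, end]`` (with the
    insertion-at-``start - 1`` rule of :func:`extract_mutations`); read
    assignment requires coverage of the flanked interval.
    """
    assigned = reads_for_locus(reads, locus, flank)
    window = (locus.start, locus.end)
    n_mutated = 0
    n_events = 0
    for read in assigned:
        events = extract_mutations(read, window, granularity)
        if events:
            n_mutated += 1
            n_events += len(events)
    return LocusMetrics(
        locus_id=locus.locus_id,
        gene=locus.gene,
        n_total_reads=len(assigned),
        n_mutated_reads=n_mutated,
        n_mutation_events=n_events,
    )


def compute_sample_score(
    metrics: Sequence[LocusMetrics],
    panel: Panel,
    sample_id: str = "sample",
    aggregation: Aggregation = "pool",
) -> SampleScore:
    """Aggregate locus metrics into the two sample-level mean percentages.

    With ``aggregation="pool"`` (default) counts are summed over each gene's
    covered loci before forming the gene's percentages; ``"mean_loci"``
    averages the per-locus percentages instead. Genes with no covered locus
    are excluded from the cross-gene mean.
    """
    by_id = {m.locus_id: m for m in metrics}
    gene_pcts: list[tuple[float, float]] = []
    for gene, loci in panel.by_gene().items():
        covered = [
            by_id[l.locus_id]
            for l in loci
            if l.locus_id in by_id and by_id[l.locus_id].covered
        ]
        if not covered:
            continue
        if aggregation == "pool":
            reads = sum(m.n_total_reads for m in covered)
            mutated = sum(m.n_mutated_reads for m in covered)
            events = sum(m.n_mutation_events for m in covered)
            gene_pcts.append((100.0 * mutated / reads, 100.0 * events / reads))
        elif aggregation == "mean_loci":
            gene_pcts.append(
                (
                    sum(m.pct_mutated_reads for m in covered) / len(covered),
                    sum(m.pct_total_mutations for m in covered) / len(covered),
                )
            )
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    if not gene_pcts:
        raise ValueError(
            f"sample {sample_id}: no gene with a covered locus; cannot score"
        )
    n = len(gene_pcts)
    return SampleScore(
        sample_id=sample_id,
        mean_pct_mutated_reads=sum(p[0] for p in gene_pcts) / n,
        mean_pct_total_mutations=sum(p[1] for p in gene_pcts) / n,
        n_genes_used=n,
        locus_metrics=tuple(metrics),
    )
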