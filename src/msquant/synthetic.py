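"""Synthetic aligned-read generation.

Builds reads whose SEQ, CIGAR, MD and NM fields are mutually consistent from
an explicit reference window and a planned mutation list, so that reference
reconstruction inverts generation exactly. Also provides the three functional
test scenarios (upstream indel, multiple independent in-tract indels,
boundary indel) and a seeded sample/cohort simulator that stands in for
non-deposited patient data.

MD strings are generated from first principles so the test suite carries no
binary tool dependency.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .msi_metrics import MutationEvent
from .panel import MicrosatelliteLocus, Panel
from .refrecon import ReferenceWindow
from .sam_model import AlignedRead

__all__ = [
    "MutationSpecError",
    "CohortModel",
    "TestCaseBundle",
    "make_read",
    "plan_deletion",
    "locus_reference",
    "demo_panel",
    "test_case_fixtures",
    "simulate_reads",
    "simulate_sample",
    "simulate_cohort",
    "write_sam",
]

_BASES = "ACGT"


class MutationSpecError(ValueError):
    """Planned mutation list is inconsistent with its reference window."""


@dataclass(frozen=True)
class CohortModel:
    """Generative model for a two-class cohort of amplicon samples.

    Each read independently acquires a slippage-style indel (one repeat unit,
    insertion or deletion, uniform position in the tract) with the per-class
    rate, plus per-base substitution noise over its aligned span.
    """

    n_msi: int
    n_mss: int
    reads_per_locus: int = 50
    indel_rate_msi: float = 0.6
    indel_rate_mss: float = 0.02
    substitution_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("indel_rate_msi", "indel_rate_mss", "substitution_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.reads_per_locus < 1:
            raise ValueError("reads_per_locus must be >= 1")
        if self.n_msi < 0 or self.n_mss < 0:
            raise ValueError("sample counts must be >= 0")


@dataclass(frozen=True)
class TestCaseBundle:
    """One functional scenario: reads over a repeat window plus the expected
    in-window event list."""

    name: str
    description: str
    reads: tuple[AlignedRead, ...]
    window: tuple[int, int]
    expected_events: tuple[MutationEvent, ...]
    reference: ReferenceWindow


def plan_deletion(window: ReferenceWindow, ref_pos: int, length: int) -> MutationEvent:
    """Deletion event with bases taken from the reference window."""
    if ref_pos < window.start or ref_pos + length - 1 > window.end:
        raise MutationSpecError(
            f"deletion [{ref_pos}, {ref_pos + length - 1}] outside window"
        )
    off = ref_pos - window.start
    return MutationEvent(ref_pos, "deletion", length, window.seq[off : off + length])


def _validate_spec(
    window: ReferenceWindow, events: Sequence[MutationEvent]
) -> tuple[dict[int, str], dict[int, str], dict[int, str]]:
    """Index events by reference position; enforce non-overlap and bounds."""
    deletions: dict[int, str] = {}  # every deleted position -> its ref base
    substitutions: dict[int, str] = {}
    insertions: dict[int, str] = {}
    occupied: set[int] = set()
    for ev in events:
        if ev.kind == "deletion":
            if ev.ref_pos < window.start or ev.ref_pos + ev.length - 1 > window.end:
                raise MutationSpecError(f"deletion at {ev.ref_pos} outside window")
            off = ev.ref_pos - window.start
            ref_slice = window.seq[off : off + ev.length]
            if ev.bases != ref_slice:
                raise MutationSpecError(
                    f"deletion bases {ev.bases!r} do not match reference "
                    f"{ref_slice!r} at {ev.ref_pos} (use plan_deletion)"
                )
            span = range(ev.ref_pos, ev.ref_pos + ev.length)
            if occupied & set(span):
                raise MutationSpecError(f"overlapping events at {ev.ref_pos}")
            occupied.update(span)
            for i, p in enumerate(span):
                deletions[p] = ev.bases[i]
        elif ev.kind == "substitution":
            if not window.start <= ev.ref_pos <= window.end:
                raise MutationSpecError(f"substitution at {ev.ref_pos} outside window")
            if ev.ref_pos in occupied:
                raise MutationSpecError(f"overlapping events at {ev.ref_pos}")
            ref_base = window.seq[ev.ref_pos - window.start]
            if ev.bases == ref_base:
                raise MutationSpecError(
                    f"substitution at {ev.ref_pos} equals reference base {ref_base!r}"
                )
            occupied.add(ev.ref_pos)
            substitutions[ev.ref_pos] = ev.bases
        else:  # insertion
            if not window.start - 1 <= ev.ref_pos <= window.end:
                raise MutationSpecError(f"insertion anchor {ev.ref_pos} outside window")
            if ev.ref_pos in insertions:
                raise MutationSpecError(f"two insertions anchored at {ev.ref_pos}")
            insertions[ev.ref_pos] = ev.bases
    for anchor in insertions:
        if anchor in deletions:
            raise MutationSpecError(
                f"insertion anchored at deleted position {anchor}"
            )
    return deletions, substitutions, insertions


def make_read(
    window: ReferenceWindow,
    events: Sequence[MutationEvent] = (),
    *,
    soft_clip: tuple[int, int] = (0, 0),
    clip_fill: str = "ACGT",
    qname: str = "read",
    flag: int = 0,
    mapq: int = 60,
) -> AlignedRead:
    """Emit a read aligned to ``window`` carrying exactly ``events``.

    SEQ, CIGAR, MD and NM are built jointly and mutually consistent:
    reconstructing the reference from the read recovers ``window.seq`` and
    NM equals the recomputed edit distance. Soft-clip bases are filled
    deterministically by cycling ``clip_fill``.
    """
    deletions, substitutions, insertions = _validate_spec(window, events)

    cigar: list[tuple[str, int]] = []

    def add_op(op: str, n: int) -> None:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    # MD assembled as alternating (match count | mismatch | deletion) tokens
    md_tokens: list[list] = []  # ["num", n] | ["sub", base] | ["del", bases]
    match_count = 0
    seq: list[str] = []
    nm = 0

    def flush_match() -> None:
        nonlocal match_count
        md_tokens.append(["num", match_count])
        match_count = 0

    if window.start - 1 in insertions:
        bases = insertions[window.start - 1]
        seq.append(bases)
        add_op("I", len(bases))
        nm += len(bases)

    prev_deleted = False
    for p in range(window.start, window.end + 1):
        ref_base = window.seq[p - window.start]
        if p in deletions:
            add_op("D", 1)
            if prev_deleted and md_tokens and md_tokens[-1][0] == "del":
                md_tokens[-1][1] += ref_base
            else:
                flush_match()
                md_tokens.append(["del", ref_base])
            nm += 1
            prev_deleted = True
        else:
            if p in substitutions:
                flush_match()
                md_tokens.append(["sub", ref_base])
                seq.append(substitutions[p])
                nm += 1
            else:
                match_count += 1
                seq.append(ref_base)
            add_op("M", 1)
            prev_deleted = False
        if p in insertions and p >= window.start:
            bases = insertions[p]
            seq.append(bases)
            add_op("I", len(bases))
            nm += len(bases)
            prev_deleted = False
    flush_match()

    md = "".join(
        str(tok[1]) if tok[0] == "num" else tok[1] if tok[0] == "sub" else "^" + tok[1]
        for tok in md_tokens
    )

    left, right = soft_clip
    if left < 0 or right < 0:
        raise MutationSpecError("soft-clip lengths must be >= 0")
    fill = clip_fill * (max(left, right) // len(clip_fill) + 1)
    if left:
        seq.insert(0, fill[:left])
        cigar.insert(0, ("S", left))
    if right:
        seq.append(fill[:right])
        cigar.append(("S", right))

    return AlignedRead(
        qname=qname,
        flag=flag,
        rname=window.chrom,
        pos=window.start,
        mapq=mapq,
        cigar=tuple(cigar),
        seq="".join(seq),
        md=md,
        nm=nm,
    )


def demo_panel() -> Panel:
    """Ten mononucleotide loci across five MSI-relevant genes.

    Coordinates are synthetic placeholders for simulation and testing only —
    this is NOT a clinically validated panel.
    """
    spec = [
        # gene, chrom, start, run base, run length
        ("ACVR2A", "chr2", 2_000, "A", 11),
        ("ACVR2A", "chr2", 2_600, "A", 13),
        ("RNF43", "chr17", 5_000, "T", 12),
        ("RNF43", "chr17", 5_600, "A", 10),
        ("TGFBR2", "chr3", 8_000, "A", 10),
        ("TGFBR2", "chr3", 8_600, "T", 14),
        ("HSP110", "chr13", 11_000, "T", 15),
        ("HSP110", "chr13", 11_600, "A", 12),
        ("BRAF", "chr7", 14_000, "A", 11),
        ("BRAF", "chr7", 14_600, "T", 13),
    ]
    loci = []
    counters: dict[str, int] = {}
    for gene, chrom, start, base, length in spec:
        counters[gene] = counters.get(gene, 0) + 1
        loci.append(
            MicrosatelliteLocus(
                locus_id=f"{gene}_{counters[gene]}",
                gene=gene,
                chrom=chrom,
                start=start,
                end=start + length - 1,
                repeat_unit=base,
            )
        )
    return Panel(loci=tuple(loci), name="demo10")


def locus_reference(locus: MicrosatelliteLocus, margin: int = 30) -> ReferenceWindow:
    """Deterministic synthetic reference context around a locus.

    Flank bases derive from a per-locus seed (CRC32 of the locus_id), so every
    sample in a cohort sees the same reference. Flank bases immediately
    adjoining the tract are forced to differ from the repeat base so the
    declared tract boundaries are the true homopolymer boundaries.
    """
    rng = np.random.default_rng(zlib.crc32(locus.locus_id.encode()))
    unit = locus.repeat_unit
    tract = (unit * (locus.length // len(unit) + 1))[: locus.length]

    def flank(n: int, avoid: str) -> str:
        bases = rng.choice(list(_BASES), size=n)
        out = "".join(bases)
        # force the tract-adjacent base away from the repeat base
        choices = [b for b in _BASES if b != avoid]
        return out, choices[int(rng.integers(len(choices)))]

    left_raw, left_adj = flank(margin - 1, tract[0])
    right_raw, right_adj = flank(margin - 1, tract[-1])
    seq = left_raw + left_adj + tract + right_adj + right_raw
    return ReferenceWindow(chrom=locus.chrom, start=locus.start - margin, seq=seq)


def _random_read_events(
    ref: ReferenceWindow,
    read_win: ReferenceWindow,
    locus: MicrosatelliteLocus,
    indel_rate: float,
    substitution_rate: float,
    rng: np.random.Generator,
) -> list[MutationEvent]:
    events: list[MutationEvent] = []
    occupied: set[int] = set()
    unit_len = len(locus.repeat_unit)
    if rng.random() < indel_rate:
        if rng.random() < 0.5 and locus.length > unit_len:
            # slippage contraction
            pos = int(rng.integers(locus.start, locus.end - unit_len + 2))
            ev = plan_deletion(read_win, pos, unit_len)
            events.append(ev)
            occupied.update(range(pos, pos + unit_len))
        else:
            # slippage expansion; anchor may sit just before the first tract base
            anchor = int(rng.integers(locus.start - 1, locus.end + 1))
            events.append(
                MutationEvent(anchor, "insertion", unit_len, locus.repeat_unit)
            )
    if substitution_rate > 0:
        for p in range(read_win.start, read_win.end + 1):
            if p in occupied or rng.random() >= substitution_rate:
                continue
            ref_base = read_win.seq[p - read_win.start]
            alt = [b for b in _BASES if b != ref_base]
            events.append(
                MutationEvent(p, "substitution", 1, alt[int(rng.integers(3))])
            )
            occupied.add(p)
    return events


def simulate_reads(
    panel: Panel,
    sample_class: str,
    model: CohortModel,
    sample_id: str,
    rng: np.random.Generator,
    margin: int = 30,
) -> list[AlignedRead]:
    """Draw the full read set of one sample (in panel/locus order)."""
    if sample_class not in ("MSI", "MSS"):
        raise ValueError(f"sample_class must be MSI or MSS, got {sample_class!r}")
    indel_rate = (
        model.indel_rate_msi if sample_class == "MSI" else model.indel_rate_mss
    )
    reads: list[AlignedRead] = []
    for locus in panel:
        ref = locus_reference(locus, margin)
        for i in range(model.reads_per_locus):
            up = int(rng.integers(5, margin - 4))
            down = int(rng.integers(5, margin - 4))
            read_win = ref.slice(locus.start - up, locus.end + down)
            events = _random_read_events(
                ref, read_win, locus, indel_rate, model.substitution_rate, rng
            )
            clips = (0, 0)
            if rng.random() < 0.25:
                clips = (int(rng.integers(1, 5)), 0)
            if rng.random() < 0.25:
                clips = (clips[0], int(rng.integers(1, 5)))
            reads.append(
                make_read(
                    read_win,
                    events,
                    soft_clip=clips,
                    qname=f"{sample_id}:{locus.locus_id}:{i}",
                )
            )
    return reads


def write_sam(reads: Sequence[AlignedRead], panel: Panel, path: str | Path) -> Path:
    """Write reads as a headered SAM text file (deterministic byte layout)."""
    path = Path(path)
    chrom_len: dict[str, int] = {}
    for locus in panel:
        chrom_len[locus.chrom] = max(
            chrom_len.get(locus.chrom, 0), locus.end + 1000
        )
    for read in reads:
        end = read.reference_span[1] if read.cigar else read.pos
        chrom_len[read.rname] = max(chrom_len.get(read.rname, 0), end + 100)
    with path.open("w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(chrom_len):
            handle.write(f"@SQ\tSN:{chrom}\tLN:{chrom_len[chrom]}\n")
        for read in reads:
            cigar = "".join(f"{n}{op}" for op, n in read.cigar) or "*"
            seq = read.seq or "*"
            qual = "F" * len(seq) if read.seq else "*"
            fields = [
                read.qname,
                str(read.flag),
                read.rname,
                str(read.pos),
                str(read.mapq),
                cigar,
                "*",
                "0",
                "0",
                seq,
                qual,
            ]
            if read.nm is not None:
                fields.append(f"NM:i:{read.nm}")
            if read.md is not None:
                fields.append(f"MD:Z:{read.md}")
            handle.write("\t".join(fields) + "\n")
    return path


def simulate_sample(
    panel: Panel,
    sample_class: str,
    model: CohortModel,
    sample_id: str,
    out_path: str | Path,
    rng: np.random.Generator | None = None,
) -> Path:
    """Simulate one sample and write it as SAM; deterministic under a seed."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    reads = simulate_reads(panel, sample_class, model, sample_id, rng)
    return write_sam(reads, panel, out_path)


def simulate_cohort(
    model: CohortModel,
    panel: Panel,
    out_dir: str | Path,
) -> dict:
    """Simulate a labeled cohort, score every sample through the full
    quantification pipeline, and write the calibration input table.

    Writes ``<out_dir>/sams/<sample>.sam``, ``scores.tsv`` (sample_id, the two
    mean percentages, truth label) and ``cohort.json``. Returns the manifest
    dictionary (paths plus per-sample rows).
    """
    from .pipeline import score_sam_file  # deferred: pipeline is a consumer too

    out_dir = Path(out_dir)
    sam_dir = out_dir / "sams"
    sam_dir.mkdir(parents=True, exist_ok=True)
    plan = [("MSI", i) for i in range(model.n_msi)] + [
        ("MSS", i) for i in range(model.n_mss)
    ]
    rows: list[dict] = []
    for sample_index, (label, i) in enumerate(plan):
        sample_id = f"{label}_{i + 1:02d}"
        rng = np.random.default_rng([model.seed, sample_index])
        sam_path = sam_dir / f"{sample_id}.sam"
        reads = simulate_reads(panel, label, model, sample_id, rng)
        write_sam(reads, panel, sam_path)
        score = score_sam_file(sam_path, panel, sample_id=sample_id).score
        rows.append(
            {
                "sample_id": sample_id,
                "pct_mutated_reads": score.mean_pct_mutated_reads,
                "pct_total_mutations": score.mean_pct_total_mutations,
                "label": label,
            }
        )
    scores_path = out_dir / "scores.tsv"
    with scores_path.open("w") as handle:
        handle.write("sample_id\tpct_mutated_reads\tpct_total_mutations\tlabel\n")
        for row in rows:
            handle.write(
                f"{row['sample_id']}\t{row['pct_mutated_reads']:.6f}\t"
                f"{row['pct_total_mutations']:.6f}\t{row['label']}\n"
            )
    manifest = {
        "model": {
            "n_msi": model.n_msi,
            "n_mss": model.n_mss,
            "reads_per_locus": model.reads_per_locus,
            "indel_rate_msi": model.indel_rate_msi,
            "indel_rate_mss": model.indel_rate_mss,
            "substitution_rate": model.substitution_rate,
            "seed": model.seed,
        },
        "panel": panel.name,
        "scores": scores_path.name,
        "samples": rows,
    }
    import json

    with (out_dir / "cohort.json").open("w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest


def test_case_fixtures() -> tuple[TestCaseBundle, TestCaseBundle, TestCaseBundle]:
    """The three functional scenarios, each one read over an A(11) tract at
    [100, 110] inside a 31-base reference window starting at 90.

    Case 1: indel strictly upstream of the tract — no in-window events.
    Case 2: three independent indels inside the tract — exactly three events.
    Case 3: insertion anchored immediately before the first tract base —
    one event under the tract-length-change boundary rule.
    """
    ref = ReferenceWindow(
        chrom="chrT",
        start=90,
        seq="CGTCGGATCG" + "A" * 11 + "GTCCGATGGC",
    )
    window = (100, 110)

    del_95 = plan_deletion(ref, 95, 1)
    case1 = TestCaseBundle(
        name="case1_upstream_indel",
        description="deletion at 95, upstream of the tract; query offsets shift "
        "but no in-window event may be reported",
        reads=(make_read(ref, [del_95], qname="tc1"),),
        window=window,
        expected_events=(),
        reference=ref,
    )

    ev2 = (
        MutationEvent(101, "insertion", 1, "A"),
        plan_deletion(ref, 104, 1),
        MutationEvent(107, "insertion", 1, "A"),
    )
    case2 = TestCaseBundle(
        name="case2_multiple_indels",
        description="three independent indels inside the tract; all three "
        "must be counted",
        reads=(make_read(ref, list(ev2), qname="tc2"),),
        window=window,
        expected_events=ev2,
        reference=ref,
    )

    ev3 = (MutationEvent(99, "insertion", 1, "A"),)
    case3 = TestCaseBundle(
        name="case3_boundary_insertion",
        description="insertion anchored at window start - 1: a repeat-unit "
        "insertion before the first tract base changes the tract length and "
        "counts as part of the microsatellite",
        reads=(make_read(ref, list(ev3), qname="tc3"),),
        window=window,
        expected_events=ev3,
        reference=ref,
    )
    return case1, case2, case3
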