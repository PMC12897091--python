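"""End-to-end workflow orchestration: parse -> filter -> assign -> reference ->
extract -> score -> classify, plus cutoff calibration and concordance runs.

All outputs are deterministic for fixed inputs and configuration: TSV rows
follow panel order, JSON is written with sorted keys, and reports carry the
tool version plus config/panel hashes instead of timestamps.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import __version__
from .msi_metrics import (
    Aggregation,
    Granularity,
    LocusMetrics,
    SampleScore,
    compute_locus_metrics,
    compute_sample_score,
)
from .msi_stats import (
    ContingencyTable,
    classify_msi,
    concordance_stats,
    roc_curve,
    youden_optimal_cutoff,
)
from .panel import Panel, load_panel, reads_for_locus
from .refrecon import NoReferenceError, build_locus_reference
from .sam_model import AlignedRead, ReadFilterPolicy, filter_reads, parse_sam_record

__all__ = [
    "PipelineError",
    "RunConfig",
    "SampleResult",
    "read_alignments",
    "score_reads",
    "score_sam_file",
    "run_sample",
    "run_calibrate",
    "run_concord",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("pct_mutated_reads", "pct_total_mutations")


class PipelineError(RuntimeError):
    """A stage-specific, user-facing pipeline failure."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one per-sample quantification run."""

    alignments: str
    panel: str
    out_dir: str
    sample_id: str = "sample"
    min_mapq: int = 60
    flank: int = 1
    granularity: Granularity = "run"
    aggregation: Aggregation = "pool"
    cutoff_mutated_reads: float | None = None
    cutoff_total_mutations: float | None = None

    def __post_init__(self) -> None:
        for name in ("cutoff_mutated_reads", "cutoff_total_mutations"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive when supplied")


@dataclass(frozen=True)
class SampleResult:
    score: SampleScore
    stage_counts: dict
    locus_provenance: dict
    calls: tuple = ()


def read_alignments(path: str | Path) -> list[AlignedRead]:
    """Read a SAM text file (or BAM, via pysam when available) into records."""
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"alignment file not found: {path}")
    if path.suffix.lower() == ".bam":
        try:
            import pysam
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise PipelineError(
                "BAM input requires pysam; convert to SAM text or install pysam"
            ) from exc
        with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
            return [parse_sam_record(rec.to_string()) for rec in bam]
    reads: list[AlignedRead] = []
    with path.open() as handle:
        for line in handle:
            if line.startswith("@") or not line.strip():
                continue
            reads.append(parse_sam_record(line))
    return reads


def score_reads(
    reads: Sequence[AlignedRead],
    panel: Panel,
    *,
    policy: ReadFilterPolicy | None = None,
    flank: int = 1,
    granularity: Granularity = "run",
    aggregation: Aggregation = "pool",
    sample_id: str = "sample",
) -> SampleResult:
    """Run the quantification stages on an in-memory read set."""
    if len(panel) == 0:
        raise PipelineError("panel is empty; nothing to quantify")
    policy = policy or ReadFilterPolicy()
    passing = filter_reads(reads, policy)
    stage_counts = {
        "reads_total": len(reads),
        "reads_passing_filters": len(passing),
        "reads_failing_filters": len(reads) - len(passing),
        "reads_per_locus": {},
        "loci_without_coverage": [],
        "loci_without_reference": [],
    }
    metrics: list[LocusMetrics] = []
    provenance: dict[str, dict] = {}
    for locus in panel:
        assigned = reads_for_locus(passing, locus, flank)
        stage_counts["reads_per_locus"][locus.locus_id] = len(assigned)
        if not assigned:
            stage_counts["loci_without_coverage"].append(locus.locus_id)
            metrics.append(
                LocusMetrics(locus.locus_id, locus.gene, 0, 0, 0)
            )
            continue
        try:
            ref = build_locus_reference(assigned, locus, flank)
            provenance[locus.locus_id] = {
                "provenance": ref.provenance.value,
                "n_support": ref.n_support,
                "n_ambiguous": ref.n_ambiguous,
            }
        except NoReferenceError:
            # covered but reference indeterminable (no MD-tagged reads):
            # excluded from scoring, logged
            stage_counts["loci_without_reference"].append(locus.locus_id)
            logger.warning(
                "locus %s: no reference could be established", locus.locus_id
            )
            metrics.append(LocusMetrics(locus.locus_id, locus.gene, 0, 0, 0))
            continue
        metrics.append(
            compute_locus_metrics(assigned, locus, flank, granularity)
        )
    try:
        score = compute_sample_score(metrics, panel, sample_id, aggregation)
    except ValueError as exc:
        raise PipelineError(f"no evaluable loci: {exc}") from exc
    return SampleResult(score=score, stage_counts=stage_counts, locus_provenance=provenance)


def score_sam_file(
    path: str | Path,
    panel: Panel,
    *,
    policy: ReadFilterPolicy | None = None,
    flank: int = 1,
    granularity: Granularity = "run",
    aggregation: Aggregation = "pool",
    sample_id: str = "sample",
) -> SampleResult:
    return score_reads(
        read_alignments(path),
        panel,
        policy=policy,
        flank=flank,
        granularity=granularity,
        aggregation=aggregation,
        sample_id=sample_id,
    )


def _fmt(value: float | None) -> str:
    return "NA" if value is None else f"{value:.4f}"


def _sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    with path.open("w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def run_sample(config: RunConfig) -> SampleResult:
    """Quantify one sample and write locus metrics, the sample score, optional
    classification calls, and a reproducibility manifest to ``out_dir``."""
    panel = load_panel(config.panel)
    if len(panel) == 0:
        raise PipelineError(f"panel {config.panel} is empty")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    policy = ReadFilterPolicy(min_mapq=config.min_mapq)
    result = score_sam_file(
        config.alignments,
        panel,
        policy=policy,
        flank=config.flank,
        granularity=config.granularity,
        aggregation=config.aggregation,
        sample_id=config.sample_id,
    )
    score = result.score

    with (out_dir / "locus_metrics.tsv").open("w") as handle:
        handle.write(
            "locus_id\tgene\tn_total_reads\tn_mutated_reads\tn_mutation_events\t"
            "pct_mutated_reads\tpct_total_mutations\n"
        )
        for m in score.locus_metrics:
            handle.write(
                f"{m.locus_id}\t{m.gene}\t{m.n_total_reads}\t{m.n_mutated_reads}\t"
                f"{m.n_mutation_events}\t{_fmt(m.pct_mutated_reads)}\t"
                f"{_fmt(m.pct_total_mutations)}\n"
            )

    with (out_dir / "sample_score.tsv").open("w") as handle:
        handle.write(
            "sample_id\tmean_pct_mutated_reads\tmean_pct_total_mutations\tn_genes_used\n"
        )
        handle.write(
            f"{score.sample_id}\t{score.mean_pct_mutated_reads:.4f}\t"
            f"{score.mean_pct_total_mutations:.4f}\t{score.n_genes_used}\n"
        )

    calls = []
    cutoffs = {
        "pct_mutated_reads": config.cutoff_mutated_reads,
        "pct_total_mutations": config.cutoff_total_mutations,
    }
    scores = {
        "pct_mutated_reads": score.mean_pct_mutated_reads,
        "pct_total_mutations": score.mean_pct_total_mutations,
    }
    if any(v is not None for v in cutoffs.values()):
        with (out_dir / "calls.tsv").open("w") as handle:
            handle.write("sample_id\tmetric\tscore\tcutoff\tcall\n")
            for metric, cutoff in cutoffs.items():
                if cutoff is None:
                    continue
                call = classify_msi(scores[metric], cutoff, metric, score.sample_id)
                calls.append(call)
                handle.write(
                    f"{call.sample_id}\t{metric}\t{call.score:.4f}\t"
                    f"{call.cutoff:.4f}\t{call.call}\n"
                )
    agreement = (
        len({c.call for c in calls}) == 1 if len(calls) == 2 else None
    )

    manifest = {
        "tool": "msquant",
        "version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "panel_hash": _sha256_file(config.panel),
        "stage_counts": result.stage_counts,
        "locus_reference_provenance": result.locus_provenance,
        "sample_score": {
            "sample_id": score.sample_id,
            "mean_pct_mutated_reads": score.mean_pct_mutated_reads,
            "mean_pct_total_mutations": score.mean_pct_total_mutations,
            "n_genes_used": score.n_genes_used,
        },
        "calls": [
            {"metric": c.metric, "score": c.score, "cutoff": c.cutoff, "call": c.call}
            for c in calls
        ],
        "metric_agreement": agreement,
    }
    _write_json(out_dir / "run_manifest.json", manifest)
    return SampleResult(
        score=score,
        stage_counts=result.stage_counts,
        locus_provenance=result.locus_provenance,
        calls=tuple(calls),
    )


def _read_scores_table(path: str | Path) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"scores file not found: {path}")
    with path.open() as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        rows = list(reader)
    if not rows:
        raise PipelineError(f"scores file {path} is empty")
    required = {"sample_id", "label"} | set(METRIC_NAMES)
    missing = required - set(rows[0])
    if missing:
        raise PipelineError(
            f"scores file {path} missing columns: {', '.join(sorted(missing))}"
        )
    return rows


def run_calibrate(scores_path: str | Path, out_dir: str | Path) -> dict:
    """Calibrate both metrics by ROC/Youden from a labeled score table.

    Writes one ROC table per metric and ``calibration.json`` holding AUC,
    cutoff and Youden J for each metric independently.
    """
    rows = _read_scores_table(scores_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = [row["label"] for row in rows]
    calibration: dict[str, dict] = {}
    for metric in METRIC_NAMES:
        scores = [float(row[metric]) for row in rows]
        try:
            roc = roc_curve(scores, labels)
        except ValueError as exc:
            raise PipelineError(f"calibration failed for {metric}: {exc}") from exc
        cutoff, j = youden_optimal_cutoff(roc)
        with (out_dir / f"roc_{metric}.tsv").open("w") as handle:
            handle.write("threshold\tsensitivity\tspecificity\tfpr\n")
            for i, t in enumerate(roc.thresholds):
                handle.write(
                    f"{t:.6f}\t{roc.sensitivity[i]:.6f}\t"
                    f"{roc.specificity[i]:.6f}\t{roc.fpr[i]:.6f}\n"
                )
        calibration[metric] = {"auc": roc.auc, "cutoff": cutoff, "youden_j": j}
    payload = {
        "tool": "msquant",
        "version": __version__,
        "n_samples": len(rows),
        "n_positive": sum(1 for l in labels if l in ("MSI", "MSI-H")),
        "n_negative": sum(1 for l in labels if l == "MSS"),
        "metrics": calibration,
    }
    _write_json(out_dir / "calibration.json", payload)
    return payload


def run_concord(
    *,
    calls_path: str | Path | None = None,
    counts: tuple[int, int, int, int] | None = None,
    reference_method: str = "reference",
    test_method: str = "test",
    out_path: str | Path | None = None,
) -> dict:
    """Concordance report from a paired-calls TSV or explicit 2x2 counts.

    The calls TSV needs columns ``sample_id``, ``reference_call`` and
    ``test_call`` with values MSI/MSS; ``counts`` is (tp, fp, fn, tn).
    """
    if (calls_path is None) == (counts is None):
        raise PipelineError("provide exactly one of calls_path or counts")
    if counts is not None:
        tp, fp, fn, tn = counts
    else:
        path = Path(calls_path)
        if not path.exists():
            raise PipelineError(f"calls file not found: {path}")
        with path.open() as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            rows = list(reader)
        if not rows:
            raise PipelineError(f"calls file {path} is empty")
        required = {"sample_id", "reference_call", "test_call"}
        if required - set(rows[0]):
            raise PipelineError(
                f"calls file {path} must have columns {sorted(required)}"
            )
        tp = fp = fn = tn = 0
        for row in rows:
            ref_pos = row["reference_call"] in ("MSI", "MSI-H")
            test_pos = row["test_call"] in ("MSI", "MSI-H")
            if ref_pos and test_pos:
                tp += 1
            elif ref_pos:
                fn += 1
            elif test_pos:
                fp += 1
            else:
                tn += 1
    table = ContingencyTable(
        tp=tp, fp=fp, fn=fn, tn=tn,
        reference_method=reference_method, test_method=test_method,
    )
    stats = concordance_stats(table)
    report = {
        "tool": "msquant",
        "version": __version__,
        "reference_method": reference_method,
        "test_method": test_method,
        "table": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "sensitivity_pct": stats.sensitivity,
        "specificity_pct": stats.specificity,
        "concordance_pct": stats.concordance,
    }
    if out_path is not None:
        _write_json(Path(out_path), report)
    return report
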