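"""Cutoff calibration (ROC/Youden), sample dichotomization, the PCR
marker-panel rule, and concordance statistics against reference assays."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "RocCurve",
    "MsiCall",
    "PcrPanelResult",
    "ContingencyTable",
    "ConcordanceResult",
    "roc_curve",
    "youden_optimal_cutoff",
    "classify_msi",
    "pcr_call",
    "concordance_stats",
]

ThresholdDialect = Literal["observed", "midpoint"]


@dataclass(frozen=True)
class RocCurve:
    """ROC analysis result for the rule *positive iff score >= threshold*.

    ``thresholds`` are in descending order; the (fpr, tpr) sequence runs from
    (0, 0) implicitly at +inf to (1, 1) at the lowest threshold. ``auc`` is
    the trapezoidal integral, which equals the fraction of positive–negative
    score pairs correctly ordered with ties counted 1/2.
    """

    thresholds: tuple[float, ...]
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    fpr: tuple[float, ...]
    auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValueError(f"AUC out of [0, 1]: {self.auc}")


@dataclass(frozen=True)
class MsiCall:
    """Dichotomized instability call for one sample and one metric."""

    sample_id: str
    metric: str
    score: float
    cutoff: float
    call: str  # "MSI" | "MSS"


@dataclass(frozen=True)
class PcrPanelResult:
    """Fragment-length panel call: MSI-H iff >= threshold fraction of markers
    are unstable; MSI-L collapses to MSS."""

    markers: tuple[tuple[str, str], ...]  # (name, "stable" | "unstable")
    threshold: float
    n_unstable: int
    call: str  # "MSI-H" | "MSS"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 call table of a test method against a reference method."""

    tp: int
    fp: int
    fn: int
    tn: int
    reference_method: str = "reference"
    test_method: str = "test"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ConcordanceResult:
    """Sensitivity/specificity/overall agreement in percent (2 decimals).

    A metric is None when its denominator is zero (undefined)."""

    sensitivity: float | None
    specificity: float | None
    concordance: float | None


def _as_bool_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        known = {"MSI": True, "MSI-H": True, "MSS": False}
        try:
            return np.array([known[str(l)] for l in arr], dtype=bool)
        except KeyError as exc:
            raise ValueError(f"unknown label {exc.args[0]!r}; expected MSI/MSS")
    return arr.astype(bool)


def roc_curve(
    scores: Sequence[float],
    labels: Sequence,
    threshold_dialect: ThresholdDialect = "observed",
) -> RocCurve:
    """ROC curve with candidate thresholds taken from the data.

    ``threshold_dialect="observed"`` (default) uses the distinct observed
    scores; ``"midpoint"`` uses midpoints between adjacent distinct scores
    (plus the minimum score, so the all-positive corner stays reachable).
    Both trace the same ROC points, so the AUC is identical; only the
    numeric cutoff values differ.

    Labels may be booleans (True = positive/MSI) or the strings "MSI"/"MSS".
    Requires both classes present; AUC is trapezoidal over (fpr, tpr).
    """
    scores_arr = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if scores_arr.shape != y.shape or scores_arr.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes required for ROC analysis (got {n_pos} positive, "
            f"{n_neg} negative)"
        )
    uniq = np.unique(scores_arr)  # ascending
    if threshold_dialect == "observed":
        thresholds = uniq[::-1]
    elif threshold_dialect == "midpoint":
        mids = (uniq[1:] + uniq[:-1]) / 2.0
        thresholds = np.sort(np.concatenate((mids, uniq[:1])))[::-1]
    else:
        raise ValueError(f"unknown threshold dialect {threshold_dialect!r}")
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = scores_arr >= t
        sens[i] = (pred & y).sum() / n_pos
        spec[i] = (~pred & ~y).sum() / n_neg
    fpr = 1.0 - spec
    # integrate from the implicit (0, 0) point at +inf
    xs = np.concatenate(([0.0], fpr))
    ys = np.concatenate(([0.0], sens))
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(
        thresholds=tuple(thresholds.tolist()),
        sensitivity=tuple(sens.tolist()),
        specificity=tuple(spec.tolist()),
        fpr=tuple(fpr.tolist()),
        auc=auc,
    )


def youden_optimal_cutoff(roc: RocCurve) -> tuple[float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken deterministically: first toward higher specificity
    (avoid false instability calls), then toward the lower cutoff value.
    Returns ``(cutoff, J)``.
    """
    best: tuple[float, float, float] | None = None  # (J, spec, -cutoff)
    best_idx = -1
    for i, t in enumerate(roc.thresholds):
        j = roc.sensitivity[i] + roc.specificity[i] - 1.0
        key = (j, roc.specificity[i], -t)
        if best is None or key > best:
            best = key
            best_idx = i
    cutoff = roc.thresholds[best_idx]
    return cutoff, best[0]


def classify_msi(score: float, cutoff: float, metric: str, sample_id: str = "sample") -> MsiCall:
    """MSI iff score >= cutoff (boundary counts as unstable, so a calibrated
    cutoff keeps its own sample positive)."""
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    return MsiCall(
        sample_id=sample_id,
        metric=metric,
        score=float(score),
        cutoff=float(cutoff),
        call="MSI" if score >= cutoff else "MSS",
    )


def pcr_call(
    marker_results: Sequence[tuple[str, str]], threshold: float = 0.30
) -> PcrPanelResult:
    """Marker-panel rule: MSI-H iff the unstable fraction is >= ``threshold``
    (default 0.30, i.e. at least two unstable markers in a five-marker panel);
    anything below — including MSI-L — is reported as MSS."""
    if not marker_results:
        raise ValueError("at least one marker result required")
    statuses = {s for _, s in marker_results}
    unknown = statuses - {"stable", "unstable"}
    if unknown:
        raise ValueError(f"unknown marker status values: {sorted(unknown)}")
    n_unstable = sum(1 for _, s in marker_results if s == "unstable")
    fraction = n_unstable / len(marker_results)
    return PcrPanelResult(
        markers=tuple(marker_results),
        threshold=threshold,
        n_unstable=n_unstable,
        call="MSI-H" if fraction >= threshold else "MSS",
    )


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return round(100.0 * num / den, 2)


def concordance_stats(table: ContingencyTable) -> ConcordanceResult:
    """Sensitivity, specificity and overall agreement of a 2x2 call table,
    as percentages rounded to 2 decimals (None where undefined)."""
    return ConcordanceResult(
        sensitivity=_pct(table.tp, table.tp + table.fn),
        specificity=_pct(table.tn, table.tn + table.fp),
        concordance=_pct(table.tp + table.tn, table.total),
    )
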