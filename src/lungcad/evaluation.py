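"""Detection and classification evaluation calculus.

Implements the confusion-count bookkeeping, the derived metric set
(sensitivity/TPR, precision, specificity, false-positive rate, F-score,
accuracy), threshold sweeps, size-stratified sensitivity reports, detection
-to-truth matching, and the per-patient average-false-positive burden.

Undefined metrics (zero denominators) are represented as ``None`` — never
silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from lungcad.io import NoduleAnnotation

DEFAULT_THRESHOLDS = tuple(round(0.1 * i, 1) for i in range(1, 10))
DEFAULT_SIZE_BINS_MM = (3.0, 5.0, 8.0, 10.0, 20.0, math.inf)


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding, as used for printed report values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsRow:
    """Derived metrics at one decision threshold; ``None`` means undefined."""

    threshold: Optional[float]
    counts: ConfusionCounts
    sensitivity: Optional[float]
    precision: Optional[float]
    specificity: Optional[float]
    false_positive_rate: Optional[float]
    f_score: Optional[float]
    accuracy: Optional[float]

    @property
    def tpr(self) -> Optional[float]:
        return self.sensitivity


@dataclass(frozen=True)
class SizeBinReport:
    label: str
    lo_mm: float
    hi_mm: float
    tp: int
    fn: int

    @property
    def sensitivity(self) -> Optional[float]:
        if self.tp + self.fn == 0:
            return None
        return self.tp / (self.tp + self.fn)

    @property
    def sensitivity_percent(self) -> Optional[float]:
        s = self.sensitivity
        return None if s is None else round_half_up(100.0 * s, 1)


def classify_at_threshold(probability: float, threshold: float) -> bool:
    """Positive iff the probability strictly exceeds the threshold."""
    if not (0.0 <= probability <= 1.0 and 0.0 <= threshold <= 1.0):
        raise ValueError("probability and threshold must lie in [0, 1]")
    return probability > threshold


def confusion_from_labels(
    predictions: Sequence[bool], truths: Sequence[bool]
) -> ConfusionCounts:
    """Tally the four confusion cells from aligned label sequences."""
    if len(predictions) != len(truths):
        raise ValueError(f"length mismatch: {len(predictions)} predictions, {len(truths)} truths")
    pred = np.asarray(predictions, dtype=bool)
    true = np.asarray(truths, dtype=bool)
    return ConfusionCounts(
        tp=int((pred & true).sum()),
        fp=int((pred & ~true).sum()),
        tn=int((~pred & ~true).sum()),
        fn=int((~pred & true).sum()),
    )


def compute_metrics(counts: ConfusionCounts, threshold: Optional[float] = None) -> MetricsRow:
    """Derive the full metric row from confusion counts.

    sensitivity/TPR = TP/(TP+FN); precision = TP/(TP+FP);
    specificity = TN/(TN+FP); FPR = FP/(TN+FP);
    F = 2*precision*TPR/(precision+TPR); accuracy = (TP+TN)/total.
    A zero denominator makes the metric undefined (``None``); F is undefined
    when either input is, and 0 when both are defined and zero.
    """

    def ratio(num: int, den: int) -> Optional[float]:
        return None if den == 0 else num / den

    sens = ratio(counts.tp, counts.tp + counts.fn)
    prec = ratio(counts.tp, counts.tp + counts.fp)
    spec = ratio(counts.tn, counts.tn + counts.fp)
    fpr = ratio(counts.fp, counts.tn + counts.fp)
    acc = ratio(counts.tp + counts.tn, counts.total)
    if sens is None or prec is None:
        f: Optional[float] = None
    elif sens == 0.0 and prec == 0.0:
        f = 0.0
    else:
        f = 2.0 * prec * sens / (prec + sens)
    return MetricsRow(
        threshold=threshold,
        counts=counts,
        sensitivity=sens,
        precision=prec,
        specificity=spec,
        false_positive_rate=fpr,
        f_score=f,
        accuracy=acc,
    )


def average_false_positive(total_fp: int, n_patients: int) -> float:
    """Per-patient false-positive burden: FP / number of patients."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    return total_fp / n_patients


def merge_detections_3d(
    detections: Sequence[tuple[float, float, float]],
    scores: Sequence[float],
    spacing: tuple[float, float, float],
    merge_radius_mm: float = 5.0,
) -> list[int]:
    """Greedy score-ordered non-maximum suppression of 3-D detections.

    Candidate ROIs are cut per slice, so one nodule (or one vessel) yields a
    vertical chain of near-coincident detections; this collapses each chain
    to its best-scoring member. Returns the kept indices in input order.
    """
    if len(detections) != len(scores):
        raise ValueError("detections and scores must align")
    dz, dy, dx = spacing
    order = sorted(range(len(detections)), key=lambda i: (-scores[i], detections[i]))
    kept: list[int] = []
    for i in order:
        di = detections[i]
        absorbed = False
        for j in kept:
            dj = detections[j]
            dist = math.sqrt(
                ((di[0] - dj[0]) * dz) ** 2
                + ((di[1] - dj[1]) * dy) ** 2
                + ((di[2] - dj[2]) * dx) ** 2
            )
            if dist <= merge_radius_mm:
                absorbed = True
                break
        if not absorbed:
            kept.append(i)
    return sorted(kept)


def match_detections(
    detections: Sequence[tuple[float, float, float]],
    annotations: Sequence[NoduleAnnotation],
    spacing: tuple[float, float, float],
    min_match_mm: float = 1.5,
) -> tuple[ConfusionCounts, dict[str, bool]]:
    """Greedy nearest-first matching of detections to ground-truth nodules.

    A detection may hit an annotation when their 3-D physical distance is at
    most ``max(diameter/2, min_match_mm)``. Each annotation absorbs at most
    one detection (extra detections of the same nodule count as FP).
    Returns detection-level counts (tn = 0; true negatives are not defined
    for detection) and a per-nodule hit map keyed by ``nodule_id``.
    """
    if spacing is None or len(spacing) != 3:
        raise ValueError("spacing (dz, dy, dx) is required for physical matching")
    dz, dy, dx = spacing
    pairs = []
    for di, det in enumerate(detections):
        for ai, ann in enumerate(annotations):
            dist = math.sqrt(
                ((det[0] - ann.centroid[0]) * dz) ** 2
                + ((det[1] - ann.centroid[1]) * dy) ** 2
                + ((det[2] - ann.centroid[2]) * dx) ** 2
            )
            if dist <= max(ann.diameter_mm / 2.0, min_match_mm):
                pairs.append((dist, di, ai))
    pairs.sort()
    matched_det: set[int] = set()
    matched_ann: set[int] = set()
    for _, di, ai in pairs:
        if di in matched_det or ai in matched_ann:
            continue
        matched_det.add(di)
        matched_ann.add(ai)
    hit_map = {ann.nodule_id: i in matched_ann for i, ann in enumerate(annotations)}
    counts = ConfusionCounts(
        tp=len(matched_ann),
        fn=len(annotations) - len(matched_ann),
        fp=len(detections) - len(matched_det),
        tn=0,
    )
    return counts, hit_map


def threshold_sweep(
    scores: Sequence[float],
    truths: Sequence[bool],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[MetricsRow]:
    """One metric row per threshold over fixed sample scores."""
    rows = []
    for thr in thresholds:
        preds = [classify_at_threshold(s, thr) for s in scores]
        rows.append(compute_metrics(confusion_from_labels(preds, truths), threshold=thr))
    return rows


def size_stratified_report(
    hit_map: Mapping[str, bool],
    annotations: Sequence[NoduleAnnotation],
    bin_edges_mm: Sequence[float] = DEFAULT_SIZE_BINS_MM,
) -> list[SizeBinReport]:
    """Per-diameter-bin TP/FN tallies; bins are left-closed, right-open.

    Diameters below the lowest edge land in an explicit underflow bin
    rather than being dropped.
    """
    edges = list(bin_edges_mm)
    if sorted(edges) != edges or len(edges) < 2:
        raise ValueError("bin_edges_mm must be sorted with >= 2 edges")
    bins: list[list[float]] = [[-math.inf, edges[0]]] + [
        [edges[i], edges[i + 1]] for i in range(len(edges) - 1)
    ]
    tallies = [[0, 0] for _ in bins]
    for ann in annotations:
        hit = bool(hit_map.get(ann.nodule_id, False))
        for i, (lo, hi) in enumerate(bins):
            if lo <= ann.diameter_mm < hi:
                tallies[i][0 if hit else 1] += 1
                break
    reports = []
    for (lo, hi), (tp, fn) in zip(bins, tallies):
        if math.isinf(lo):
            if tp + fn == 0:
                continue  # underflow bin shown only when occupied
            label = f"<{edges[0]:g} mm"
        elif math.isinf(hi):
            label = f">{lo:g} mm"
        else:
            label = f"{lo:g}-{hi:g} mm"
        reports.append(SizeBinReport(label=label, lo_mm=lo, hi_mm=hi, tp=tp, fn=fn))
    return reports


def report_to_markdown(rows: Sequence[MetricsRow]) -> str:
    """Render a threshold sweep as a Markdown table."""

    def fmt(v: Optional[float], nd: int = 5) -> str:
        return "-" if v is None else f"{round_half_up(v, nd):g}"

    lines = [
        "| Threshold | TP | FN | FP | TN | TPR | Precision | F-score |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for row in rows:
        c = row.counts
        lines.append(
            f"| {row.threshold if row.threshold is not None else '-'} "
            f"| {c.tp} | {c.fn} | {c.fp} | {c.tn} "
            f"| {fmt(row.sensitivity)} | {fmt(row.precision)} | {fmt(row.f_score)} |"
        )
    return "\n".join(lines)


def size_report_to_markdown(reports: Sequence[SizeBinReport]) -> str:
    lines = [
        "| Nodule size | TP | FN | Sensitivity (%) |",
        "|---|---|---|---|",
    ]
    tp_total = fn_total = 0
    for rep in reports:
        tp_total += rep.tp
        fn_total += rep.fn
        pct = rep.sensitivity_percent
        lines.append(f"| {rep.label} | {rep.tp} | {rep.fn} | {'-' if pct is None else pct} |")
    total_pct = (
        round_half_up(100.0 * tp_total / (tp_total + fn_total), 1)
        if tp_total + fn_total else None
    )
    lines.append(f"| Total | {tp_total} | {fn_total} | {'-' if total_pct is None else total_pct} |")
    return "\n".join(lines)
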