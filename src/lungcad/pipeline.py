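"""End-to-end orchestration: segment -> detect -> encode -> score -> evaluate."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from lungcad import __version__
from lungcad.candidates import CandidateParams, CandidateROI, detect_candidates
from lungcad.encoding import (
    DEFAULT_FG_THRESHOLD,
    DEFAULT_WINDOW,
    compose_rgb,
    get_scorer,
)
from lungcad.evaluation import (
    DEFAULT_THRESHOLDS,
    ConfusionCounts,
    SizeBinReport,
    average_false_positive,
    classify_at_threshold,
    match_detections,
    merge_detections_3d,
    size_stratified_report,
)
from lungcad.io import CTVolume, NoduleAnnotation, load_ct_volume, parse_lidc_annotations
from lungcad.phantom import default_test_spec, generate_phantom
from lungcad.segmentation import SegmentationParams, segment_lungs

logger = logging.getLogger(__name__)

PHANTOM_PREFIX = "phantom:"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a run."""

    source: str = "phantom:easy"  # "phantom:<difficulty>" or a volume path
    annotations_path: Optional[str] = None
    noise_sd: float = 20.0  # phantom sources only
    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    candidates: CandidateParams = field(default_factory=CandidateParams)
    window: tuple[float, float] = DEFAULT_WINDOW
    fg_byte_threshold: int = DEFAULT_FG_THRESHOLD
    scorer: str = "baseline"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    log_level: str = "INFO"

    def validate(self) -> None:
        get_scorer(self.scorer)
        if not all(0.0 <= t <= 1.0 for t in self.thresholds):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.source.startswith(PHANTOM_PREFIX):
            difficulty = self.source[len(PHANTOM_PREFIX):]
            default_test_spec(difficulty)  # raises on unknown label

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "segmentation" in raw and isinstance(raw["segmentation"], dict):
            raw["segmentation"] = SegmentationParams(**raw["segmentation"])
        if "candidates" in raw and isinstance(raw["candidates"], dict):
            raw["candidates"] = CandidateParams(**raw["candidates"])
        for key in ("window", "thresholds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ThresholdDetectionRow:
    """Detection-level outcome at one score threshold."""

    threshold: float
    counts: ConfusionCounts
    sensitivity: Optional[float]
    fp_per_patient: float


@dataclass
class DetectionReport:
    """Deterministic record of one pipeline run."""

    config: PipelineConfig
    patient_id: str
    n_candidates: int
    candidate_records: list[dict]
    detection_rows: list[ThresholdDetectionRow]
    size_report: list[SizeBinReport]
    best_threshold: Optional[float]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "patient_id": self.patient_id,
            "n_candidates": self.n_candidates,
            "candidates": self.candidate_records,
            "detection_rows": [
                {
                    "threshold": row.threshold,
                    "tp": row.counts.tp,
                    "fn": row.counts.fn,
                    "fp": row.counts.fp,
                    "sensitivity": row.sensitivity,
                    "fp_per_patient": row.fp_per_patient,
                }
                for row in self.detection_rows
            ],
            "size_report": [
                {
                    "label": rep.label,
                    "tp": rep.tp,
                    "fn": rep.fn,
                    "sensitivity_percent": rep.sensitivity_percent,
                }
                for rep in self.size_report
            ],
            "best_threshold": self.best_threshold,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def resolve_input(
    config: PipelineConfig,
) -> tuple[CTVolume, list[NoduleAnnotation], Optional[np.ndarray]]:
    """Materialise the input volume, ground truth when available."""
    if config.source.startswith(PHANTOM_PREFIX):
        difficulty = config.source[len(PHANTOM_PREFIX):]
        spec = default_test_spec(difficulty, seed=config.seed, noise_sd=config.noise_sd)
        return generate_phantom(spec)
    volume = load_ct_volume(config.source)
    annotations: list[NoduleAnnotation] = []
    if config.annotations_path:
        annotations = parse_lidc_annotations(Path(config.annotations_path))
    return volume, annotations, None


def run_pipeline(config: PipelineConfig) -> DetectionReport:
    """Execute every stage; evaluation sections require ground truth."""
    config.validate()
    logging.getLogger("lungcad").setLevel(config.log_level)

    stage = "input"
    try:
        volume, annotations, _ = resolve_input(config)
        stage = "segmentation"
        mask, parenchyma = segment_lungs(volume, config.segmentation)
        stage = "candidate-detection"
        candidates = detect_candidates(parenchyma, mask, config.candidates)
        stage = "scoring"
        scorer = get_scorer(config.scorer)
        scored: list[tuple[CandidateROI, float]] = []
        for cand in candidates:
            composite = compose_rgb(cand, config.window)
            scored.append((cand, float(scorer(composite))))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    candidate_records = [
        {"center": list(cand.center), "score": score} for cand, score in scored
    ]

    detection_rows: list[ThresholdDetectionRow] = []
    size_report: list[SizeBinReport] = []
    best_threshold: Optional[float] = None
    if annotations:
        best_hit_map = None
        best_key = None
        for thr in config.thresholds:
            positives = [
                (cand.center, score)
                for cand, score in scored
                if classify_at_threshold(score, thr)
            ]
            centers = [c for c, _ in positives]
            # one nodule yields a vertical chain of per-slice candidates;
            # collapse each chain to its best-scoring member before matching
            keep = merge_detections_3d(
                centers, [s for _, s in positives], volume.spacing
            )
            centers = [centers[i] for i in keep]
            counts, hit_map = match_detections(centers, annotations, volume.spacing)
            sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
            row = ThresholdDetectionRow(
                threshold=thr,
                counts=counts,
                sensitivity=sens,
                fp_per_patient=average_false_positive(counts.fp, 1),
            )
            detection_rows.append(row)
            key = (sens if sens is not None else -1.0, -counts.fp)
            if best_key is None or key > best_key:
                best_key, best_threshold, best_hit_map = key, thr, hit_map
        if best_hit_map is not None:
            size_report = size_stratified_report(best_hit_map, annotations)

    return DetectionReport(
        config=config,
        patient_id=volume.patient_id,
        n_candidates=len(scored),
        candidate_records=candidate_records,
        detection_rows=detection_rows,
        size_report=size_report,
        best_threshold=best_threshold,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "scorer": config.scorer,
        },
    )
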