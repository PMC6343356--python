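"""Candidate nodule localisation and ROI extraction.

Within the parenchyma, per-slice thresholding isolates dense structures;
small specks and elongated (vessel-like) components are discarded; each
surviving component's centroid seeds a 64x64 tri-slice ROI stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from lungcad.io import HU_MIN, CTVolume

ROI_SIZE = 64  # fixed patch side length


@dataclass(frozen=True)
class SliceComponent:
    """A connected component on one slice with its shape moments."""

    slice_index: int
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    major_axis: float
    minor_axis: float
    pixels: tuple[tuple[int, int], ...] = field(repr=False, default=())

    @property
    def axis_ratio(self) -> float:
        if self.minor_axis <= 0:
            return float("inf")
        return self.major_axis / self.minor_axis


@dataclass(frozen=True)
class CandidateROI:
    """A 3 x 64 x 64 HU patch stack centred on a candidate."""

    patient_id: str
    center: tuple[int, int, int]  # (slice, row, col)
    patches: np.ndarray
    provenance: tuple[str, ...] = ()
    truth_label: Optional[bool] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "patches", np.asarray(self.patches))
        if self.patches.shape != (3, ROI_SIZE, ROI_SIZE):
            raise ValueError(
                f"patch stack must be (3, {ROI_SIZE}, {ROI_SIZE}), got {self.patches.shape}"
            )


@dataclass(frozen=True)
class CandidateParams:
    candidate_hu_min: int = -750
    min_area_px: int = 9
    max_axis_ratio: float = 3.0
    roi_size: int = ROI_SIZE

    def __post_init__(self) -> None:
        if self.roi_size != ROI_SIZE:
            raise ValueError(f"roi_size is fixed at {ROI_SIZE}")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.max_axis_ratio < 1:
            raise ValueError("max_axis_ratio must be >= 1")


def min_area_px_from_mm2(area_mm2: float, spacing: tuple[float, float, float]) -> int:
    """Convert an in-plane area threshold from mm^2 to whole pixels."""
    return max(1, int(round(area_mm2 / (spacing[1] * spacing[2]))))


def label_candidate_components(
    parenchyma: CTVolume,
    mask: np.ndarray,
    candidate_hu_min: int = -750,
) -> list[SliceComponent]:
    """Label dense in-mask pixels (HU >= threshold) slice by slice."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != parenchyma.shape:
        raise ValueError("mask/volume shape mismatch")
    dense = mask & (parenchyma.voxels >= candidate_hu_min)
    structure = ndimage.generate_binary_structure(2, 2)  # 8-connected
    components: list[SliceComponent] = []
    for z in range(dense.shape[0]):
        labels, n = ndimage.label(dense[z], structure=structure)
        if n == 0:
            continue
        for prop in regionprops(labels):
            if prop.area == 1:
                major = minor = 1.0  # single-pixel convention
            else:
                major, minor = prop.axis_major_length, prop.axis_minor_length
            pixels = tuple((int(r), int(c)) for r, c in prop.coords)
            components.append(
                SliceComponent(
                    slice_index=z,
                    area_px=int(prop.area),
                    centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                    major_axis=float(major),
                    minor_axis=float(minor),
                    pixels=pixels,
                )
            )
    return components


def filter_small_components(
    components: Sequence[SliceComponent], min_area_px: int = 9
) -> list[SliceComponent]:
    """Drop components below the (inclusive) area floor."""
    return [c for c in components if c.area_px >= min_area_px]


def filter_elongated_components(
    components: Sequence[SliceComponent], max_axis_ratio: float = 3.0
) -> list[SliceComponent]:
    """Drop stripe-like components (moment-ellipse axis ratio too high).

    Degenerate (collinear) components have ratio +inf and are removed.
    """
    return [c for c in components if c.axis_ratio <= max_axis_ratio]


def extract_roi_stack(
    volume: CTVolume,
    center: tuple[int, int, int],
    roi_size: int = ROI_SIZE,
    provenance: tuple[str, ...] = (),
) -> CandidateROI:
    """Crop the tri-slice ``roi_size`` window centred at ``center``.

    Out-of-plane overhang is padded with background (-1024 HU); a missing
    z-neighbour at the first/last slice is replicated from the centre slice.
    The centre voxel lands at patch index (roi_size // 2, roi_size // 2).
    """
    nz, ny, nx = volume.shape
    if nz < 3:
        raise ValueError("volume must have >= 3 slices")
    z, r, c = (int(v) for v in center)
    if not (0 <= z < nz and 0 <= r < ny and 0 <= c < nx):
        raise ValueError(f"center {center} outside volume {volume.shape}")
    half = roi_size // 2

    def crop(slice_idx: int) -> np.ndarray:
        patch = np.full((roi_size, roi_size), HU_MIN, dtype=volume.voxels.dtype)
        r0, r1 = r - half, r + half
        c0, c1 = c - half, c + half
        sr0, sr1 = max(r0, 0), min(r1, ny)
        sc0, sc1 = max(c0, 0), min(c1, nx)
        if sr0 < sr1 and sc0 < sc1:
            patch[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = volume.voxels[slice_idx, sr0:sr1, sc0:sc1]
        return patch

    zs = [z - 1 if z > 0 else z, z, z + 1 if z < nz - 1 else z]
    patches = np.stack([crop(zi) for zi in zs])
    return CandidateROI(
        patient_id=volume.patient_id,
        center=(z, r, c),
        patches=patches,
        provenance=provenance,
    )


def detect_candidates(
    volume: CTVolume,
    mask: np.ndarray,
    params: CandidateParams = CandidateParams(),
) -> list[CandidateROI]:
    """Full candidate chain: label, filter, then cut ROI stacks.

    Candidates are ordered by (slice, row, col). A component centroid that
    rounds to a pixel outside the component/mask is snapped to the nearest
    component pixel so every candidate centre stays inside the lung.
    """
    mask = np.asarray(mask, dtype=bool)
    components = label_candidate_components(volume, mask, params.candidate_hu_min)
    components = filter_small_components(components, params.min_area_px)
    components = filter_elongated_components(components, params.max_axis_ratio)

    candidates = []
    for comp in components:
        r = int(round(comp.centroid[0]))
        c = int(round(comp.centroid[1]))
        if not mask[comp.slice_index, r, c]:
            pix = np.asarray(comp.pixels)
            d2 = (pix[:, 0] - comp.centroid[0]) ** 2 + (pix[:, 1] - comp.centroid[1]) ** 2
            r, c = (int(v) for v in pix[int(np.argmin(d2))])
        candidates.append(
            extract_roi_stack(
                volume,
                (comp.slice_index, r, c),
                params.roi_size,
                provenance=("threshold", "min_area", "axis_ratio"),
            )
        )
    candidates.sort(key=lambda roi: roi.center)
    return candidates


def write_candidates_csv(candidates: Sequence[CandidateROI], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "slice", "row", "col", "provenance"])
        for cand in candidates:
            writer.writerow([cand.patient_id, *cand.center, "|".join(cand.provenance)])
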