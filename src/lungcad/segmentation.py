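"""Pulmonary parenchyma extraction.

The stage sequence is: threshold binarization (air-like voxels), removal of
border-connected external air and retention of the dominant interior
components, per-slice hole filling (airways/vessel lumina), contour
corrosion (erosion) to detach pleural adhesions followed by contour mending
(morphological closing), then masking the volume so only parenchyma
survives. All morphology is per-slice 2-D; structuring elements are disks
whose radii are given in millimetres and converted via in-plane spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from lungcad.io import HU_MIN, CTVolume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the parenchyma extraction pipeline."""

    hu_threshold: int = -320
    erosion_radius_mm: float = 1.5
    mending_radius_mm: float = 3.0
    border_margin_px: int = 2
    connectivity: int = 8  # per-slice pixel connectivity: 4 or 8

    def __post_init__(self) -> None:
        if self.erosion_radius_mm < 0 or self.mending_radius_mm < 0:
            raise ValueError("radii must be >= 0")
        if not -1024 <= self.hu_threshold <= 0:
            raise ValueError(f"hu_threshold must lie in [-1024, 0], got {self.hu_threshold}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _label_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def _disk_px(radius_mm: float, spacing: tuple[float, float, float]) -> int:
    in_plane = (spacing[1] + spacing[2]) / 2.0
    return int(round(radius_mm / in_plane))


def binarize(volume: CTVolume, hu_threshold: int = -320) -> np.ndarray:
    """Mark air-like voxels: HU strictly below ``hu_threshold``."""
    return volume.voxels < hu_threshold


def extract_lung_mask(
    air_mask: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Keep the dominant interior air components of each slice.

    Components touching the slice border (within ``border_margin_px``) are
    external air and removed. Of the interior components, the largest is
    kept along with every component at least 25 % of its area, so both
    lungs survive whether or not they are connected.
    """
    air_mask = np.asarray(air_mask, dtype=bool)
    out = np.zeros_like(air_mask)
    structure = _label_structure(params.connectivity)
    nz = air_mask.shape[0]
    for z in range(nz):
        labels, n = ndimage.label(air_mask[z], structure=structure)
        if n == 0:
            continue
        m = params.border_margin_px
        border = np.zeros_like(labels, dtype=bool)
        width = max(m + 1, 1)
        border[:width, :] = border[-width:, :] = True
        border[:, :width] = border[:, -width:] = True
        border_labels = set(np.unique(labels[border])) - {0}
        areas = ndimage.sum_labels(air_mask[z], labels, index=np.arange(1, n + 1))
        interior = [
            (areas[i - 1], i) for i in range(1, n + 1) if i not in border_labels
        ]
        if not interior:
            if nz // 4 <= z <= 3 * nz // 4:
                logger.warning("slice %d: no interior air component; empty lung mask", z)
            continue
        largest = max(a for a, _ in interior)
        keep = [i for a, i in interior if a >= 0.25 * largest]
        out[z] = np.isin(labels, keep)
    return out


def fill_airways(mask: np.ndarray) -> np.ndarray:
    """Per-slice hole filling: interior false regions become true."""
    mask = np.asarray(mask, dtype=bool)
    out = np.empty_like(mask)
    for z in range(mask.shape[0]):
        out[z] = ndimage.binary_fill_holes(mask[z])
    return out


def refine_contour(
    mask: np.ndarray,
    erosion_radius_mm: float,
    mending_radius_mm: float,
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Corrode the contour, then mend and re-expand it.

    Erosion detaches thin pleural adhesions; dilating back by the same disk
    (together an opening) restores the contour without the adhesions; the
    final closing with the mending disk re-includes juxtapleural
    indentations up to that radius. The result is a superset of the eroded
    mask (dilation and closing are both extensive).
    """
    mask = np.asarray(mask, dtype=bool)
    er_px = _disk_px(erosion_radius_mm, spacing)
    mend_px = _disk_px(mending_radius_mm, spacing)
    out = np.empty_like(mask)
    er_selem = disk(er_px) if er_px > 0 else None
    mend_selem = disk(mend_px) if mend_px > 0 else None
    for z in range(mask.shape[0]):
        sl = mask[z]
        had_content = sl.any()
        if er_selem is not None:
            sl = ndimage.binary_erosion(sl, structure=er_selem)
            if had_content and not sl.any():
                logger.warning("slice %d eroded to empty at radius %.1f mm", z, erosion_radius_mm)
            sl = ndimage.binary_dilation(sl, structure=er_selem)
        if mend_selem is not None and sl.any():
            # close each component separately so mending never bridges the
            # two lungs across the mediastinal gap
            labels, n = ndimage.label(sl, structure=_label_structure(8))
            closed = np.zeros_like(sl)
            for i in range(1, n + 1):
                closed |= ndimage.binary_closing(labels == i, structure=mend_selem)
            sl = closed
        out[z] = sl
    return out


def apply_parenchyma_mask(
    volume: CTVolume, mask: np.ndarray, background_hu: int = HU_MIN
) -> CTVolume:
    """Zero out (to ``background_hu``) everything outside the lung mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    voxels = np.where(mask, volume.voxels, np.int16(background_hu))
    return volume.with_voxels(voxels)


def segment_lungs(
    volume: CTVolume,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[np.ndarray, CTVolume]:
    """Run the full parenchyma extraction; returns (mask, parenchyma volume)."""
    air = binarize(volume, params.hu_threshold)
    lungs = extract_lung_mask(air, params)
    if not lungs.any():
        logger.warning("no lung-like region found in volume %r", volume.patient_id)
    filled = fill_airways(lungs)
    refined = refine_contour(
        filled, params.erosion_radius_mm, params.mending_radius_mm, volume.spacing
    )
    parenchyma = apply_parenchyma_mask(volume, refined)
    return refined, parenchyma
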