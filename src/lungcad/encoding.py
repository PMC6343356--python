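"""Tri-slice RGB pseudo-color encoding and sphere-likeness scoring.

Three consecutive axial patches are windowed to bytes and assigned to the
red (upper slice), green (centre) and blue (lower) channels. A spherical
structure produces nearly coincident channel foregrounds, while an oblique
tubular vessel shifts between channels; the coincidence score quantifies
that, and the baseline scorer combines it with the compactness of the
three-channel intersection to yield a [0, 1] sphere-likeness probability.
Trained model scorers can be registered under the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label, perimeter as sk_perimeter

from lungcad.candidates import ROI_SIZE, CandidateROI

DEFAULT_WINDOW = (-600.0, 1500.0)  # (center HU, width HU) lung window
DEFAULT_FG_THRESHOLD = 96  # byte threshold: solid tissue yes, aerated lung no


@dataclass(frozen=True)
class RGBComposite:
    """A 64 x 64 x 3 byte image plus its provenance."""

    channels: np.ndarray  # (64, 64, 3) uint8
    channel_assignment: tuple[str, str, str] = ("upper", "center", "lower")
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        channels = np.asarray(self.channels)
        if channels.shape != (ROI_SIZE, ROI_SIZE, 3):
            raise ValueError(f"composite must be ({ROI_SIZE}, {ROI_SIZE}, 3), got {channels.shape}")
        if channels.min() < 0 or channels.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        object.__setattr__(self, "channels", channels.astype(np.uint8))


def window_to_bytes(
    patch: np.ndarray, center_hu: float = DEFAULT_WINDOW[0], width_hu: float = DEFAULT_WINDOW[1]
) -> np.ndarray:
    """Linearly map the HU window onto [0, 255] with clamping.

    The mapping sends ``center - width/2`` to 0 and ``center + width/2`` to
    255; values outside the window clamp. Rounding is half-up, so the window
    centre maps to 128.
    """
    if width_hu <= 0:
        raise ValueError("width_hu must be > 0")
    lo = center_hu - width_hu / 2.0
    scaled = (np.asarray(patch, dtype=np.float64) - lo) / width_hu * 255.0
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def compose_rgb(
    roi: CandidateROI, window: tuple[float, float] = DEFAULT_WINDOW
) -> RGBComposite:
    """Superimpose the three windowed patches on the R, G and B channels."""
    center, width = window
    channels = np.stack(
        [window_to_bytes(roi.patches[i], center, width) for i in range(3)], axis=-1
    )
    return RGBComposite(channels=channels, window=(float(center), float(width)))


def _foregrounds(composite: RGBComposite, fg_byte_threshold: int):
    ch = composite.channels
    return [ch[:, :, i] > fg_byte_threshold for i in range(3)]


def coincidence_score(
    composite: RGBComposite, fg_byte_threshold: int = DEFAULT_FG_THRESHOLD
) -> float:
    """Jaccard overlap of the three channel foregrounds.

    ``|R ∩ G ∩ B| / |R ∪ G ∪ B|``; an empty union scores 0. Symmetric under
    any channel permutation.
    """
    r, g, b = _foregrounds(composite, fg_byte_threshold)
    union = int((r | g | b).sum())
    if union == 0:
        return 0.0
    inter = int((r & g & b).sum())
    return inter / union


def _compactness(region: np.ndarray) -> float:
    """Isoperimetric compactness 4*pi*area/perimeter^2 of the largest blob."""
    area = int(region.sum())
    if area == 0:
        return 0.0
    perim = sk_perimeter(region)
    if perim <= 0:  # single pixel / degenerate: treat as maximally compact
        return 1.0
    return float(min(4.0 * np.pi * area / perim ** 2, 1.0))


def baseline_score(
    composite: RGBComposite,
    fg_byte_threshold: int = DEFAULT_FG_THRESHOLD,
) -> float:
    """Deterministic sphere-likeness probability in [0, 1].

    Channel coincidence times compactness of the R∩G∩B core, both
    restricted to the foreground-union connected component at the patch
    centre — the candidate's own structure — so an unrelated bright object
    elsewhere in the window cannot inflate (or dilute) the score. Spheres
    keep a round coincident core across the three slices; tilted vessels
    lose overlap and leave a thin, low-compactness sliver. Vertical vessels
    are the documented blind spot: their sections coincide like a sphere's.
    """
    r, g, b = _foregrounds(composite, fg_byte_threshold)
    union = r | g | b
    if not union.any():
        return 0.0
    # despeckle: a cross-shaped opening removes one-pixel filaments (e.g.
    # the partial-volume rim along the lung contour) that would otherwise
    # bridge the candidate blob to unrelated foreground
    cross = ndimage.generate_binary_structure(2, 1)
    opened = ndimage.binary_opening(union, structure=cross)
    if opened.any():
        union = opened
    labels = sk_label(union, connectivity=2)
    cy = cx = ROI_SIZE // 2
    lab = labels[cy, cx]
    if lab == 0:  # centre pixel dimmed (e.g. noise): take the nearest blob
        ys, xs = np.nonzero(union)
        idx = int(np.argmin((ys - cy) ** 2 + (xs - cx) ** 2))
        lab = labels[ys[idx], xs[idx]]
    blob = labels == lab
    inter = r & g & b & blob
    if not inter.any():
        return 0.0
    overlap = float(inter.sum()) / float(blob.sum())
    return overlap * _compactness(inter)


# ---------------------------------------------------------------------------
# Scorer registry (the seam where trained models would attach)
# ---------------------------------------------------------------------------

ScorerFn = Callable[[RGBComposite], float]

_SCORERS: dict[str, ScorerFn] = {}


def register_scorer(name: str, fn: ScorerFn) -> None:
    _SCORERS[name] = fn


def get_scorer(name: str) -> ScorerFn:
    try:
        return _SCORERS[name]
    except KeyError:
        raise KeyError(f"unknown scorer {name!r}; registered: {sorted(_SCORERS)}") from None


def available_scorers() -> list[str]:
    return sorted(_SCORERS)


register_scorer("baseline", baseline_score)
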