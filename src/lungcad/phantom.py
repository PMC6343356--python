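"""Synthetic CT phantoms with known ground truth.

A phantom is an air background, a soft-tissue body ellipse per slice, two
low-attenuation lung ellipsoids, straight cylindrical vessels at controlled
tilt angles, and spherical nodules (solid, GGO-like faint, or juxtapleural).
Every structure is painted with a one-voxel linear partial-volume falloff;
i.i.d. Gaussian HU noise is added last. Ground truth (annotations + lung
mask) is returned alongside the volume, which makes each downstream stage
testable without external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from lungcad.io import (
    HU_MAX,
    HU_MIN,
    Characteristics,
    CTVolume,
    NoduleAnnotation,
)

NODULE_KINDS = ("solid", "ggo", "juxtapleural")


@dataclass(frozen=True)
class VesselSpec:
    """A straight cylindrical vessel.

    ``tilt_deg`` is the angle between the vessel axis and the axial (z)
    normal: 0 means perpendicular to the slice plane, 90 means in-plane.
    ``anchor`` is a voxel coordinate the axis passes through.
    """

    radius_mm: float
    tilt_deg: float
    azimuth_deg: float
    anchor: tuple[float, float, float]
    hu: int = 40

    def direction_mm(self) -> np.ndarray:
        """Unit axis direction in physical (z, y, x) space."""
        t = math.radians(self.tilt_deg)
        a = math.radians(self.azimuth_deg)
        return np.array([math.cos(t), math.sin(t) * math.cos(a), math.sin(t) * math.sin(a)])


@dataclass(frozen=True)
class NoduleSpec:
    centroid: tuple[float, float, float]  # voxel (z, y, x)
    diameter_mm: float
    hu: int
    kind: str = "solid"

    def __post_init__(self) -> None:
        if self.kind not in NODULE_KINDS:
            raise ValueError(f"unknown nodule kind {self.kind!r}; expected one of {NODULE_KINDS}")
        if not self.diameter_mm > 0:
            raise ValueError("diameter_mm must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of a synthetic CT phantom."""

    shape: tuple[int, int, int] = (40, 128, 128)
    spacing: tuple[float, float, float] = (2.5, 0.7, 0.7)
    body_hu: int = 40
    lung_hu: int = -850
    air_hu: int = -1000
    noise_sd: float = 0.0
    vessels: tuple[VesselSpec, ...] = ()
    nodules: tuple[NoduleSpec, ...] = ()
    seed: int = 0
    # lung ellipsoids: ((center_z, center_y, center_x), (semi_z, semi_y, semi_x))
    # in voxel units; None -> derived from shape
    lungs: Optional[tuple[tuple, tuple]] = None

    def lung_geometry(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Centers and semi-axes (voxel units) of the two lung ellipsoids."""
        nz, ny, nx = self.shape
        if self.lungs is not None:
            centers, semis = self.lungs
            return [(np.asarray(c, float), np.asarray(s, float)) for c, s in zip(centers, semis)]
        cz, cy = nz / 2.0, ny / 2.0
        semi = np.array([0.42 * nz, 0.33 * ny, 0.18 * nx])
        left = (np.array([cz, cy, 0.30 * nx]), semi)
        right = (np.array([cz, cy, 0.70 * nx]), semi)
        return [left, right]

    def validate(self) -> None:
        if any(n < 3 for n in self.shape[:1]) or len(self.shape) != 3:
            raise ValueError(f"shape must be 3-D with >= 3 slices, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lungs = self.lung_geometry()
        for nod in self.nodules:
            if not _inside_any_ellipsoid(nod.centroid, lungs):
                raise ValueError(f"nodule centroid {nod.centroid} lies outside the lung ellipsoids")
            if nod.kind == "ggo" and not (self.lung_hu < nod.hu < self.body_hu):
                raise ValueError(
                    f"GGO nodule HU {nod.hu} must lie strictly between lung "
                    f"({self.lung_hu}) and body ({self.body_hu})"
                )
        # unambiguous ground truth: nodules must not overlap
        dz, dy, dx = self.spacing
        for i, a in enumerate(self.nodules):
            for b in self.nodules[i + 1:]:
                dist = math.sqrt(
                    ((a.centroid[0] - b.centroid[0]) * dz) ** 2
                    + ((a.centroid[1] - b.centroid[1]) * dy) ** 2
                    + ((a.centroid[2] - b.centroid[2]) * dx) ** 2
                )
                if dist < (a.diameter_mm + b.diameter_mm) / 2.0:
                    raise ValueError(
                        f"nodules at {a.centroid} and {b.centroid} overlap "
                        f"(distance {dist:.1f} mm)"
                    )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        raw = json.loads(text)
        raw["vessels"] = tuple(
            VesselSpec(
                radius_mm=v["radius_mm"], tilt_deg=v["tilt_deg"], azimuth_deg=v["azimuth_deg"],
                anchor=tuple(v["anchor"]), hu=v["hu"],
            )
            for v in raw.get("vessels", ())
        )
        raw["nodules"] = tuple(
            NoduleSpec(
                centroid=tuple(n["centroid"]), diameter_mm=n["diameter_mm"],
                hu=n["hu"], kind=n["kind"],
            )
            for n in raw.get("nodules", ())
        )
        for key in ("shape", "spacing"):
            raw[key] = tuple(raw[key])
        if raw.get("lungs") is not None:
            centers, semis = raw["lungs"]
            raw["lungs"] = (tuple(tuple(c) for c in centers), tuple(tuple(s) for s in semis))
        return cls(**raw)


def _inside_any_ellipsoid(point, lungs) -> bool:
    p = np.asarray(point, float)
    for center, semi in lungs:
        if (((p - center) / semi) ** 2).sum() <= 1.0:
            return True
    return False


# ---------------------------------------------------------------------------
# Painting helpers — all operate on a float HU canvas with a one-voxel
# (in-plane) linear partial-volume falloff: alpha 1 at dist <= r - e/2,
# 0 at dist >= r + e/2, linear between, with e = in-plane spacing.
# ---------------------------------------------------------------------------

def _phys_grids(shape, spacing):
    nz, ny, nx = shape
    dz, dy, dx = spacing
    z = np.arange(nz)[:, None, None] * dz
    y = np.arange(ny)[None, :, None] * dy
    x = np.arange(nx)[None, None, :] * dx
    return z, y, x


def _alpha_from_distance(dist_mm: np.ndarray, radius_mm: float, edge_mm: float) -> np.ndarray:
    return np.clip((radius_mm - dist_mm) / edge_mm + 0.5, 0.0, 1.0)


def _paint(canvas: np.ndarray, alpha: np.ndarray, hu: float, limit: Optional[np.ndarray] = None) -> None:
    if limit is not None:
        alpha = alpha * limit
    canvas += alpha * (hu - canvas)


def _sphere_alpha(shape, spacing, centroid, radius_mm):
    """Partial-volume membership of a sphere, restricted to a bounding box."""
    dz, dy, dx = spacing
    edge = min(dy, dx)
    margin = radius_mm + edge
    z0 = max(int((centroid[0] * dz - margin) / dz) - 1, 0)
    z1 = min(int((centroid[0] * dz + margin) / dz) + 2, shape[0])
    y0 = max(int((centroid[1] * dy - margin) / dy) - 1, 0)
    y1 = min(int((centroid[1] * dy + margin) / dy) + 2, shape[1])
    x0 = max(int((centroid[2] * dx - margin) / dx) - 1, 0)
    x1 = min(int((centroid[2] * dx + margin) / dx) + 2, shape[2])
    z = (np.arange(z0, z1)[:, None, None] - centroid[0]) * dz
    y = (np.arange(y0, y1)[None, :, None] - centroid[1]) * dy
    x = (np.arange(x0, x1)[None, None, :] - centroid[2]) * dx
    dist = np.sqrt(z ** 2 + y ** 2 + x ** 2)
    alpha = _alpha_from_distance(dist, radius_mm, edge)
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1)), alpha


def _cylinder_alpha(shape, spacing, vessel: VesselSpec):
    """Partial-volume membership of an infinite straight cylinder."""
    dz, dy, dx = spacing
    z, y, x = _phys_grids(shape, spacing)
    anchor = np.asarray(vessel.anchor, float) * np.asarray(spacing)
    d = vessel.direction_mm()
    rz, ry, rx = z - anchor[0], y - anchor[1], x - anchor[2]
    proj = rz * d[0] + ry * d[1] + rx * d[2]
    perp2 = (rz - proj * d[0]) ** 2 + (ry - proj * d[1]) ** 2 + (rx - proj * d[2]) ** 2
    dist = np.sqrt(perp2)
    return _alpha_from_distance(dist, vessel.radius_mm, min(dy, dx))


def _lung_masks(spec: PhantomSpec):
    """Boolean lung mask (voxel-center membership) and soft alpha for painting."""
    z, y, x = _phys_grids(spec.shape, spec.spacing)
    dz, dy, dx = spec.spacing
    hard = np.zeros(spec.shape, dtype=bool)
    soft = np.zeros(spec.shape, dtype=float)
    for center, semi in spec.lung_geometry():
        c_mm = center * np.asarray(spec.spacing)
        s_mm = semi * np.asarray(spec.spacing)
        q = np.sqrt(
            ((z - c_mm[0]) / s_mm[0]) ** 2
            + ((y - c_mm[1]) / s_mm[1]) ** 2
            + ((x - c_mm[2]) / s_mm[2]) ** 2
        )
        hard |= q <= 1.0
        # approximate mm distance to the ellipsoid surface for the falloff
        scale = float(np.min(s_mm))
        soft = np.maximum(soft, np.clip((1.0 - q) * scale / min(dy, dx) + 0.5, 0.0, 1.0))
    return hard, soft


def _body_alpha(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    y = np.arange(ny)[:, None] * dy
    x = np.arange(nx)[None, :] * dx
    cy, cx = (ny / 2.0) * dy, (nx / 2.0) * dx
    sy, sx = 0.42 * ny * dy, 0.45 * nx * dx
    q = np.sqrt(((y - cy) / sy) ** 2 + ((x - cx) / sx) ** 2)
    alpha2d = np.clip((1.0 - q) * min(sy, sx) / min(dy, dx) + 0.5, 0.0, 1.0)
    return np.broadcast_to(alpha2d, (nz, ny, nx)).copy()


def _synth_characteristics(nod: NoduleSpec) -> Characteristics:
    ggo = nod.kind == "ggo"
    return Characteristics(
        subtlety=2 if ggo else 4,
        internalStructure=1,
        calcification=6,
        sphericity=4,
        margin=3 if ggo else 4,
        lobulation=1,
        spiculation=1,
        texture=1 if ggo else 5,
        malignancy=3,
    )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CTVolume, list[NoduleAnnotation], np.ndarray]:
    """Render a phantom volume with its ground truth.

    Returns ``(volume, annotations, lung_mask)`` where ``lung_mask`` marks
    lung-interior voxels before vessels/nodules are painted, and
    ``annotations`` lists every nodule with its true centroid, diameter and
    synthesised characteristic ratings (GGO nodules get non-solid texture).
    """
    spec.validate()
    canvas = np.full(spec.shape, float(spec.air_hu))

    _paint(canvas, _body_alpha(spec), spec.body_hu)
    lung_mask, lung_soft = _lung_masks(spec)
    _paint(canvas, lung_soft, spec.lung_hu)

    for vessel in spec.vessels:
        alpha = _cylinder_alpha(spec.shape, spec.spacing, vessel)
        _paint(canvas, alpha, vessel.hu, limit=lung_soft)

    annotations = []
    for i, nod in enumerate(spec.nodules):
        radius = nod.diameter_mm / 2.0
        box, alpha = _sphere_alpha(spec.shape, spec.spacing, nod.centroid, radius)
        sub = canvas[box]
        _paint(sub, alpha, nod.hu, limit=lung_soft[box] if nod.kind != "juxtapleural" else None)
        canvas[box] = sub
        annotations.append(
            NoduleAnnotation(
                nodule_id=f"phantom-{i}",
                centroid=tuple(float(c) for c in nod.centroid),
                diameter_mm=nod.diameter_mm,
                characteristics=_synth_characteristics(nod),
                reader_id="phantom",
                is_ggo=nod.kind == "ggo",
            )
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    voxels = np.clip(np.rint(canvas), HU_MIN, HU_MAX).astype(np.int16)
    volume = CTVolume(voxels=voxels, spacing=spec.spacing, patient_id=f"phantom-seed{spec.seed}")
    return volume, annotations, lung_mask


# ---------------------------------------------------------------------------
# Documented presets used by the test and acceptance suites
# ---------------------------------------------------------------------------

def default_test_spec(difficulty: str, seed: int = 0, noise_sd: float = 0.0) -> PhantomSpec:
    """Fixed, documented phantom presets.

    - ``easy``: ten nodules with diameters spanning 4-20 mm (one GGO) and
      two obliquely tilted vessels.
    - ``ggo-heavy``: three faint GGO nodules (<= 200 HU above lung
      background) plus one solid nodule.
    - ``vessel-heavy``: vessels tilted 0, 30, 45 and 60 degrees from the
      axial normal plus three solid nodules.
    """
    shape = (40, 128, 128)
    # lung centers at x = 38.4 / 89.6; semi-axes (16.8, 42.2, 23.0) voxels
    lz, ly = 20.0, 64.0
    lx_left, lx_right = 0.30 * 128, 0.70 * 128

    if difficulty == "easy":
        nodules = (
            NoduleSpec((10, 50, 38), 4.0, 30, "solid"),
            NoduleSpec((10, 80, 38), 6.0, 30, "solid"),
            NoduleSpec((16, 40, 30), 8.0, 30, "solid"),
            NoduleSpec((22, 88, 44), 10.0, -700, "ggo"),
            NoduleSpec((28, 56, 38), 12.0, 30, "solid"),
            NoduleSpec((10, 50, 90), 14.0, 30, "solid"),
            NoduleSpec((16, 84, 96), 16.0, 30, "solid"),
            NoduleSpec((22, 44, 86), 18.0, 30, "solid"),
            NoduleSpec((29, 74, 92), 20.0, 30, "solid"),
            NoduleSpec((24, 64, 28), 10.0, 30, "solid"),
        )
        vessels = (
            VesselSpec(2.0, 45.0, 0.0, (20.0, 64.0, 52.0), 40),
            VesselSpec(2.0, 60.0, 90.0, (20.0, 64.0, lx_right), 40),
        )
    elif difficulty == "ggo-heavy":
        nodules = (
            NoduleSpec((12, 52, 38), 10.0, -700, "ggo"),
            NoduleSpec((20, 80, 40), 12.0, -680, "ggo"),
            NoduleSpec((22, 48, 90), 14.0, -660, "ggo"),
            NoduleSpec((12, 80, 92), 12.0, 30, "solid"),
        )
        vessels = (
            VesselSpec(2.0, 30.0, 0.0, (20.0, 64.0, 52.0), 40),
        )
    elif difficulty == "vessel-heavy":
        nodules = (
            NoduleSpec((12, 44, 30), 8.0, 30, "solid"),
            NoduleSpec((20, 88, 44), 12.0, 30, "solid"),
            NoduleSpec((28, 48, 92), 16.0, 30, "solid"),
        )
        vessels = (
            VesselSpec(2.5, 0.0, 0.0, (20.0, 64.0, lx_left), 40),
            VesselSpec(2.5, 30.0, 0.0, (20.0, 80.0, lx_right), 40),
            VesselSpec(2.5, 45.0, 90.0, (20.0, 52.0, lx_right), 40),
            VesselSpec(1.5, 60.0, 90.0, (10.0, 80.0, lx_left), 40),
        )
    else:
        raise ValueError(
            f"unknown difficulty {difficulty!r}; expected easy | ggo-heavy | vessel-heavy"
        )

    spec = PhantomSpec(
        shape=shape,
        nodules=nodules,
        vessels=vessels,
        seed=seed,
        noise_sd=noise_sd,
    )
    spec.validate()
    return spec


def vessel_centerline_voxels(
    spec: PhantomSpec, vessel: VesselSpec, mask: Optional[np.ndarray] = None
) -> list[tuple[int, int, int]]:
    """One voxel per slice where the vessel axis crosses it (optionally
    restricted to ``mask``); empty for exactly in-plane vessels."""
    d = vessel.direction_mm()
    if abs(d[0]) < 1e-9:
        return []
    spacing = np.asarray(spec.spacing)
    anchor = np.asarray(vessel.anchor, float) * spacing
    centers = []
    for z in range(spec.shape[0]):
        t = (z * spacing[0] - anchor[0]) / d[0]
        p = anchor + t * d
        vox = (z, int(round(p[1] / spacing[1])), int(round(p[2] / spacing[2])))
        if not (0 <= vox[1] < spec.shape[1] and 0 <= vox[2] < spec.shape[2]):
            continue
        if mask is not None and not mask[vox]:
            continue
        centers.append(vox)
    return centers
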