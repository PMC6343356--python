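"""CT volume and annotation I/O.

Volumes are held as slice-major ``(z, y, x)`` integer Hounsfield-unit grids.
Supported on-disk formats: DICOM series (requires the optional ``pydicom``
dependency), NIfTI (via nibabel, the fixture workhorse) and raster stacks
(a directory of 16-bit TIFF slices plus a JSON sidecar). Annotations follow
a reading-session XML dialect with per-reader nodule marks and the nine
standard characteristic ratings.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

HU_MIN = -1024
HU_MAX = 3071

#: Valid rating range per characteristic (both ends inclusive).
CHARACTERISTIC_RANGES: Mapping[str, tuple[int, int]] = {
    "subtlety": (1, 5),
    "internalStructure": (1, 4),
    "calcification": (1, 6),
    "sphericity": (1, 5),
    "margin": (1, 5),
    "lobulation": (1, 5),
    "spiculation": (1, 5),
    "texture": (1, 5),
    "malignancy": (1, 5),
}

CHARACTERISTIC_NAMES = tuple(CHARACTERISTIC_RANGES)


class AnnotationError(ValueError):
    """Raised for malformed or out-of-range annotation content."""


@dataclass(eq=False)
class CTVolume:
    """A CT attenuation volume in Hounsfield units.

    Parameters
    ----------
    voxels
        Slice-major ``(z, y, x)`` integer array of HU values.
    spacing
        ``(dz, dy, dx)`` voxel spacing in millimetres, each > 0.
    patient_id
        Opaque identifier carried through the pipeline.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if self.voxels.shape[0] < 3:
            raise ValueError(
                f"volume needs >= 3 slices for tri-slice composites, got {self.voxels.shape[0]}"
            )
        if not np.issubdtype(self.voxels.dtype, np.integer):
            rounded = np.rint(self.voxels)
            self.voxels = rounded.astype(np.int16)
        if self.voxels.min() < HU_MIN or self.voxels.max() > HU_MAX:
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: "
                f"range is [{self.voxels.min()}, {self.voxels.max()}]"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        return CTVolume(voxels=voxels, spacing=self.spacing, patient_id=self.patient_id)


@dataclass(frozen=True)
class Characteristics:
    """The nine standard nodule characteristic ratings."""

    subtlety: int
    internalStructure: int
    calcification: int
    sphericity: int
    margin: int
    lobulation: int
    spiculation: int
    texture: int
    malignancy: int

    def __post_init__(self) -> None:
        for name, (lo, hi) in CHARACTERISTIC_RANGES.items():
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or not lo <= int(value) <= hi:
                raise AnnotationError(
                    f"characteristic {name!r} = {value!r} outside valid range [{lo}, {hi}]"
                )

    def as_dict(self) -> dict[str, int]:
        return {name: int(getattr(self, name)) for name in CHARACTERISTIC_NAMES}


# GGO selection defaults: non-solid/part-solid texture, soft-tissue internal
# structure. The cut-offs are configurable in select_ggo_annotations.
DEFAULT_TEXTURE_MAX = 2
DEFAULT_INTERNAL_STRUCTURE = 1


def _is_ggo(characteristics: Optional[Characteristics]) -> bool:
    if characteristics is None:
        return False
    return (
        characteristics.texture <= DEFAULT_TEXTURE_MAX
        and characteristics.internalStructure == DEFAULT_INTERNAL_STRUCTURE
    )


@dataclass(frozen=True)
class NoduleAnnotation:
    """One reader's mark of one nodule.

    ``centroid`` is 0-based ``(slice, row, col)`` voxel coordinates.
    ``characteristics`` is ``None`` for small/characteristic-free marks.
    """

    nodule_id: str
    centroid: tuple[float, float, float]
    diameter_mm: float
    characteristics: Optional[Characteristics] = None
    reader_id: str = ""
    is_ggo: bool = field(default=False)

    def __post_init__(self) -> None:
        if len(self.centroid) != 3:
            raise AnnotationError(f"centroid must be (slice, row, col), got {self.centroid}")
        if not self.diameter_mm > 0:
            raise AnnotationError(f"diameter_mm must be > 0, got {self.diameter_mm}")

    def validate_against(self, volume: CTVolume) -> None:
        """Check that the centroid lies inside ``volume``."""
        for coord, dim in zip(self.centroid, volume.shape):
            if not 0 <= coord < dim:
                raise AnnotationError(
                    f"centroid {self.centroid} outside volume bounds {volume.shape}"
                )


# ---------------------------------------------------------------------------
# Volume readers / writers
# ---------------------------------------------------------------------------

def load_ct_volume(path: str | Path, format: Optional[str] = None) -> CTVolume:
    """Load a CT volume, dispatching on ``format`` or the path itself.

    Formats: ``"dicom-series"`` (directory of .dcm files), ``"nifti"``
    (.nii / .nii.gz), ``"raster-stack"`` (directory of TIFF slices with a
    ``meta.json`` sidecar).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.is_file() and (path.name.endswith(".nii") or path.name.endswith(".nii.gz")):
            format = "nifti"
        elif path.is_dir() and (path / "meta.json").exists():
            format = "raster-stack"
        elif path.is_dir():
            format = "dicom-series"
        else:
            raise ValueError(f"cannot infer volume format for {path}")
    if format == "nifti":
        return load_nifti(path)
    if format == "raster-stack":
        return load_raster_stack(path)
    if format == "dicom-series":
        return load_dicom_series(path)
    raise ValueError(f"unknown volume format {format!r}")


def load_nifti(path: str | Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)  # (x, y, z)
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing/invalid spacing in NIfTI header: zooms={zooms}")
    voxels = np.transpose(data, (2, 1, 0)).astype(np.int16)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(voxels=voxels, spacing=spacing, patient_id=Path(path).stem.split(".")[0])


def save_nifti(volume: CTVolume, path: str | Path) -> Path:
    import nibabel as nib

    path = Path(path)
    dz, dy, dx = volume.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    data = np.transpose(volume.voxels.astype(np.int16), (2, 1, 0))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))
    return path


def save_mask_nifti(mask: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> Path:
    import nibabel as nib

    dz, dy, dx = spacing
    data = np.transpose(mask.astype(np.uint8), (2, 1, 0))
    img = nib.Nifti1Image(data, np.diag([dx, dy, dz, 1.0]))
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))
    return Path(path)


def load_raster_stack(path: str | Path) -> CTVolume:
    """Load a directory of per-slice 16-bit TIFFs sorted by filename.

    ``meta.json`` must provide ``spacing`` (dz, dy, dx); ``patient_id`` and
    ``hu_offset`` (stored value + offset = HU) are optional.
    """
    import tifffile

    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ValueError(f"raster stack {path} lacks meta.json (spacing must be explicit)")
    meta = json.loads(meta_path.read_text())
    if "spacing" not in meta:
        raise ValueError(f"{meta_path} has no 'spacing' entry; refusing to default")
    offset = int(meta.get("hu_offset", 0))
    files = sorted(p for p in path.iterdir() if p.suffix in {".tif", ".tiff"})
    if not files:
        raise ValueError(f"no TIFF slices found in {path}")
    slices = [tifffile.imread(str(f)).astype(np.int32) + offset for f in files]
    voxels = np.stack(slices).astype(np.int16)
    return CTVolume(
        voxels=voxels,
        spacing=tuple(meta["spacing"]),
        patient_id=str(meta.get("patient_id", path.name)),
    )


def save_raster_stack(volume: CTVolume, path: str | Path) -> Path:
    import tifffile

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # store unsigned to stay in baseline TIFF; offset recorded in the sidecar
    offset = -HU_MIN
    meta = {
        "spacing": list(volume.spacing),
        "patient_id": volume.patient_id,
        "hu_offset": -offset,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    for i, sl in enumerate(volume.voxels):
        stored = (sl.astype(np.int32) + offset).astype(np.uint16)
        tifffile.imwrite(str(path / f"slice_{i:04d}.tif"), stored)
    return path


def load_dicom_series(path: str | Path) -> CTVolume:
    """Load a single-series DICOM directory.

    Slices are sorted by axial position; vendor rescale slope/intercept are
    applied so voxel values are HU. Mixed series identifiers or missing
    rescale/spacing tags are hard errors.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM support requires the optional 'pydicom' dependency "
            "(pip install lungcad[dicom])"
        ) from exc

    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets = [d for d in datasets if hasattr(d, "pixel_array")]
    if not datasets:
        raise ValueError(f"no DICOM images found in {path}")
    uids = {str(getattr(d, "SeriesInstanceUID", "?")) for d in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed DICOM series in {path}: {sorted(uids)}")

    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        if hasattr(ds, "SliceLocation"):
            return float(ds.SliceLocation)
        raise ValueError("DICOM slice lacks axial position tags")

    datasets.sort(key=z_of)
    slices = []
    for ds in datasets:
        if not hasattr(ds, "RescaleSlope") or not hasattr(ds, "RescaleIntercept"):
            raise ValueError("DICOM slice lacks rescale slope/intercept; refusing to assume identity")
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(np.rint(hu).astype(np.int16))
    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError("DICOM series lacks PixelSpacing; refusing to default")
    dy, dx = (float(v) for v in first.PixelSpacing)
    zs = [z_of(d) for d in datasets]
    if len(zs) > 1:
        dz = float(np.median(np.diff(zs)))
    elif hasattr(first, "SliceThickness"):
        dz = float(first.SliceThickness)
    else:
        raise ValueError("cannot determine slice spacing")
    voxels = np.clip(np.stack(slices), HU_MIN, HU_MAX).astype(np.int16)
    return CTVolume(
        voxels=voxels,
        spacing=(abs(dz), dy, dx),
        patient_id=str(getattr(first, "PatientID", path.name)),
    )


# ---------------------------------------------------------------------------
# Annotation XML dialect
# ---------------------------------------------------------------------------

def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find(elem: ET.Element, name: str) -> Optional[ET.Element]:
    for child in elem.iter():
        if _strip_ns(child.tag) == name:
            return child
    return None


def _children(elem: ET.Element, name: str) -> list[ET.Element]:
    return [c for c in elem.iter() if _strip_ns(c.tag) == name]


def parse_lidc_annotations(
    source: str | Path,
    pixel_spacing: Optional[float] = None,
    one_based: bool = True,
) -> list[NoduleAnnotation]:
    """Parse a reading-session annotation XML file.

    One annotation is returned per (reader, nodule) pair; readers are never
    merged. Pixel coordinates in the file are 1-based by convention
    (``one_based=False`` disables the shift). ``pixel_spacing`` (mm/px,
    in-plane) enables diameter estimation from edge maps when no explicit
    ``diameterMm`` element is present; marks with neither fall back to the
    3 mm small-nodule convention.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "<" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise AnnotationError(f"malformed annotation XML: {exc}") from exc

    shift = 1.0 if one_based else 0.0
    annotations: list[NoduleAnnotation] = []
    for session in _children(root, "readingSession"):
        reader_el = _find(session, "servicingRadiologistID")
        reader_id = reader_el.text.strip() if reader_el is not None and reader_el.text else ""
        for nodule in _children(session, "unblindedReadNodule"):
            annotations.append(_parse_nodule(nodule, reader_id, shift, pixel_spacing))
    return annotations


def _parse_nodule(
    nodule: ET.Element, reader_id: str, shift: float, pixel_spacing: Optional[float]
) -> NoduleAnnotation:
    id_el = _find(nodule, "noduleID")
    nodule_id = id_el.text.strip() if id_el is not None and id_el.text else ""

    characteristics = None
    char_el = None
    for child in list(nodule):
        if _strip_ns(child.tag) == "characteristics":
            char_el = child
    if char_el is not None and len(list(char_el)):
        ratings = {}
        for child in char_el:
            name = _strip_ns(child.tag)
            if name in CHARACTERISTIC_RANGES:
                try:
                    ratings[name] = int(child.text.strip())
                except (TypeError, ValueError) as exc:
                    raise AnnotationError(f"non-integer rating for {name!r}") from exc
        if set(ratings) == set(CHARACTERISTIC_NAMES):
            characteristics = Characteristics(**ratings)
        elif ratings:
            raise AnnotationError(
                f"nodule {nodule_id!r}: incomplete characteristics "
                f"(missing {sorted(set(CHARACTERISTIC_NAMES) - set(ratings))})"
            )

    slice_indices: list[float] = []
    rows: list[float] = []
    cols: list[float] = []
    extent_px = 0.0
    for roi in _children(nodule, "roi"):
        si_el = _find(roi, "sliceIndex")
        if si_el is None:
            raise AnnotationError(f"nodule {nodule_id!r}: roi lacks sliceIndex")
        slice_indices.append(float(si_el.text.strip()))
        pts = []
        for edge in _children(roi, "edgeMap"):
            x_el, y_el = _find(edge, "xCoord"), _find(edge, "yCoord")
            if x_el is None or y_el is None:
                raise AnnotationError(f"nodule {nodule_id!r}: edgeMap lacks coordinates")
            pts.append((float(y_el.text.strip()) - shift, float(x_el.text.strip()) - shift))
        if not pts:
            raise AnnotationError(f"nodule {nodule_id!r}: roi has no edgeMap points")
        rows.extend(p[0] for p in pts)
        cols.extend(p[1] for p in pts)
        if len(pts) > 1:
            arr = np.array(pts)
            d = np.sqrt(((arr[:, None, :] - arr[None, :, :]) ** 2).sum(-1)).max()
            extent_px = max(extent_px, float(d))
    if not slice_indices:
        raise AnnotationError(f"nodule {nodule_id!r}: no roi elements")

    centroid = (
        float(np.mean(slice_indices)),
        float(np.mean(rows)),
        float(np.mean(cols)),
    )

    diam_el = _find(nodule, "diameterMm")
    if diam_el is not None and diam_el.text:
        diameter = float(diam_el.text.strip())
    elif pixel_spacing is not None and extent_px > 0:
        diameter = extent_px * pixel_spacing
    else:
        diameter = 3.0  # small-mark convention: "< 3 mm"

    return NoduleAnnotation(
        nodule_id=nodule_id,
        centroid=centroid,
        diameter_mm=diameter,
        characteristics=characteristics,
        reader_id=reader_id,
        is_ggo=_is_ggo(characteristics),
    )


def serialize_lidc_annotations(annotations: Sequence[NoduleAnnotation]) -> str:
    """Write annotations back to the XML dialect (inverse of the parser)."""
    root = ET.Element("LidcReadMessage")
    by_reader: dict[str, list[NoduleAnnotation]] = {}
    for ann in annotations:
        by_reader.setdefault(ann.reader_id, []).append(ann)
    for reader_id, anns in by_reader.items():
        session = ET.SubElement(root, "readingSession")
        ET.SubElement(session, "servicingRadiologistID").text = reader_id
        for ann in anns:
            nod = ET.SubElement(session, "unblindedReadNodule")
            ET.SubElement(nod, "noduleID").text = ann.nodule_id
            if ann.characteristics is not None:
                chars = ET.SubElement(nod, "characteristics")
                for name, value in ann.characteristics.as_dict().items():
                    ET.SubElement(chars, name).text = str(value)
            roi = ET.SubElement(nod, "roi")
            z, r, c = ann.centroid
            ET.SubElement(roi, "sliceIndex").text = f"{z:g}"
            edge = ET.SubElement(roi, "edgeMap")
            ET.SubElement(edge, "xCoord").text = f"{c + 1:g}"
            ET.SubElement(edge, "yCoord").text = f"{r + 1:g}"
            ET.SubElement(nod, "diameterMm").text = f"{ann.diameter_mm:g}"
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


def select_ggo_annotations(
    annotations: Sequence[NoduleAnnotation],
    texture_max: int = DEFAULT_TEXTURE_MAX,
    internal_structure_value: int = DEFAULT_INTERNAL_STRUCTURE,
) -> list[NoduleAnnotation]:
    """Filter to GGO-like annotations by texture and internal-structure ratings.

    Keeps annotations with ``texture <= texture_max`` and
    ``internalStructure == internal_structure_value``, preserving input
    order. Characteristic-free annotations are excluded with a warning.
    """
    selected = []
    for ann in annotations:
        if ann.characteristics is None:
            logger.warning(
                "annotation %r (reader %r) has no characteristics; excluded from GGO selection",
                ann.nodule_id, ann.reader_id,
            )
            continue
        if (
            ann.characteristics.texture <= texture_max
            and ann.characteristics.internalStructure == internal_structure_value
        ):
            selected.append(ann)
    return selected


def union_of_readers(
    annotations: Sequence[NoduleAnnotation],
    spacing: tuple[float, float, float],
) -> list[NoduleAnnotation]:
    """Collapse per-reader marks of the same physical nodule to one each.

    Greedy clustering: two marks refer to one nodule when their centroids
    are within the larger mark's radius (min 1.5 mm) in physical space.
    The first reader's mark represents each cluster.
    """
    dz, dy, dx = spacing
    reps: list[NoduleAnnotation] = []
    for ann in annotations:
        matched = False
        for rep in reps:
            dist = math.sqrt(
                ((ann.centroid[0] - rep.centroid[0]) * dz) ** 2
                + ((ann.centroid[1] - rep.centroid[1]) * dy) ** 2
                + ((ann.centroid[2] - rep.centroid[2]) * dx) ** 2
            )
            tol = max(max(ann.diameter_mm, rep.diameter_mm) / 2.0, 1.5)
            if dist <= tol:
                matched = True
                break
        if not matched:
            reps.append(ann)
    return reps


def write_annotations_csv(annotations: Sequence[NoduleAnnotation], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["nodule_id", "reader_id", "slice", "row", "col", "diameter_mm", "is_ggo"]
        header += list(CHARACTERISTIC_NAMES)
        writer.writerow(header)
        for ann in annotations:
            chars = ann.characteristics.as_dict() if ann.characteristics else {}
            writer.writerow(
                [ann.nodule_id, ann.reader_id, *ann.centroid, ann.diameter_mm, int(ann.is_ggo)]
                + [chars.get(name, "") for name in CHARACTERISTIC_NAMES]
            )
    return path


# ---------------------------------------------------------------------------
# Composite export
# ---------------------------------------------------------------------------

def export_composite_png(composite, path: str | Path) -> Path:
    """Write an RGB composite as a lossless 8-bit PNG."""
    from PIL import Image

    channels = np.asarray(getattr(composite, "channels", composite))
    if channels.min() < 0 or channels.max() > 255:
        raise ValueError("composite channel values must lie in [0, 255]")
    img = Image.fromarray(channels.astype(np.uint8), mode="RGB")
    path = Path(path)
    img.save(str(path), format="PNG")
    return path


def load_composite_png(path: str | Path) -> np.ndarray:
    from PIL import Image

    with Image.open(str(path)) as img:
        return np.asarray(img.convert("RGB"))
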