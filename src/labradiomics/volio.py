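"""Volume / label-map I/O, per-substructure region extraction, and morphometry.

The pipeline works on 3-D T2-weighted-style intensity volumes together with an
integer label map that assigns every voxel to one of seven labyrinth
substructures (or background 0).  Regions of interest are tight bounding-box
crops carrying a boolean mask; all downstream statistics are computed on mask
voxels only, while crop voxels outside the mask provide spatial context for
neighbourhood filters.

Morphometry follows the surface-rendering convention: structure volume is the
voxel count times the physical voxel volume, surface area is the area of the
0.5-level iso-surface mesh of the binary mask (marching cubes after one-voxel
Gaussian anti-aliasing), with the voxel spacing applied.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

#: Canonical substructure labels of the labyrinth.
SUBSTRUCTURES: Mapping[int, str] = {
    1: "cochlea",
    2: "reuniting_duct",
    3: "vestibule",
    4: "anterior_canal",
    5: "posterior_canal",
    6: "horizontal_canal",
    7: "common_crus",
}

#: Name used for the union of all seven substructures.
LABYRINTH = "labyrinth"

_NAME_TO_LABEL = {v: k for k, v in SUBSTRUCTURES.items()}


def resolve_label(label: "int | str") -> int:
    """Map a substructure name or integer label to the integer label."""
    if isinstance(label, str):
        try:
            return _NAME_TO_LABEL[label]
        except KeyError:
            raise KeyError(f"unknown substructure name {label!r}") from None
    label = int(label)
    if label not in SUBSTRUCTURES:
        raise KeyError(f"unknown substructure label {label}")
    return label


@dataclass
class Volume:
    """A 3-D scalar image with physical voxel spacing (mm)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must all be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        self.origin = tuple(float(o) for o in self.origin)


@dataclass
class LabelMap:
    """Integer substructure labels on the same grid as a :class:`Volume`."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    label_names: Mapping[int, str] = field(default_factory=lambda: dict(SUBSTRUCTURES))
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label map must be 3-D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.array_equal(rounded, self.data):
                raise ValueError("label map must contain integers")
            self.data = rounded.astype(np.uint8)
        present = np.unique(self.data)
        bad = [int(v) for v in present if v < 0 or v > 7]
        if bad:
            raise ValueError(f"labels must lie in 0..7, found {bad}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    def labels_present(self) -> list[int]:
        return [int(v) for v in np.unique(self.data) if v != 0]


@dataclass
class RegionExtract:
    """Tight bounding-box crop of one substructure plus its boolean mask.

    ``crop_origin`` is the (inclusive, 0-based) voxel offset of the crop
    within the parent volume; bounding boxes are half-open.
    """

    crop: np.ndarray
    mask: np.ndarray
    crop_origin: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.crop = np.asarray(self.crop, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.crop.shape != self.mask.shape:
            raise ValueError("crop and mask shapes differ")
        if not self.mask.any():
            raise ValueError("region mask is empty")
        self.crop_origin = tuple(int(o) for o in self.crop_origin)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class Morphometry:
    surface_area_mm2: float
    volume_mm3: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.surface_area_mm2) and self.surface_area_mm2 >= 0):
            raise ValueError("surface area must be finite and non-negative")
        if not (math.isfinite(self.volume_mm3) and self.volume_mm3 >= 0):
            raise ValueError("volume must be finite and non-negative")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), _affine(volume.spacing_mm, volume.origin))
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return Volume(data, spacing, origin)


def write_labels(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(np.asarray(labels.data, dtype=np.uint8), _affine(labels.spacing_mm, labels.origin))
    nib.save(img, str(path))


def read_labels(path) -> LabelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return LabelMap(data.astype(np.uint8), spacing, dict(SUBSTRUCTURES), origin)


def check_aligned(volume: Volume, labels: LabelMap) -> None:
    """Raise if a volume and label map do not share a grid."""
    if volume.data.shape != labels.data.shape:
        raise ValueError(
            f"volume shape {volume.data.shape} does not match label map shape {labels.data.shape}"
        )


# ---------------------------------------------------------------------------
# Region extraction


def _region_from_mask(volume: Volume, mask: np.ndarray, what: str) -> RegionExtract:
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        raise ValueError(f"selection {what} is empty")
    lo = tuple(int(i.min()) for i in idx)
    hi = tuple(int(i.max()) + 1 for i in idx)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return RegionExtract(volume.data[sl].copy(), mask[sl].copy(), lo, volume.spacing_mm)


def extract_region(volume: Volume, labels: LabelMap, label: "int | str") -> RegionExtract:
    """Tight bounding-box region of one substructure."""
    check_aligned(volume, labels)
    lab = resolve_label(label)
    return _region_from_mask(volume, labels.data == lab, SUBSTRUCTURES[lab])


def labyrinth_region(volume: Volume, labels: LabelMap) -> RegionExtract:
    """Region of the whole labyrinth (union of labels 1-7)."""
    check_aligned(volume, labels)
    mask = (labels.data >= 1) & (labels.data <= 7)
    return _region_from_mask(volume, mask, LABYRINTH)


# ---------------------------------------------------------------------------
# Morphometry


def _selection_mask(labels: LabelMap, selection) -> np.ndarray:
    if selection == LABYRINTH:
        sel = list(SUBSTRUCTURES)
    elif isinstance(selection, (int, np.integer, str)):
        sel = [resolve_label(selection)]
    else:
        sel = [resolve_label(s) for s in selection]
    return np.isin(labels.data, sel)


def morphometry(labels: LabelMap, selection) -> Morphometry:
    """Surface area (iso-surface mesh) and volume (voxel count) of a selection.

    ``selection`` is a label, a substructure name, an iterable of labels, or
    the string ``"labyrinth"`` for the union of all seven substructures.
    """
    mask = _selection_mask(labels, selection)
    if not mask.any():
        raise ValueError(f"selection {selection!r} is empty")
    voxel_volume = float(np.prod(labels.spacing_mm))
    volume_mm3 = float(mask.sum()) * voxel_volume
    # One-voxel Gaussian anti-aliasing before meshing: the 0.5 level set of the
    # raw binary mask carries a persistent staircase area bias (~8% on a
    # sphere) that does not vanish under refinement; smoothing restores the
    # sub-percent accuracy and monotone convergence of surface rendering.
    padded = np.pad(mask, 2).astype(np.float32)
    field = ndimage.gaussian_filter(padded, sigma=1.0)
    if field.max() <= 0.5:  # structures a few voxels thin smooth away entirely
        field = padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=labels.spacing_mm)
    area = float(measure.mesh_surface_area(verts, faces))
    return Morphometry(area, volume_mm3)


def morphometry_table(labels: LabelMap) -> pd.DataFrame:
    """Per-substructure + whole-labyrinth surface area and volume."""
    rows = []
    for lab, name in SUBSTRUCTURES.items():
        m = morphometry(labels, lab)
        rows.append({"label": lab, "substructure": name,
                     "surface_area_mm2": m.surface_area_mm2, "volume_mm3": m.volume_mm3})
    m = morphometry(labels, LABYRINTH)
    rows.append({"label": 0, "substructure": LABYRINTH,
                 "surface_area_mm2": m.surface_area_mm2, "volume_mm3": m.volume_mm3})
    return pd.DataFrame(rows)
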