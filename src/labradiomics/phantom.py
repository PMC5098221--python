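"""Synthetic labyrinth phantoms and cohorts.

No imaging from the study population is deposited anywhere, so every
downstream stage is exercised on synthetic phantoms: a stylized membranous
labyrinth assembled from parametric primitives — a spiral tube for the
cochlea, an ellipsoid for the vestibule, three mutually orthogonal torus arcs
for the semicircular canals, a straight tube for the common crus, and a small
tube for the region containing the reuniting duct (deliberately the smallest
substructure).  The geometry is stylized and compact rather than anatomically
dimensioned; what matters for the pipeline is that all seven substructures
exist, differ in size, and present curved boundaries to the filter bank.

Intensities follow a two-compartment model: background voxels are
Normal(base_intensity, noise_sd), labyrinth voxels Normal(lumen_intensity,
noise_sd), mimicking the bright endolymph/perilymph signal of heavily
T2-weighted sequences.  Cohorts add mild inter-subject geometric jitter
(random rigid rotation up to 5 degrees, isotropic size jitter up to 5%) to
both groups, and apply the requested effects only to case subjects.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .volio import SUBSTRUCTURES, LabelMap, Volume, resolve_label, write_labels, write_volume

EFFECT_KINDS = ("mean_shift", "variance_scale", "gradient_tilt")

#: Global scale of the stylized geometry (mm per base unit).
_GEOM_SCALE = 1.2

# Painting order: structures drawn first keep contested voxels.
_PAINT_ORDER = (3, 1, 2, 4, 5, 6, 7)


class GeometryError(ValueError):
    """A substructure does not fit inside the requested grid."""


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (0.4, 0.4, 0.4)
    base_intensity: float = 100.0
    lumen_intensity: float = 200.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.spacing_mm, (int, float)):
            self.spacing_mm = (float(self.spacing_mm),) * 3
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.grid_shape) != 3 or any(n < 32 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 values each >= 32, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class EffectSpec:
    """A group-specific perturbation confined to one substructure.

    ``magnitude`` is an additive shift in units of noise_sd (mean_shift), a
    multiplicative factor on the noise deviation (variance_scale), or an
    intensity slope per voxel along the first grid axis (gradient_tilt).
    """

    substructure: int
    effect_kind: str
    magnitude: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "substructure", resolve_label(self.substructure))
        if self.effect_kind not in EFFECT_KINDS:
            raise ValueError(f"effect_kind must be one of {EFFECT_KINDS}, got {self.effect_kind!r}")
        if self.effect_kind == "variance_scale" and not self.magnitude > 0:
            raise ValueError("variance_scale magnitude must be > 0")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    volume_path: str
    labels_path: str


@dataclass
class CohortManifest:
    subjects: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        for grp in ("case", "control"):
            if sum(s.group == grp for s in self.subjects) < 2:
                raise ValueError(f"need >= 2 subjects in group {grp!r}")

    def to_csv(self, path) -> None:
        pd.DataFrame([s.__dict__ for s in self.subjects]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortManifest":
        df = pd.read_csv(path)
        return cls([SubjectRecord(str(r.subject_id), str(r.group),
                                  str(r.volume_path), str(r.labels_path))
                    for r in df.itertuples()])


# ---------------------------------------------------------------------------
# geometry


def _spiral_skeleton() -> tuple[np.ndarray, np.ndarray]:
    """Cochlear spiral: 2.25 turns, shrinking radius, slight axial rise."""
    t_max = 2.25 * 2 * np.pi
    t = np.linspace(0.0, t_max, 400)
    frac = t / t_max
    radius = 1.9 * (1.0 - 0.55 * frac)
    pts = np.column_stack([
        -3.8 + radius * np.cos(t),
        radius * np.sin(t),
        -0.6 + 1.0 * frac,
    ])
    tube = 0.62 * (1.0 - 0.35 * frac)
    return pts, tube


def _arc_skeleton(center, u, w, radius, theta_deg) -> np.ndarray:
    th = np.deg2rad(np.linspace(theta_deg[0], theta_deg[1], 260))
    u = np.asarray(u, float)
    w = np.asarray(w, float)
    return np.asarray(center, float) + radius * (np.cos(th)[:, None] * u + np.sin(th)[:, None] * w)


def _line_skeleton(a, b, n=60) -> np.ndarray:
    s = np.linspace(0.0, 1.0, n)[:, None]
    return np.asarray(a, float) * (1 - s) + np.asarray(b, float) * s


_SQ2 = np.sqrt(2.0)


def _base_tubes() -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Skeleton points and per-point tube radii, in base units, per label."""
    spiral_pts, spiral_r = _spiral_skeleton()
    tubes: dict[int, tuple[np.ndarray, np.ndarray]] = {
        1: (spiral_pts, spiral_r),
        2: (_line_skeleton((-1.5, 0.5, -1.0), (-0.4, 0.35, -0.65)),
            np.full(60, 0.30)),
        # anterior and posterior canals: vertical rings at +/-45 deg, gap facing
        # the vestibule; horizontal canal: ring in the axial plane.
        4: (_arc_skeleton((0.5, 1.0, 3.2), (1 / _SQ2, -1 / _SQ2, 0), (0, 0, 1),
                          2.1, (-60, 240)), np.full(260, 0.42)),
        5: (_arc_skeleton((0.5, -1.0, 3.2), (1 / _SQ2, 1 / _SQ2, 0), (0, 0, 1),
                          2.1, (-60, 240)), np.full(260, 0.42)),
        6: (_arc_skeleton((-0.4, 0.0, 1.2), (1, 0, 0), (0, 1, 0),
                          2.4, (30, 330)), np.full(260, 0.42)),
        7: (_line_skeleton((0.5, 0.0, 3.0), (0.5, 0.0, 4.8)), np.full(60, 0.40)),
    }
    return tubes


_VESTIBULE_CENTER = np.array([1.2, 0.0, 0.0])
_VESTIBULE_AXES = np.array([1.5, 1.2, 1.0])


def _paint_tube(lab: np.ndarray, value: int, pts: np.ndarray, radii: np.ndarray,
                spacing: np.ndarray, name: str) -> None:
    shape = np.array(lab.shape)
    ctr = (shape - 1) / 2.0
    for p, r in zip(pts, radii):
        idx = p / spacing + ctr
        rvox = r / spacing
        lo = np.floor(idx - rvox).astype(int)
        hi = np.ceil(idx + rvox).astype(int) + 1
        if (lo < 0).any() or (hi > shape).any():
            raise GeometryError(f"substructure '{name}' does not fit grid shape {tuple(shape)}")
        ax = [((np.arange(l, h) - c) * s - pc) ** 2
              for l, h, c, s, pc in zip(lo, hi, ctr, spacing, p)]
        d2 = ax[0][:, None, None] + ax[1][None, :, None] + ax[2][None, None, :]
        sub = lab[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[(d2 <= r * r) & (sub == 0)] = value
        near = tuple(np.rint(idx).astype(int))
        if lab[near] == 0:
            lab[near] = value


def _paint_ellipsoid(lab: np.ndarray, value: int, rot: np.ndarray, scale: float,
                     spacing: np.ndarray, name: str) -> None:
    shape = np.array(lab.shape)
    ctr = (shape - 1) / 2.0
    center_w = scale * rot @ (_GEOM_SCALE * _VESTIBULE_CENTER)
    reach = scale * _GEOM_SCALE * _VESTIBULE_AXES.max()
    lo = np.floor((center_w - reach) / spacing + ctr).astype(int)
    hi = np.ceil((center_w + reach) / spacing + ctr).astype(int) + 1
    if (lo < 0).any() or (hi > shape).any():
        raise GeometryError(f"substructure '{name}' does not fit grid shape {tuple(shape)}")
    axes_coords = [(np.arange(l, h) - c) * s for l, h, c, s in zip(lo, hi, ctr, spacing)]
    gx, gy, gz = np.meshgrid(*axes_coords, indexing="ij")
    pw = np.stack([gx, gy, gz], axis=-1)
    # invert the rigid+scale transform to evaluate the base-frame ellipsoid
    base = (pw @ rot) / (scale * _GEOM_SCALE)  # pw @ rot == rot.T applied to rows
    q = ((base - _VESTIBULE_CENTER) / _VESTIBULE_AXES) ** 2
    inside = q.sum(axis=-1) <= 1.0
    sub = lab[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[inside & (sub == 0)] = value


def build_label_map(grid_shape: Sequence[int], spacing_mm: Sequence[float],
                    rotation: np.ndarray | None = None, scale: float = 1.0) -> np.ndarray:
    """Rasterize the stylized labyrinth onto a voxel grid.

    ``rotation`` (3x3) and ``scale`` apply a rigid rotation and isotropic size
    change to the whole geometry about the grid center.  Returns a uint8 array
    with labels 1-7, pairwise disjoint and each non-empty.
    """
    rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
    spacing = np.asarray(spacing_mm, float)
    lab = np.zeros(tuple(int(n) for n in grid_shape), dtype=np.uint8)
    tubes = _base_tubes()
    for value in _PAINT_ORDER:
        name = SUBSTRUCTURES[value]
        if value == 3:
            _paint_ellipsoid(lab, value, rot, scale, spacing, name)
        else:
            pts, radii = tubes[value]
            pts_w = scale * (_GEOM_SCALE * pts) @ rot.T
            _paint_tube(lab, value, pts_w, scale * _GEOM_SCALE * radii, spacing, name)
    for value, name in SUBSTRUCTURES.items():
        if not (lab == value).any():
            raise GeometryError(f"substructure '{name}' rasterized to zero voxels")
    return lab


# ---------------------------------------------------------------------------
# intensity synthesis


def _validate_effects(effects: Iterable[EffectSpec]) -> list[EffectSpec]:
    effects = list(effects)
    for e in effects:
        if e.substructure not in SUBSTRUCTURES:
            raise ValueError(f"unknown substructure label {e.substructure}")
    return effects


def _synthesize(config: PhantomConfig, rng: np.random.Generator, lab: np.ndarray,
                effects: Sequence[EffectSpec]) -> np.ndarray:
    noise = rng.standard_normal(lab.shape)
    for e in effects:
        if e.effect_kind == "variance_scale":
            noise[lab == e.substructure] *= e.magnitude
    data = np.where(lab > 0, config.lumen_intensity, config.base_intensity).astype(float)
    data += config.noise_sd * noise
    for e in effects:
        m = lab == e.substructure
        if e.effect_kind == "mean_shift":
            data[m] += e.magnitude * config.noise_sd
        elif e.effect_kind == "gradient_tilt":
            i0 = np.nonzero(m)[0].astype(float)
            data[m] += e.magnitude * (i0 - i0.mean())  # mean-free ramp along axis 0
    return data


def generate_phantom(config: PhantomConfig, seed: int | None = None) -> tuple[Volume, LabelMap]:
    """One phantom volume + label map (base geometry, no jitter).

    Deterministic given (config, seed); ``seed=None`` falls back to
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lab = build_label_map(config.grid_shape, config.spacing_mm)
    data = _synthesize(config, rng, lab, [])
    labels = LabelMap(lab, config.spacing_mm)
    return Volume(data, config.spacing_mm), labels


def iter_cohort_subjects(n_case: int, n_control: int, config: PhantomConfig,
                         effects: Iterable[EffectSpec], seed: int,
                         ) -> Iterator[tuple[str, str, Volume, LabelMap]]:
    """Generate cohort subjects lazily, without touching disk.

    Case subjects receive every effect; controls none.  Jitter (rotation up
    to 5 degrees about a random axis, size factor in [0.95, 1.05]) is drawn
    identically in distribution for both groups.  Per-subject seeds derive
    deterministically from the cohort seed and subject index.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need n_case >= 2 and n_control >= 2")
    effects = _validate_effects(effects)
    groups = [("case", i) for i in range(n_case)] + [("control", i) for i in range(n_control)]
    for subject_index, (group, i) in enumerate(groups):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), subject_index]))
        angle = np.deg2rad(rng.uniform(0.0, 5.0))
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        scale = rng.uniform(0.95, 1.05)
        rot = Rotation.from_rotvec(angle * axis).as_matrix()
        lab = build_label_map(config.grid_shape, config.spacing_mm, rot, scale)
        data = _synthesize(config, rng, lab, effects if group == "case" else [])
        subject_id = f"{group}_{i + 1:03d}"
        yield subject_id, group, Volume(data, config.spacing_mm), LabelMap(lab, config.spacing_mm)


def generate_cohort(n_case: int, n_control: int, config: PhantomConfig,
                    effects: Iterable[EffectSpec], seed: int, out_dir) -> CohortManifest:
    """Write a full synthetic cohort (NIfTI volumes + label maps + manifest CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for subject_id, group, volume, labels in iter_cohort_subjects(
            n_case, n_control, config, effects, seed):
        vpath = out / f"{subject_id}_volume.nii.gz"
        lpath = out / f"{subject_id}_labels.nii.gz"
        write_volume(volume, vpath)
        write_labels(labels, lpath)
        records.append(SubjectRecord(subject_id, group, str(vpath), str(lpath)))
    manifest = CohortManifest(records)
    manifest.to_csv(out / "manifest.csv")
    return manifest
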