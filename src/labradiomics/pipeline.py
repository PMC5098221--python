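"""Per-subject feature extraction and whole-labyrinth ratio normalization.

Each subject contributes eight 26x23 feature grids: one per substructure and
one for the whole labyrinth.  Normalization divides every substructure cell
by the matching whole-labyrinth cell of the same subject, the study's device
for suppressing scanner- and protocol-scale effects.  Denominators smaller
than 1e-12 in magnitude (routine for binarizing filters whose minimum is
exactly zero) yield an explicitly missing cell rather than an infinity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import featstats, volio
from .featstats import FeatureGrid
from .phantom import CohortManifest
from .volio import SUBSTRUCTURES, LabelMap, Volume

logger = logging.getLogger(__name__)

DENOMINATOR_GUARD = 1e-12


@dataclass
class SubjectFeatures:
    subject_id: str
    group: str
    raw: dict[int, FeatureGrid]
    labyrinth: FeatureGrid
    normalized: Optional[dict[int, FeatureGrid]] = None


def extract_subject(volume: Volume, labels: LabelMap,
                    substructures: Optional[Sequence[int]] = None,
                    subject_id: str = "", group: str = "") -> SubjectFeatures:
    """Raw feature grids for the requested substructures plus the labyrinth."""
    wanted = [volio.resolve_label(s) for s in (substructures or list(SUBSTRUCTURES))]
    present = set(labels.labels_present())
    for lab in wanted:
        if lab not in present:
            raise ValueError(f"substructure '{SUBSTRUCTURES[lab]}' (label {lab}) missing from label map")
    raw = {lab: featstats.compute_grid(volio.extract_region(volume, labels, lab))
           for lab in wanted}
    labyrinth = featstats.compute_grid(volio.labyrinth_region(volume, labels))
    return SubjectFeatures(subject_id, group, raw, labyrinth)


def _ratio(raw: np.ndarray, denom: np.ndarray) -> np.ndarray:
    ok = np.isfinite(raw) & np.isfinite(denom) & (np.abs(denom) >= DENOMINATOR_GUARD)
    out = np.full(raw.shape, np.nan)
    out[ok] = raw[ok] / denom[ok]
    return out


def normalize(subject: SubjectFeatures) -> SubjectFeatures:
    """Fill the normalized grids: substructure cell / labyrinth cell."""
    denom = subject.labyrinth.values
    normalized = {lab: FeatureGrid(_ratio(grid.values, denom))
                  for lab, grid in subject.raw.items()}
    return SubjectFeatures(subject.subject_id, subject.group, subject.raw,
                           subject.labyrinth, normalized)


# ---------------------------------------------------------------------------
# cohort store


class CohortStore:
    """Normalized feature grids (and optional morphometry) for a cohort."""

    def __init__(self) -> None:
        self.groups: dict[str, str] = {}
        self.normalized: dict[tuple[str, int], np.ndarray] = {}
        self.raw_labyrinth: dict[str, np.ndarray] = {}
        self.morphometry: Optional[pd.DataFrame] = None
        self.failures: list[tuple[str, str]] = []

    def add_subject(self, feats: SubjectFeatures) -> None:
        if feats.normalized is None:
            feats = normalize(feats)
        self.groups[feats.subject_id] = feats.group
        self.raw_labyrinth[feats.subject_id] = feats.labyrinth.values
        for lab, grid in feats.normalized.items():
            self.normalized[(feats.subject_id, lab)] = grid.values

    def subjects(self, group: Optional[str] = None) -> list[str]:
        return [s for s, g in self.groups.items() if group is None or g == group]

    def labels_present(self) -> list[int]:
        return sorted({lab for _, lab in self.normalized})

    def cell(self, label: int, filter_index: int, statistic_index: int,
             ) -> tuple[np.ndarray, np.ndarray]:
        """(case values, control values) of one normalized grid cell."""
        label = volio.resolve_label(label)
        out = {"case": [], "control": []}
        for sid, grp in self.groups.items():
            grid = self.normalized.get((sid, label))
            if grid is not None:
                out[grp].append(grid[filter_index - 1, statistic_index - 1])
        return np.asarray(out["case"]), np.asarray(out["control"])

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for (sid, lab), values in self.normalized.items():
            grid = FeatureGrid(values)
            frames.append(grid.to_long_frame(subject_id=sid, group=self.groups[sid],
                                             substructure=lab))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortStore":
        store = cls()
        for (sid, lab), part in df.groupby(["subject_id", "substructure"], sort=False):
            store.groups[str(sid)] = str(part["group"].iloc[0])
            store.normalized[(str(sid), int(lab))] = FeatureGrid.from_long_frame(part).values
        return store

    @classmethod
    def from_csv(cls, path) -> "CohortStore":
        return cls.from_frame(pd.read_csv(path))


def _morphometry_rows(labels: LabelMap, subject_id: str, group: str) -> pd.DataFrame:
    df = volio.morphometry_table(labels)
    df.insert(0, "group", group)
    df.insert(0, "subject_id", subject_id)
    return df


def run_cohort_from_subjects(subjects: Iterable[tuple[str, str, Volume, LabelMap]],
                             substructures: Optional[Sequence[int]] = None,
                             compute_morphometry: bool = True) -> CohortStore:
    """Run extraction + normalization over in-memory subjects.

    Per-subject failures are recorded and skipped; the run fails only if a
    group ends with fewer than two usable subjects.
    """
    store = CohortStore()
    morph_frames = []
    for subject_id, group, volume, labels in subjects:
        try:
            feats = extract_subject(volume, labels, substructures, subject_id, group)
            store.add_subject(normalize(feats))
            if compute_morphometry:
                morph_frames.append(_morphometry_rows(labels, subject_id, group))
        except Exception as exc:  # isolate the subject, keep the cohort going
            logger.warning("subject %s failed: %s", subject_id, exc)
            store.failures.append((subject_id, str(exc)))
    if compute_morphometry and morph_frames:
        store.morphometry = pd.concat(morph_frames, ignore_index=True)
    for grp in ("case", "control"):
        if len(store.subjects(grp)) < 2:
            raise RuntimeError(f"group {grp!r} has fewer than 2 usable subjects "
                               f"({len(store.failures)} failures: {store.failures[:3]})")
    return store


def _iter_manifest(manifest: CohortManifest):
    for rec in manifest.subjects:
        volume = volio.read_volume(rec.volume_path)
        labels = volio.read_labels(rec.labels_path)
        volio.check_aligned(volume, labels)
        yield rec.subject_id, rec.group, volume, labels


def run_cohort(manifest: CohortManifest,
               substructures: Optional[Sequence[int]] = None,
               compute_morphometry: bool = True) -> CohortStore:
    """Run the per-subject pipeline over a manifest of files on disk."""

    def gen():
        for rec in manifest.subjects:
            try:
                volume = volio.read_volume(rec.volume_path)
                labels = volio.read_labels(rec.labels_path)
                volio.check_aligned(volume, labels)
            except Exception as exc:
                logger.warning("subject %s unreadable: %s", rec.subject_id, exc)
                _read_failures.append((rec.subject_id, str(exc)))
                continue
            yield rec.subject_id, rec.group, volume, labels

    _read_failures: list[tuple[str, str]] = []
    store = run_cohort_from_subjects(gen(), substructures, compute_morphometry)
    store.failures = _read_failures + store.failures
    return store
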