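"""Permutation inference over 26x23 feature grids: p-values, counts, bands.

Group comparison uses a two-sided permutation test on the difference of group
means.  When the number of distinct group-label assignments is no larger than
the requested permutation count, the test enumerates all assignments and the
p-value is exact; otherwise it samples uniformly with the add-one correction
p = (1 + #extreme) / (1 + n_perm), so p is never zero.

Following the study design, no multiple-testing correction is applied across
the 598 cells; the informal guard is the *band*: a row (statistic) or column
(filter) of the significance grid holding three or more significant cells.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Optional

import numpy as np
import pandas as pd

from . import volio
from .featstats import N_FILTERS, N_STATISTICS
from .pipeline import CohortStore

_REL_TOL = 1e-12  # tie tolerance when comparing |T_perm| with |T_obs|


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return x[np.isfinite(x)]


def derive_cell_seed(seed: int, filter_index: int, statistic_index: int) -> int:
    """Deterministic per-cell seed from the grid seed and cell coordinates."""
    ss = np.random.SeedSequence([int(seed), int(filter_index), int(statistic_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def permutation_test(a, b, n_perm: int = 10000, seed: int = 0,
                     method: str = "auto") -> float:
    """Two-sided permutation p-value for mean(a) - mean(b).

    Non-finite entries are dropped first; a group left with fewer than two
    values gives a missing (NaN) p-value.  With ``method="auto"`` exhaustive
    enumeration is used whenever C(n, |a|) <= n_perm, making the p-value
    exact; ``"exhaustive"`` and ``"sampled"`` force the respective route.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if method not in ("auto", "exhaustive", "sampled"):
        raise ValueError(f"unknown method {method!r}")
    a, b = _clean(a), _clean(b)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return float("nan")
    pooled = np.concatenate([a, b])
    n = na + nb
    total_sum = float(pooled.sum())
    t_obs = float(a.mean() - b.mean())
    tol = _REL_TOL * max(1.0, abs(t_obs))

    n_assign = comb(n, na)
    if method == "exhaustive" or (method == "auto" and n_assign <= n_perm):
        idx = np.fromiter(itertools.chain.from_iterable(itertools.combinations(range(n), na)),
                          dtype=np.intp, count=n_assign * na).reshape(n_assign, na)
        s = pooled[idx].sum(axis=1)
        t = s / na - (total_sum - s) / nb
        hits = int(np.count_nonzero(np.abs(t) >= abs(t_obs) - tol))
        return hits / n_assign

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, int(2e7) // n)
    remaining = n_perm
    while remaining > 0:
        m = min(chunk, remaining)
        order = np.argsort(rng.random((m, n)), axis=1)[:, :na]
        s = pooled[order].sum(axis=1)
        t = s / na - (total_sum - s) / nb
        hits += int(np.count_nonzero(np.abs(t) >= abs(t_obs) - tol))
        remaining -= m
    return (1 + hits) / (1 + n_perm)


@dataclass
class SignificanceGrid:
    """26x23 grid of two-sided permutation p-values for one substructure."""

    p: np.ndarray
    alpha: float = 0.05
    n_perm: int = 10000
    seed: int = 0
    substructure: Optional[int] = None
    n_eff: Optional[np.ndarray] = None  # per-cell (n_case + n_control) after deletion

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_FILTERS, N_STATISTICS):
            raise ValueError(f"p grid must be {N_FILTERS}x{N_STATISTICS}, got {self.p.shape}")
        finite = self.p[np.isfinite(self.p)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("p-values must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class BandReport:
    row_bands: list[int]     # statistic indices with >= min_run significant cells
    column_bands: list[int]  # filter indices with >= min_run significant cells
    min_run: int
    n_significant: int

    @property
    def n_bands(self) -> int:
        return len(self.row_bands) + len(self.column_bands)


def build_significance_grid(store: CohortStore, substructure, alpha: float = 0.05,
                            n_perm: int = 10000, seed: int = 0) -> SignificanceGrid:
    """Per-cell permutation tests on one substructure's normalized features.

    Missing subjects are deleted pairwise per cell; each cell's RNG seed
    derives from (seed, filter_index, statistic_index) so any cell can be
    reproduced by a standalone :func:`permutation_test` call.
    """
    label = volio.resolve_label(substructure)
    if label not in store.labels_present():
        raise ValueError(f"substructure {substructure!r} absent from store")
    p = np.full((N_FILTERS, N_STATISTICS), np.nan)
    n_eff = np.zeros((N_FILTERS, N_STATISTICS), dtype=int)
    for fi in range(1, N_FILTERS + 1):
        for si in range(1, N_STATISTICS + 1):
            a, b = store.cell(label, fi, si)
            a, b = _clean(a), _clean(b)
            n_eff[fi - 1, si - 1] = a.size + b.size
            p[fi - 1, si - 1] = permutation_test(
                a, b, n_perm=n_perm, seed=derive_cell_seed(seed, fi, si))
    return SignificanceGrid(p, alpha, n_perm, seed, label, n_eff)


def count_significant(grid: SignificanceGrid) -> int:
    """Number of non-missing cells with p strictly below alpha."""
    with np.errstate(invalid="ignore"):
        return int(np.count_nonzero(grid.p < grid.alpha))


def detect_bands(grid: SignificanceGrid, min_run: int = 3) -> BandReport:
    """Rows (statistics) and columns (filters) with >= min_run significant cells.

    Cells need not be adjacent; a missing p never counts as significant.
    """
    with np.errstate(invalid="ignore"):
        sig = grid.p < grid.alpha
    row_bands = [si for si in range(1, N_STATISTICS + 1)
                 if int(sig[:, si - 1].sum()) >= min_run]
    column_bands = [fi for fi in range(1, N_FILTERS + 1)
                    if int(sig[fi - 1, :].sum()) >= min_run]
    return BandReport(row_bands, column_bands, min_run, int(sig.sum()))


def grid_summary(grid: SignificanceGrid, min_run: int = 3) -> dict:
    report = detect_bands(grid, min_run)
    return {
        "substructure": None if grid.substructure is None
        else volio.SUBSTRUCTURES[grid.substructure],
        "n_significant": report.n_significant,
        "n_bands": report.n_bands,
        "row_bands": report.row_bands,
        "column_bands": report.column_bands,
    }


def compare_morphometry(store: CohortStore, n_perm: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Permutation tests on surface area and volume, per structure (16 tests)."""
    if store.morphometry is None:
        raise ValueError("store holds no morphometry (run the cohort with compute_morphometry=True)")
    df = store.morphometry
    rows = []
    for label, part in df.groupby("label"):
        name = volio.LABYRINTH if label == 0 else volio.SUBSTRUCTURES[int(label)]
        for mi, measure in enumerate(("surface_area_mm2", "volume_mm3")):
            a = part.loc[part["group"] == "case", measure].to_numpy()
            b = part.loc[part["group"] == "control", measure].to_numpy()
            cell_seed = derive_cell_seed(seed, 100 + int(label), mi)
            rows.append({
                "label": int(label), "structure": name, "measure": measure,
                "p_value": permutation_test(a, b, n_perm=n_perm, seed=cell_seed),
                "n_case": int(a.size), "n_control": int(b.size),
            })
    return pd.DataFrame(rows)
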