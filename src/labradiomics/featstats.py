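"""The 23 secondary radiomic features: scalar statistics of masked values.

Statistics are computed on a filtered region's mask voxels, taken in raster
order (axis 0 slowest).  A statistic whose value is undefined for the data at
hand (e.g. variance confidence bounds at n < 2, the autocorrelation test on a
constant series) yields a *missing* value, represented as NaN throughout;
computation never fails on degenerate but non-empty inputs.

Conventions: variance and standard deviation use the n-1 (sample) form;
skewness and kurtosis use biased moment estimators, with kurtosis non-excess
(normal -> 3); the intensity centroid is the intensity-weighted mean voxel
coordinate per axis relative to the crop origin; "Commonest" is the mean of
the centers of all maximal-count bins of a 64-bin histogram; the
autocorrelation test is the Ljung-Box portmanteau p-value at lag
min(10, floor(n/5)) on the raster-ordered sequence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import filterbank
from .volio import RegionExtract

N_FILTERS = 26
N_STATISTICS = 23
N_CELLS = N_FILTERS * N_STATISTICS  # 598 features per region


@dataclass(frozen=True)
class StatisticSpec:
    index: int
    name: str
    params: Mapping[str, object] = field(default_factory=dict)


_REGISTRY = (
    StatisticSpec(1, "MinIntensity"),
    StatisticSpec(2, "MaxIntensity"),
    StatisticSpec(3, "MeanIntensity"),
    StatisticSpec(4, "MedianIntensity"),
    StatisticSpec(5, "StandardDeviationIntensity", {"ddof": 1}),
    StatisticSpec(6, "TotalIntensity"),
    StatisticSpec(7, "Skew"),
    StatisticSpec(8, "IntensityCentroid (x-coordinate)", {"axis": 0}),
    StatisticSpec(9, "IntensityCentroid (y-coordinate)", {"axis": 1}),
    StatisticSpec(10, "IntensityCentroid (z-coordinate)", {"axis": 2}),
    StatisticSpec(11, "Entropy", {"bins": 64}),
    StatisticSpec(12, "Energy"),
    StatisticSpec(13, "DominantColors (amount)", {"k": 5, "abundance_floor": 0.05}),
    StatisticSpec(14, "DominantColors (primary)", {"k": 5}),
    StatisticSpec(15, "VarianceCI (low)", {"level": 0.95}),
    StatisticSpec(16, "VarianceCI (high)", {"level": 0.95}),
    StatisticSpec(17, "Kurtosis"),
    StatisticSpec(18, "TrimmedMean", {"trim_frac": 0.05}),
    StatisticSpec(19, "MeanDeviation"),
    StatisticSpec(20, "RootMeanSquare"),
    StatisticSpec(21, "Variance", {"ddof": 1}),
    StatisticSpec(22, "Commonest (mean)", {"bins": 64}),
    StatisticSpec(23, "AutocorrelationTest", {"max_lag": 10}),
)


def registry() -> tuple[StatisticSpec, ...]:
    """The 23 secondary-feature specs in stable order."""
    return _REGISTRY


@dataclass(frozen=True)
class FeatureValue:
    value: float  # NaN means missing
    filter_index: int
    statistic_index: int

    @property
    def missing(self) -> bool:
        return math.isnan(self.value)


class FeatureGrid:
    """A 26 x 23 matrix of feature values for one region; NaN marks missing."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (N_FILTERS, N_STATISTICS):
            raise ValueError(f"feature grid must be {N_FILTERS}x{N_STATISTICS}, got {values.shape}")
        self.values = values

    @property
    def n_cells(self) -> int:
        return N_CELLS

    def cell(self, filter_index: int, statistic_index: int) -> FeatureValue:
        return FeatureValue(float(self.values[filter_index - 1, statistic_index - 1]),
                            filter_index, statistic_index)

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_long_frame(self, **ids) -> pd.DataFrame:
        fi, si = np.meshgrid(np.arange(1, N_FILTERS + 1), np.arange(1, N_STATISTICS + 1),
                             indexing="ij")
        df = pd.DataFrame({
            "filter_index": fi.ravel(),
            "statistic_index": si.ravel(),
            "value": self.values.ravel(),
        })
        df["missing"] = np.isnan(df["value"])
        for key, val in ids.items():
            df.insert(0, key, val)
        return df

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "FeatureGrid":
        values = np.full((N_FILTERS, N_STATISTICS), np.nan)
        values[df["filter_index"].to_numpy() - 1, df["statistic_index"].to_numpy() - 1] = \
            df["value"].to_numpy()
        return cls(values)


class FeatureComputationError(RuntimeError):
    """A filter or statistic failed; carries the grid cell coordinates."""

    def __init__(self, filter_index: int, statistic_index: Optional[int], cause: Exception):
        self.filter_index = filter_index
        self.statistic_index = statistic_index
        where = f"filter {filter_index}" if statistic_index is None \
            else f"cell ({filter_index}, {statistic_index})"
        super().__init__(f"feature computation failed at {where}: {cause}")


# ---------------------------------------------------------------------------
# core computations


@lru_cache(maxsize=4096)
def _chi2_ppf(q: float, df: int) -> float:
    return float(chi2.ppf(q, df))


def ljung_box_pvalue(values: np.ndarray, lags: int) -> float:
    """Ljung-Box portmanteau p-value for autocorrelation up to ``lags``.

    Q = n(n+2) * sum_k r_k^2 / (n-k), compared against chi-square with
    ``lags`` degrees of freedom.  NaN for a constant series.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if lags < 1 or n <= lags:
        return float("nan")
    x = v - v.mean()
    denom = float(x @ x)
    if denom <= 0.0:
        return float("nan")
    ks = np.arange(1, lags + 1)
    r = np.array([float(x[:-k] @ x[k:]) for k in ks]) / denom
    q = n * (n + 2.0) * float(np.sum(r**2 / (n - ks)))
    return float(chi2.sf(q, lags))


def _statistics_vector(v: np.ndarray, coords: tuple[np.ndarray, ...]) -> np.ndarray:
    """All 23 statistics of a non-empty value vector; NaN where undefined."""
    n = v.size
    if n == 0:
        raise ValueError("statistics require a non-empty value vector")
    out = np.full(N_STATISTICS, np.nan)
    s = np.sort(v)
    mean = float(v.mean())
    out[0] = s[0]
    out[1] = s[-1]
    out[2] = mean
    out[3] = (s[(n - 1) // 2] + s[n // 2]) / 2.0  # midpoint median
    total = float(v.sum())
    out[5] = total

    d = v - mean
    m2 = float(np.mean(d * d))
    if n >= 2:
        var = float(d @ d) / (n - 1)
        out[4] = math.sqrt(var)
        out[20] = var
        out[14] = (n - 1) * var / _chi2_ppf(0.975, n - 1)
        out[15] = (n - 1) * var / _chi2_ppf(0.025, n - 1)
    if m2 > 0.0:
        out[6] = float(np.mean(d**3)) / m2**1.5
        out[16] = float(np.mean(d**4)) / m2**2

    if total != 0.0:
        for axis in range(3):
            out[7 + axis] = float(v @ coords[axis]) / total

    lo, hi = float(s[0]), float(s[-1])
    if hi > lo:
        counts, _ = np.histogram(v, bins=64, range=(lo, hi))
        p = counts[counts > 0] / n
        out[10] = float(-(p * np.log(p)).sum())
        centers = lo + (np.arange(64) + 0.5) * (hi - lo) / 64.0
        out[21] = float(centers[counts == counts.max()].mean())
    else:
        out[10] = 0.0
        out[21] = lo

    out[11] = float(v @ v)

    cent, edges = filterbank.kmeans_1d(v, 5)
    counts5 = np.bincount(np.searchsorted(edges, v), minlength=5)
    out[12] = float(np.count_nonzero(counts5 >= 0.05 * n))
    out[13] = float(cent[int(np.argmax(counts5))])

    t = int(0.05 * n)
    out[17] = float(s[t : n - t].mean())
    out[18] = float(np.abs(d).mean())
    out[19] = math.sqrt(float(v @ v) / n)

    out[22] = ljung_box_pvalue(v, min(10, n // 5))
    return out


def _filtered_inputs(filtered: filterbank.FilteredRegion) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    v = filtered.values[filtered.mask].astype(float)
    coords = tuple(c.astype(float) for c in np.nonzero(filtered.mask))
    return v, coords


def compute_all_statistics(filtered: filterbank.FilteredRegion) -> np.ndarray:
    """Vector of all 23 statistics for one filtered region."""
    v, coords = _filtered_inputs(filtered)
    return _statistics_vector(v, coords)


def compute_statistic(filtered: filterbank.FilteredRegion, spec: StatisticSpec) -> FeatureValue:
    """One secondary feature of a filtered region."""
    if not (1 <= spec.index <= N_STATISTICS):
        raise ValueError(f"statistic index {spec.index} outside 1..{N_STATISTICS}")
    value = compute_all_statistics(filtered)[spec.index - 1]
    return FeatureValue(float(value), filtered.filter_index, spec.index)


def compute_grid(region: RegionExtract) -> FeatureGrid:
    """The full 26 x 23 feature grid (598 cells) for one region."""
    values = np.empty((N_FILTERS, N_STATISTICS))
    for fspec in filterbank.registry():
        try:
            filtered = filterbank.apply_filter(region, fspec)
        except Exception as exc:  # attach the failing cell column
            raise FeatureComputationError(fspec.index, None, exc) from exc
        try:
            values[fspec.index - 1] = compute_all_statistics(filtered)
        except Exception as exc:
            raise FeatureComputationError(fspec.index, None, exc) from exc
    return FeatureGrid(values)
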