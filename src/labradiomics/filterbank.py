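"""The 26 primary radiomic features: image filters applied to a region crop.

Each primary feature is a deterministic transform of a region's bounding-box
crop.  Index 1 is the identity ("No filter"); 2-16 and 25-26 are shape
preserving; 17-24 are the eight first-level sub-bands of a 3-D orthonormal
Haar transform and return half-resolution grids with a correspondingly
downsampled mask.

Filters run on the full crop, with true out-of-mask intensities serving as
context: masking to zero first would create artificial edges that dominate
edge and entropy responses.  Statistics downstream only ever read mask voxels.

All fixed parameters (DCT threshold fraction, entropy bin count, Hessian and
Gaussian sigmas, k-means k, tone-map gain) live in the registry so a run's
exact filter definitions can be archived alongside its results.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import yaml
from scipy import fft as sp_fft
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class FilterSpec:
    """One primary radiomic feature: a named, parameterized image transform."""

    index: int
    name: str
    params: Mapping[str, object] = field(default_factory=dict)


@dataclass
class FilteredRegion:
    """Output grid of one filter, with the mask on which statistics run."""

    values: np.ndarray
    mask: np.ndarray
    filter_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("filtered values and mask shapes differ")
        if not self.mask.any():
            raise ValueError("filtered mask is empty")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError(f"filter {self.filter_index} produced non-finite values on mask")

    def masked_values(self) -> np.ndarray:
        """Mask voxels in raster order (axis 0 slowest)."""
        return self.values[self.mask]


_HAAR_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _build_registry() -> tuple[FilterSpec, ...]:
    specs = [
        FilterSpec(1, "No filter"),
        FilterSpec(2, "FourierDCTFilter", {"threshold_frac": 0.05}),
        FilterSpec(3, "EdgeDetect"),
        FilterSpec(4, "GradientOrientationFilter"),
    ]
    for r in range(1, 7):
        specs.append(FilterSpec(4 + r, f"EntropyFilter (range {r})", {"radius": r, "bins": 32}))
    specs += [
        FilterSpec(11, "LaplacianFilter"),
        FilterSpec(12, "RidgeFilter", {"sigma": 1.0}),
        FilterSpec(13, "LaplacianGaussianFilter", {"sigma": 1.0}),
        FilterSpec(14, "ClusteringComponents", {"k": 3, "max_iter": 100}),
        FilterSpec(15, "MorphologicalComponents", {"connectivity": 26}),
        FilterSpec(16, "MorphologicalBinarize"),
    ]
    for i, band in enumerate(_HAAR_SUBBANDS, start=17):
        specs.append(FilterSpec(i, f"DiscreteWaveletTransform ({i - 16})", {"subband": band}))
    specs += [
        FilterSpec(25, "ImageSaliencyFilter", {"sigma": 3.0}),
        FilterSpec(26, "ColorToneMapping", {"gain": 10.0}),
    ]
    return tuple(specs)


_REGISTRY = _build_registry()


def registry() -> tuple[FilterSpec, ...]:
    """The 26 primary-feature specs, index 1 = "No filter", stable order."""
    return _REGISTRY


def registry_to_yaml(path) -> None:
    """Archive the filter definitions (index, name, params) as YAML."""
    entries = [{"index": s.index, "name": s.name, "params": dict(s.params)} for s in _REGISTRY]
    with open(path, "w") as fh:
        yaml.safe_dump({"primary_features": entries}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# helpers


def _gradients(crop: np.ndarray) -> list[np.ndarray]:
    # np.gradient needs >= 2 samples per axis; degenerate axes get zero slope
    out = []
    for ax in range(3):
        if crop.shape[ax] >= 2:
            out.append(np.gradient(crop, axis=ax))
        else:
            out.append(np.zeros_like(crop))
    return out


def _otsu_binary(crop: np.ndarray) -> np.ndarray:
    if crop.max() == crop.min():
        return np.zeros_like(crop, dtype=bool)
    # flatten so skimage does not mistake a 3-voxel-wide crop for RGB
    return crop > threshold_otsu(crop.ravel())


def _mask_range(crop: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    v = crop[mask]
    return float(v.min()), float(v.max())


def kmeans_1d(values: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D Lloyd k-means with quantile initialization.

    Centroids start at the (2i+1)/(2k) quantiles and stay sorted, so cluster
    index orders by value.  Fewer than k distinct values leave duplicate
    (degenerate) centroids, which is allowed.  Returns (centroids, edges);
    assignment of any value is ``np.searchsorted(edges, value)``.
    """
    v = np.asarray(values, dtype=float).ravel()
    qs = [(2 * i + 1) / (2 * k) for i in range(k)]
    cent = np.quantile(v, qs)
    for _ in range(max_iter):
        edges = (cent[:-1] + cent[1:]) / 2.0
        lab = np.searchsorted(edges, v)
        cnt = np.bincount(lab, minlength=k)
        sums = np.bincount(lab, weights=v, minlength=k)
        new = np.where(cnt > 0, sums / np.maximum(cnt, 1), cent)
        new = np.sort(new)
        if np.array_equal(new, cent):
            break
        cent = new
    edges = (cent[:-1] + cent[1:]) / 2.0
    return cent, edges


# ---------------------------------------------------------------------------
# Haar transform


def _haar_1d(x: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Single-level orthonormal Haar split along one axis.

    Pairs map to (sum, difference)/sqrt(2); an odd tail sample passes through
    unchanged into the low band (zero detail), keeping the transform
    orthonormal — and hence energy conserving — for every length.
    """
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    m = n // 2
    ev, od = x[0 : 2 * m : 2], x[1 : 2 * m : 2]
    lo = (ev + od) / _SQRT2
    hi = (ev - od) / _SQRT2
    if n % 2:
        lo = np.concatenate([lo, x[-1:]], axis=0)
        hi = np.concatenate([hi, np.zeros_like(x[-1:])], axis=0)
    return np.moveaxis(lo, 0, axis), np.moveaxis(hi, 0, axis)


def haar_subband(crop: np.ndarray, code: str) -> np.ndarray:
    """One sub-band of the single-level 3-D Haar transform.

    ``code`` is three letters, one per grid axis in order, L = low pass,
    H = high pass.
    """
    out = crop
    for axis, letter in enumerate(code):
        lo, hi = _haar_1d(out, axis)
        out = lo if letter == "L" else hi
    return out


def haar_subbands(crop: np.ndarray) -> dict[str, np.ndarray]:
    """All eight sub-bands, keyed LLL..HHH."""
    bands = {"": np.asarray(crop, dtype=float)}
    for axis in range(3):
        nxt: dict[str, np.ndarray] = {}
        for key, val in bands.items():
            lo, hi = _haar_1d(val, axis)
            nxt[key + "L"] = lo
            nxt[key + "H"] = hi
        bands = nxt
    return bands


def downsample_mask(mask: np.ndarray) -> np.ndarray:
    """2x2x2 majority-vote mask downsampling (ties -> true).

    The vote runs over the in-crop positions of each block (boundary blocks
    may hold fewer than 8).  If a sparse mask would empty out entirely, fall
    back to marking every block containing at least one mask voxel, so the
    result is never empty for a non-empty input.
    """
    shape = mask.shape
    out_shape = tuple(-(-s // 2) for s in shape)
    pad = tuple((0, 2 * o - s) for s, o in zip(shape, out_shape))
    t = np.pad(mask, pad).astype(np.int16)
    present = np.pad(np.ones(shape, dtype=np.int16), pad)
    r = (out_shape[0], 2, out_shape[1], 2, out_shape[2], 2)
    t_cnt = t.reshape(r).sum(axis=(1, 3, 5))
    p_cnt = present.reshape(r).sum(axis=(1, 3, 5))
    out = (2 * t_cnt >= p_cnt) & (p_cnt > 0)
    if not out.any():
        out = t_cnt > 0
    return out


# ---------------------------------------------------------------------------
# filter implementations (each returns (values, mask-or-None))


def _f_identity(crop, mask, params):
    return crop.copy(), None


def _f_dct(crop, mask, params):
    coeff = sp_fft.dctn(crop, type=2, norm="ortho")
    peak = np.abs(coeff).max()
    if peak > 0:
        coeff[np.abs(coeff) < params["threshold_frac"] * peak] = 0.0
    return sp_fft.idctn(coeff, type=2, norm="ortho"), None


def _f_edge(crop, mask, params):
    g = _gradients(crop)
    mag = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
    return _otsu_binary(mag).astype(float), None


def _f_orientation(crop, mask, params):
    g = _gradients(crop)
    theta = np.arctan2(g[1], g[0])  # azimuth of the gradient in the (x, y) plane
    return (theta + np.pi) / (2.0 * np.pi), None


def _f_entropy(crop, mask, params):
    lo, hi = _mask_range(crop, mask)
    if hi <= lo:
        return np.zeros_like(crop), None
    bins = params["bins"]
    q = np.clip(((crop - lo) / (hi - lo) * bins).astype(np.int32), 0, bins - 1)
    size = 2 * params["radius"] + 1
    ent = np.zeros(crop.shape, dtype=np.float64)
    for b in range(bins):
        p = ndi.uniform_filter((q == b).astype(np.float64), size=size, mode="reflect")
        nz = p > 1e-12
        ent[nz] -= p[nz] * np.log(p[nz])
    return ent, None


_LAP_KERNEL = np.zeros((3, 3, 3))
_LAP_KERNEL[1, 1, 1] = -6.0
for _off in ((0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)):
    _LAP_KERNEL[_off] = 1.0


def _f_laplacian(crop, mask, params):
    return ndi.convolve(crop, _LAP_KERNEL, mode="reflect"), None


def _f_ridge(crop, mask, params):
    if min(crop.shape) < 2:
        return np.zeros_like(crop), None
    H = hessian_matrix(crop, sigma=params["sigma"], mode="reflect", use_gaussian_derivatives=False)
    eig = hessian_matrix_eigvals(H)  # sorted descending; eig[-1] most negative
    return np.maximum(0.0, -eig[-1]), None


def _f_log(crop, mask, params):
    return ndi.gaussian_laplace(crop, sigma=params["sigma"], mode="reflect"), None


def _f_clustering(crop, mask, params):
    k = params["k"]
    _, edges = kmeans_1d(crop[mask], k, params["max_iter"])
    labels = np.searchsorted(edges, crop)
    return labels / (k - 1), None


def _f_components(crop, mask, params):
    binary = _otsu_binary(crop)
    lab = cc_label(binary, connectivity=3)
    n = int(lab.max())
    if n == 0:
        return np.zeros_like(crop), None
    sizes = np.bincount(lab.ravel())
    # rank 1 = largest component; ties broken by label id for determinism
    order = sorted(range(1, n + 1), key=lambda c: (-sizes[c], c))
    rank = np.zeros(n + 1, dtype=float)
    for r, c in enumerate(order, start=1):
        rank[c] = r
    return rank[lab] / n, None


def _f_binarize(crop, mask, params):
    return _otsu_binary(crop).astype(float), None


def _f_haar(crop, mask, params):
    return haar_subband(crop, params["subband"]), downsample_mask(mask)


def _f_saliency(crop, mask, params):
    return np.abs(crop - ndi.gaussian_filter(crop, sigma=params["sigma"], mode="reflect")), None


def _f_tonemap(crop, mask, params):
    lo, hi = _mask_range(crop, mask)
    if hi <= lo:
        return np.zeros_like(crop), None
    gain = params["gain"]
    scaled = np.clip((crop - lo) / (hi - lo), 0.0, 1.0)
    return np.log1p(gain * scaled) / np.log1p(gain), None


_DISPATCH: dict[int, Callable] = {
    1: _f_identity,
    2: _f_dct,
    3: _f_edge,
    4: _f_orientation,
    11: _f_laplacian,
    12: _f_ridge,
    13: _f_log,
    14: _f_clustering,
    15: _f_components,
    16: _f_binarize,
    25: _f_saliency,
    26: _f_tonemap,
}
for _i in range(5, 11):
    _DISPATCH[_i] = _f_entropy
for _i in range(17, 25):
    _DISPATCH[_i] = _f_haar


def apply_filter(region, spec: FilterSpec) -> FilteredRegion:
    """Apply one primary-feature filter to a region's crop.

    Shape-preserving filters reuse the region mask; Haar sub-bands (17-24)
    return half-resolution grids with a majority-vote downsampled mask.
    """
    if not (1 <= spec.index <= 26):
        raise ValueError(f"filter index {spec.index} outside 1..26")
    crop = np.asarray(region.crop, dtype=float)
    values, new_mask = _DISPATCH[spec.index](crop, region.mask, spec.params)
    mask = region.mask if new_mask is None else new_mask
    return FilteredRegion(values, mask, spec.index)
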