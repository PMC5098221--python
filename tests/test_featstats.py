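import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labradiomics import filterbank
from labradiomics.featstats import (
    FeatureGrid,
    compute_all_statistics,
    compute_grid,
    compute_statistic,
    ljung_box_pvalue,
    registry,
)
from labradiomics.filterbank import FilteredRegion
from labradiomics.volio import RegionExtract


def _filtered(values, mask=None):
    values = np.asarray(values, float)
    if mask is None:
        mask = np.ones_like(values, bool)
    return FilteredRegion(values, mask, 1)


def _stats_of(seq):
    v = np.asarray(seq, float).reshape(-1, 1, 1)
    return compute_all_statistics(_filtered(v))


class TestRegistry:
    def test_has_23_entries_in_order(self):
        specs = registry()
        assert len(specs) == 23
        assert [s.index for s in specs] == list(range(1, 24))
        assert specs[0].name == "MinIntensity"
        assert specs[22].name == "AutocorrelationTest"


class TestHandComputedValues:
    def test_one_two_three(self):
        out = _stats_of([1, 2, 3])
        assert out[2] == pytest.approx(2.0)      # mean
        assert out[5] == pytest.approx(6.0)      # total
        assert out[20] == pytest.approx(1.0)     # variance (n-1)
        assert out[19] == pytest.approx(math.sqrt(14 / 3))  # RMS
        assert out[0] == 1.0 and out[1] == 3.0
        assert out[3] == 2.0                     # median

    def test_symmetric_sample_has_zero_skew(self):
        out = _stats_of([1, 2, 2, 3])
        assert out[6] == pytest.approx(0.0, abs=1e-12)

    def test_constant_degeneracies(self):
        out = _stats_of([4.0] * 20)
        assert out[10] == 0.0                    # entropy
        assert math.isnan(out[22])               # autocorrelation test missing
        assert math.isnan(out[6]) and math.isnan(out[16])  # skew / kurtosis
        assert out[21] == 4.0                    # commonest: the constant itself

    def test_kurtosis_of_normal_near_three(self):
        v = np.random.default_rng(5).standard_normal(200_000)
        out = _stats_of(v)
        assert out[16] == pytest.approx(3.0, abs=0.05)

    def test_zero_sum_weights_make_centroid_missing(self):
        out = _stats_of([-1.0, 1.0])
        assert math.isnan(out[7]) and math.isnan(out[8]) and math.isnan(out[9])

    def test_trimmed_mean_drops_five_percent_tails(self):
        v = list(range(1, 41)) + [1000.0]  # n=41, floor(0.05*41)=2 per tail
        out = _stats_of(v)
        expected = np.mean(sorted(v)[2:-2])
        assert out[17] == pytest.approx(expected)


class TestVarianceCI:
    def test_matches_chi_square_quantile_oracle(self):
        """Independent oracle: recompute the bounds from scipy's quantile function."""
        from scipy.stats import chi2

        v = np.random.default_rng(1).standard_normal(10_000)
        out = _stats_of(v)
        n = v.size
        s2 = v.var(ddof=1)
        lo = (n - 1) * s2 / chi2.ppf(0.975, n - 1)
        hi = (n - 1) * s2 / chi2.ppf(0.025, n - 1)
        assert out[14] == pytest.approx(lo, abs=1e-10)
        assert out[15] == pytest.approx(hi, abs=1e-10)
        assert out[14] < s2 < out[15]

    def test_missing_below_two_samples(self):
        out = _stats_of([3.0])
        assert math.isnan(out[14]) and math.isnan(out[15])
        assert math.isnan(out[4]) and math.isnan(out[20])


class TestLjungBox:
    def test_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import acorr_ljungbox

        rng = np.random.default_rng(2)
        for v in (rng.standard_normal(200), np.sin(np.arange(150) / 3) + rng.standard_normal(150) * 0.1):
            m = min(10, v.size // 5)
            ours = ljung_box_pvalue(v, m)
            theirs = float(acorr_ljungbox(v, lags=[m]).lb_pvalue.iloc[0])
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_strong_autocorrelation_detected(self):
        v = np.repeat(np.random.default_rng(3).standard_normal(30), 10)
        assert ljung_box_pvalue(v, 10) < 1e-6


class TestScaleEquivariance:
    SCALE_BY_C = [1, 2, 3, 4, 5, 6, 14, 18, 19, 20, 22]
    SCALE_BY_C2 = [12, 15, 16, 21]
    INVARIANT = [7, 8, 9, 10, 11, 17, 23]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), c=st.floats(0.1, 10.0))
    def test_ledger(self, seed, c):
        rng = np.random.default_rng(seed)
        v = rng.normal(10.0, 3.0, size=(5, 4, 3))
        base = compute_all_statistics(_filtered(v))
        scaled = compute_all_statistics(_filtered(c * v))
        for idx in self.SCALE_BY_C:
            assert scaled[idx - 1] == pytest.approx(c * base[idx - 1], rel=1e-8), idx
        for idx in self.SCALE_BY_C2:
            assert scaled[idx - 1] == pytest.approx(c**2 * base[idx - 1], rel=1e-8), idx
        for idx in self.INVARIANT:
            if math.isnan(base[idx - 1]):
                assert math.isnan(scaled[idx - 1])
            else:
                assert scaled[idx - 1] == pytest.approx(base[idx - 1], rel=1e-7, abs=1e-9), idx


class TestCentroid:
    def test_constant_symmetric_region_centroid_is_geometric_center(self):
        v = np.full((7, 5, 9), 2.0)
        out = compute_all_statistics(_filtered(v))
        assert out[7] == pytest.approx(3.0, abs=1e-9)
        assert out[8] == pytest.approx(2.0, abs=1e-9)
        assert out[9] == pytest.approx(4.0, abs=1e-9)


class TestGrid:
    def test_grid_has_598_unique_cells(self, random_region):
        grid = compute_grid(random_region)
        assert grid.n_cells == 598
        assert grid.values.shape == (26, 23)

    def test_constant_region_no_filter_sd_zero(self):
        region = RegionExtract(np.full((6, 6, 6), 9.0), np.ones((6, 6, 6), bool),
                               (0, 0, 0), (1, 1, 1))
        grid = compute_grid(region)
        assert grid.cell(1, 5).value == 0.0

    def test_cells_equal_one_off_composition(self, random_region):
        """Compositional oracle: grid cells == standalone filter+statistic calls."""
        grid = compute_grid(random_region)
        rng = np.random.default_rng(0)
        for fi, si in zip(rng.integers(1, 27, 8), rng.integers(1, 24, 8)):
            filtered = filterbank.apply_filter(random_region, filterbank.registry()[fi - 1])
            one = compute_statistic(filtered, registry()[si - 1])
            cell = grid.cell(fi, si)
            if one.missing:
                assert cell.missing
            else:
                assert cell.value == pytest.approx(one.value, rel=1e-12)

    def test_long_frame_roundtrip(self, random_region):
        grid = compute_grid(random_region)
        df = grid.to_long_frame(subject_id="s1")
        assert len(df) == 598
        back = FeatureGrid.from_long_frame(df)
        assert np.array_equal(np.isnan(back.values), np.isnan(grid.values))
        assert np.allclose(back.values[~np.isnan(grid.values)],
                           grid.values[~np.isnan(grid.values)])
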