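import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from labradiomics.inference import (
    SignificanceGrid,
    build_significance_grid,
    compare_morphometry,
    count_significant,
    derive_cell_seed,
    detect_bands,
    permutation_test,
)
from labradiomics.pipeline import CohortStore


def brute_force_exact_p(a, b):
    """Independent oracle: enumerate every label assignment with itertools."""
    pooled = list(a) + list(b)
    na = len(a)
    t_obs = abs(np.mean(a) - np.mean(b))
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(np.mean(ga) - np.mean(gb)) >= t_obs - 1e-12:
            hits += 1
    return hits / total


def _grid_from_p(p, alpha=0.05):
    return SignificanceGrid(p, alpha=alpha, n_perm=100, seed=0)


class TestPermutationTest:
    def test_identical_constant_groups_give_p_one(self):
        assert permutation_test([5.0] * 4, [5.0] * 4, n_perm=100, seed=0) == 1.0

    def test_separated_groups_exact_enumeration(self):
        # both fully-separated assignments are the only ones as extreme
        p = permutation_test([10, 11, 12], [0, 1, 2], n_perm=10_000, seed=0)
        assert p == pytest.approx(2 / comb(6, 3))
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 4), rng.normal(0.8, 1, 5)
        ours = permutation_test(a, b, n_perm=10_000, seed=0)
        assert ours == pytest.approx(brute_force_exact_p(a, b), abs=1e-12)

    def test_sampled_close_to_exact_for_small_groups(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 6), rng.normal(1.0, 1, 6)
        exact = permutation_test(a, b, n_perm=comb(12, 6), seed=0)  # exhaustive
        sampled = permutation_test(a, b, n_perm=100_000, seed=3)
        assert comb(12, 6) == 924
        assert sampled == pytest.approx(exact, abs=0.01)

    def test_small_group_after_missing_removal_is_missing(self):
        p = permutation_test([1.0, np.nan, np.nan], [0.0, 1.0, 2.0], n_perm=100)
        assert np.isnan(p)

    def test_monotone_in_shift(self):
        rng = np.random.default_rng(1)
        b = rng.normal(0, 1, 12)
        a0 = rng.normal(0, 1, 12)
        ps = [permutation_test(a0 + shift, b, n_perm=2000, seed=5)
              for shift in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_null_p_values_are_valid(self):
        """P(p <= t) <= t + enumeration granularity under the null."""
        rng = np.random.default_rng(42)
        n_feat = 400
        ps = np.array([permutation_test(rng.normal(0, 1, 8), rng.normal(0, 1, 8),
                                        n_perm=400, seed=int(s))
                       for s in rng.integers(0, 2**31, n_feat)])
        for t in (0.01, 0.05, 0.1):
            rate = float(np.mean(ps <= t))
            se = np.sqrt(t * (1 - t) / n_feat)
            assert rate <= t + 1 / 401 + 3 * se


class TestCounting:
    def test_all_ones_and_all_small(self):
        assert count_significant(_grid_from_p(np.ones((26, 23)))) == 0
        assert count_significant(_grid_from_p(np.full((26, 23), 0.01))) == 598

    def test_random_grid_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        p = rng.random((26, 23))
        p[rng.random((26, 23)) < 0.05] = np.nan
        grid = _grid_from_p(p)
        brute = sum(1 for fi in range(26) for si in range(23)
                    if not np.isnan(p[fi, si]) and p[fi, si] < 0.05)
        assert count_significant(grid) == brute


class TestBands:
    def test_three_in_one_statistic_row(self):
        p = np.ones((26, 23))
        p[[2, 10, 20], 8] = 0.01  # statistic row 9
        report = detect_bands(_grid_from_p(p))
        assert report.row_bands == [9]
        assert report.column_bands == []
        assert report.n_bands == 1

    def test_two_significant_cells_no_band(self):
        p = np.ones((26, 23))
        p[0, 0] = p[13, 12] = 0.001
        assert detect_bands(_grid_from_p(p)).n_bands == 0

    def test_column_band_in_filter(self):
        p = np.ones((26, 23))
        p[11, [0, 5, 9, 14]] = 0.02  # filter column 12
        report = detect_bands(_grid_from_p(p))
        assert report.column_bands == [12]

    def test_random_patterns_match_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            p = rng.random((26, 23)) ** (1 + 3 * rng.random())
            report = detect_bands(_grid_from_p(p))
            sig = p < 0.05
            rows = [si + 1 for si in range(23) if sig[:, si].sum() >= 3]
            cols = [fi + 1 for fi in range(26) if sig[fi, :].sum() >= 3]
            assert report.row_bands == rows
            assert report.column_bands == cols
            assert report.n_significant == int(sig.sum())


def _store_from_cells(case_grids, control_grids, label=1):
    store = CohortStore()
    for i, g in enumerate(case_grids):
        sid = f"case_{i}"
        store.groups[sid] = "case"
        store.normalized[(sid, label)] = g
    for i, g in enumerate(control_grids):
        sid = f"control_{i}"
        store.groups[sid] = "control"
        store.normalized[(sid, label)] = g
    return store


class TestSignificanceGrid:
    def test_cell_reproducible_by_standalone_call(self):
        rng = np.random.default_rng(0)
        store = _store_from_cells([rng.normal(size=(26, 23)) for _ in range(6)],
                                  [rng.normal(size=(26, 23)) for _ in range(6)])
        grid = build_significance_grid(store, 1, n_perm=200, seed=17)
        for fi, si in [(1, 1), (12, 9), (26, 23)]:
            a, b = store.cell(1, fi, si)
            p = permutation_test(a, b, n_perm=200,
                                 seed=derive_cell_seed(17, fi, si))
            assert grid.p[fi - 1, si - 1] == pytest.approx(p, abs=1e-15)

    def test_absent_substructure_fails(self):
        rng = np.random.default_rng(0)
        store = _store_from_cells([rng.normal(size=(26, 23))] * 2,
                                  [rng.normal(size=(26, 23))] * 2)
        with pytest.raises(ValueError, match="absent"):
            build_significance_grid(store, 5, n_perm=50)

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(4)
        grids = [rng.normal(size=(26, 23)) for _ in range(4)]
        store = _store_from_cells(grids, grids)  # element-for-element identical
        grid = build_significance_grid(store, 1, n_perm=200, seed=2)
        assert count_significant(grid) == 0


class TestMorphometryComparison:
    @staticmethod
    def _store_with_morph(case_vols, control_vols):
        rows = []
        for grp, vols in (("case", case_vols), ("control", control_vols)):
            for i, v in enumerate(vols):
                for label in list(range(1, 8)) + [0]:
                    rows.append({"subject_id": f"{grp}_{i}", "group": grp,
                                 "label": label, "substructure": str(label),
                                 "surface_area_mm2": 6.0 * v ** (2 / 3),
                                 "volume_mm3": v})
        store = CohortStore()
        for grp, vols in (("case", case_vols), ("control", control_vols)):
            for i in range(len(vols)):
                store.groups[f"{grp}_{i}"] = grp
        store.morphometry = pd.DataFrame(rows)
        return store

    def test_sixteen_tests_null_near_one(self):
        rng = np.random.default_rng(0)
        vols = rng.normal(100, 5, 10)
        store = self._store_with_morph(vols, vols)
        df = compare_morphometry(store, n_perm=200, seed=1)
        assert len(df) == 16
        assert (df["p_value"] > 0.5).all()

    def test_inflated_case_volumes_detected(self):
        rng = np.random.default_rng(1)
        control = rng.normal(100, 5, 10)
        case = rng.normal(150, 5, 10)  # 50% larger structures
        df = compare_morphometry(self._store_with_morph(case, control),
                                 n_perm=2000, seed=2)
        vol_p = df.loc[df["measure"] == "volume_mm3", "p_value"]
        assert (vol_p < 0.05).all()
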