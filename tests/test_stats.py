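"""Permutation Mann-Whitney machinery, Fisher combination, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import random_feature_table
from meaphen.stats import (
    StatsParams,
    combine_divs,
    compare_drug_response,
    drug_ratio,
    fisher_combine,
    genotype_comparison,
    mwu_p,
    normalize_to_wt,
    permuted_mwu,
)
from meaphen.types import FeatureTable


class TestMWU:
    def test_matches_scipy_exact_small_groups(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 8)))
            y = rng.normal(size=int(rng.integers(3, 8)))
            _, p = mwu_p(x, y)
            want = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(want, rel=1e-12)

    def test_matches_scipy_asymptotic_large_groups(self, rng):
        for _ in range(10):
            x = rng.normal(size=24)
            y = rng.normal(0.3, 1.0, size=24)
            _, p = mwu_p(x, y)
            want = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert p == pytest.approx(want, rel=1e-9)

    def test_tie_correction_matches_scipy(self, rng):
        x = rng.integers(0, 4, size=20).astype(float)
        y = rng.integers(0, 4, size=20).astype(float)
        _, p = mwu_p(x, y)
        want = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(want, rel=1e-9)


class TestPermutedMWU:
    def test_identical_constant_groups_give_p_one(self):
        values = np.full(12, 3.7)
        labels = np.array(["WT"] * 6 + ["K78R"] * 6)
        _, _, p_perm = permuted_mwu(values, labels, n_perm=200, seed=0)
        assert p_perm == 1.0

    def test_exhaustive_small_example(self):
        # 3v3 separated groups: most extreme two-sided exact p is 0.1, and the
        # 20 label assignments are enumerated rather than sampled
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        _, p_raw, p_perm = permuted_mwu(values, labels, n_perm=1000, seed=0)
        assert p_raw == pytest.approx(0.1)
        assert p_perm == pytest.approx(2 / 20)  # both extreme assignments tie

    def test_missing_values_dropped_with_labels(self, rng):
        values = np.array([1.0, 2.0, np.nan, 4.0, 10.0, 11.0, 12.0, np.nan])
        labels = np.array(["A"] * 4 + ["B"] * 4)
        u, p_raw, p_perm = permuted_mwu(values, labels, n_perm=100, seed=1)
        assert np.isfinite(p_perm)

    def test_deterministic_given_seed(self, rng):
        values = rng.normal(size=30)
        labels = np.array(["A"] * 15 + ["B"] * 15)
        out1 = permuted_mwu(values, labels, n_perm=500, seed=42)
        out2 = permuted_mwu(values, labels, n_perm=500, seed=42)
        assert out1 == out2

    def test_group_too_small_is_error(self):
        with pytest.raises(ValueError):
            permuted_mwu(np.array([1.0, 2.0, 3.0]), np.array(["A", "B", "B"]))

    def test_exhaustive_agrees_with_sampled(self, rng):
        """Enumeration and sampling estimate the same permutation p."""
        values = rng.normal(size=10)
        values[:5] += 1.2
        labels = np.array(["A"] * 5 + ["B"] * 5)
        # C(10,5) = 252 <= 1000 -> exhaustive
        _, _, p_exh = permuted_mwu(values, labels, n_perm=1000, seed=0)
        # force sampling by lowering n_perm below 252
        _, _, p_smp = permuted_mwu(values, labels, n_perm=199, seed=0)
        se = np.sqrt(p_exh * (1 - p_exh) / 199)
        assert abs(p_smp - p_exh) < 4 * se + 1e-6

    def test_null_uniformity_ks(self, rng):
        """Permutation p-values are approximately uniform under the null."""
        pvals = []
        labels = np.array(["A"] * 12 + ["B"] * 12)
        for k in range(300):
            values = rng.normal(size=24)
            _, _, p_perm = permuted_mwu(values, labels, n_perm=199, seed=int(rng.integers(2**31)))
            pvals.append(p_perm)
        stat = sps.kstest(pvals, "uniform").pvalue
        assert stat > 0.01


class TestFisher:
    def test_single_p_identity(self):
        assert fisher_combine([0.2]) == pytest.approx(0.2, rel=1e-9)

    def test_closed_form_two_values(self):
        # X = -4 ln 0.05 = 11.983; p = e^(-X/2)(1 + X/2)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.01747, abs=1e-4)

    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        ps=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=6),
        idx=st.integers(min_value=0, max_value=5),
        factor=st.floats(min_value=0.1, max_value=0.999),
    )
    def test_monotone_in_every_input(self, ps, idx, factor):
        idx = idx % len(ps)
        smaller = list(ps)
        smaller[idx] = ps[idx] * factor
        assert fisher_combine(smaller) <= fisher_combine(ps) + 1e-12


class TestNormalization:
    def test_worked_example(self):
        table = FeatureTable.from_rows(
            [
                {"plate": "P1", "well": "A1", "div": 15, "f": 2.0},
                {"plate": "P1", "well": "A2", "div": 15, "f": 4.0},
                {"plate": "P1", "well": "A3", "div": 15, "f": 6.0},
            ]
        )
        pmap = _pmap(["A1", "A2", "A3"], ["WT", "WT", "K78R"])
        norm = normalize_to_wt(table, pmap)
        got = norm.data["f"].to_numpy()
        np.testing.assert_allclose(got, [2 / 3, 4 / 3, 2.0])
        assert norm.normalized

    def test_wt_mean_exactly_one(self, rng):
        table = random_feature_table(
            rng, wells=[f"A{k}" for k in range(1, 9)], divs=(15, 18, 21),
            features=("f1", "f2", "f3"), missing_frac=0.1,
        )
        pmap = _pmap(
            [f"A{k}" for k in range(1, 9)], ["WT"] * 4 + ["K78R"] * 4
        )
        norm = normalize_to_wt(table, pmap)
        wt_wells = {f"A{k}" for k in range(1, 5)}
        for (plate, div), sub in norm.data.groupby(level=["plate", "div"]):
            wt = sub[sub.index.get_level_values("well").isin(wt_wells)]
            for feat in wt.columns:
                m = wt[feat].mean(skipna=True)
                if not np.isnan(m):
                    assert m == pytest.approx(1.0, abs=1e-12)

    def test_all_equal_wt_values_become_one(self):
        table = FeatureTable.from_rows(
            [
                {"plate": "P1", "well": "A1", "div": 15, "f": 5.0},
                {"plate": "P1", "well": "A2", "div": 15, "f": 5.0},
            ]
        )
        norm = normalize_to_wt(table, _pmap(["A1", "A2"], ["WT", "WT"]))
        np.testing.assert_allclose(norm.data["f"].to_numpy(), [1.0, 1.0])

    def test_zero_wt_mean_gives_missing_with_warning(self):
        table = FeatureTable.from_rows(
            [
                {"plate": "P1", "well": "A1", "div": 15, "f": 0.0},
                {"plate": "P1", "well": "A2", "div": 15, "f": 3.0},
            ]
        )
        with pytest.warns(UserWarning, match="WT mean"):
            norm = normalize_to_wt(table, _pmap(["A1", "A2"], ["WT", "K78R"]))
        assert norm.data["f"].isna().all()


class TestDrugRatio:
    def test_equal_tables_give_ones(self, rng):
        t = random_feature_table(rng)
        ratios = drug_ratio(t, t)
        np.testing.assert_allclose(ratios.data.to_numpy(), 1.0)

    def test_simple_ratio(self):
        base = FeatureTable.from_rows(
            [{"plate": "P1", "well": "A1", "div": 20, "f": 4.0}]
        )
        drug = FeatureTable.from_rows(
            [{"plate": "P1", "well": "A1", "div": 20, "f": 2.0}]
        )
        assert drug_ratio(base, drug).data["f"].iloc[0] == pytest.approx(0.5)

    def test_zero_baseline_missing(self):
        base = FeatureTable.from_rows(
            [{"plate": "P1", "well": "A1", "div": 20, "f": 0.0}]
        )
        drug = FeatureTable.from_rows(
            [{"plate": "P1", "well": "A1", "div": 20, "f": 2.0}]
        )
        assert np.isnan(drug_ratio(base, drug).data["f"].iloc[0])

    def test_mismatched_wells_error(self):
        base = FeatureTable.from_rows(
            [{"plate": "P1", "well": "A1", "div": 20, "f": 1.0}]
        )
        drug = FeatureTable.from_rows(
            [{"plate": "P1", "well": "A2", "div": 20, "f": 1.0}]
        )
        with pytest.raises(ValueError, match="different wells"):
            drug_ratio(base, drug)


class TestBonferroni:
    def test_single_feature_unchanged(self, rng):
        out = _drug_comparison(rng, features=["f1"])
        assert out["p_adjusted"].iloc[0] == pytest.approx(out["p_perm"].iloc[0])

    def test_multiplied_by_feature_count_and_capped(self, rng):
        out = _drug_comparison(rng, features=["f1", "f2"])
        for _, row in out.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_perm"] * 2))


class TestCombineDIVs:
    def test_well_mean_collapses_divs(self, rng):
        table = random_feature_table(rng, divs=(15, 18))
        per_well = combine_divs(table, mode="well_mean")
        assert len(per_well) == 4
        want = table.data.groupby(level=["plate", "well"])["f1"].mean()
        got = per_well.set_index(["plate", "well"])["f1"]
        pd.testing.assert_series_equal(got, want, check_names=False)

    def test_pool_keeps_all_observations(self, rng):
        table = random_feature_table(rng, divs=(15, 18))
        assert len(combine_divs(table, mode="pool")) == 8

    def test_div_selection(self, rng):
        table = random_feature_table(rng, divs=(15, 18, 21))
        pooled = combine_divs(table, divs=[15, 18], mode="pool")
        assert len(pooled) == 8


def _pmap(wells, genotypes):
    from meaphen.types import PlateMap

    return PlateMap(
        table=pd.DataFrame(
            {
                "well": wells,
                "plate": "P1",
                "genotype": genotypes,
                "drug": "none",
                "dose_mM": 0.0,
                "condition": "baseline",
            }
        )
    )


def _drug_comparison(rng, features):
    wells = [f"A{k}" for k in range(1, 13)]
    table = random_feature_table(rng, wells=wells, divs=(20,), features=features)
    pmap = _pmap(wells, ["WT"] * 6 + ["K78R"] * 6)
    return compare_drug_response(table, pmap, features=features,
                                 params=StatsParams(n_perm=200), seed=3)
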