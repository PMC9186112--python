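import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scipy.stats as sps

from _dip_oracle import dip_oracle
from spinemorph.population_stats import (HistogramSpec,
                                         compare_populations, density_histogram,
                                         dip_statistic, dip_test, dip_test_nd,
                                         mann_whitney, significance_stars,
                                         spearman_with_wald)
from spinemorph.synthetic_spines import make_bimodal_population


class TestDensityHistogram:
    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=1,
                    max_size=300),
           st.integers(min_value=1, max_value=60),
           st.sampled_from(["log", "linear"]))
    @settings(max_examples=60, deadline=None)
    def test_integral_is_one(self, xs, n_bins, scale):
        edges, dens = density_histogram(np.array(xs),
                                        HistogramSpec(scale=scale, n_bins=n_bins))
        assert (dens * np.diff(edges)).sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_value(self):
        edges, dens = density_histogram([2.0], HistogramSpec(n_bins=5))
        occupied = dens > 0
        assert occupied.sum() == 1
        assert dens[occupied][0] == pytest.approx(
            1.0 / np.diff(edges)[occupied][0])

    def test_doubling_counts_leaves_density(self):
        x = np.random.default_rng(0).lognormal(0, 1, 400)
        spec = HistogramSpec(n_bins=20)
        _, d1 = density_histogram(x, spec)
        _, d2 = density_histogram(np.concatenate([x, x]), spec)
        np.testing.assert_allclose(d1, d2, rtol=1e-9)

    def test_log_scale_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            density_histogram([-1.0, 2.0], HistogramSpec(scale="log"))


class TestMannWhitney:
    def test_worked_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_scipy_no_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            nx, ny = rng.integers(2, 9, 2)
            x = rng.normal(0, 1, nx)
            y = rng.normal(0.5, 1, ny)
            mine = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)
            assert mine.statistic == pytest.approx(ref.statistic)

    def test_exact_with_ties_matches_permutation(self):
        rng = np.random.default_rng(4)
        for _ in range(8):
            x = rng.integers(0, 4, 5).astype(float)
            y = rng.integers(0, 4, 5).astype(float)
            mine = mann_whitney(x, y)

            def stat(a, b):
                return sps.mannwhitneyu(a, b, alternative="two-sided").statistic

            ref = sps.permutation_test(
                (x, y), stat, permutation_type="independent", n_resamples=np.inf,
                alternative="two-sided")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_vs_asymptotic_agree(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.8, 1, 8)
        exact = mann_whitney(x, y)                      # 16 <= threshold
        approx = mann_whitney(x, y, exact_max_n=2)      # force normal branch
        assert abs(exact.p_value - approx.p_value) < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestDipStatistic:
    def test_two_distinct_points(self):
        assert dip_statistic([0.0, 1.0]) == pytest.approx(0.25)

    def test_range_bounds(self):
        rng = np.random.default_rng(0)
        for n in (5, 20, 100):
            x = rng.normal(0, 1, n)
            d = dip_statistic(x)
            assert 1 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12

    def test_equispaced_attains_lower_bound(self):
        n = 1000
        assert dip_statistic(np.arange(n) / n) == pytest.approx(1 / (2 * n))

    def test_matches_oracle_n_le_8(self):
        rng = np.random.default_rng(11)
        for trial in range(60):
            n = int(rng.integers(2, 9))
            if trial % 3 == 0:
                x = rng.integers(0, 3, n).astype(float)   # ties
            else:
                x = rng.normal(0, 1, n)
            assert dip_statistic(x) == pytest.approx(dip_oracle(x), abs=1e-10)

    def test_matches_oracle_continuous_larger_n(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.uniform(0, 1, int(rng.integers(10, 25)))
            assert dip_statistic(x) == pytest.approx(dip_oracle(x), abs=1e-10)

    def test_affine_invariance(self):
        x = np.random.default_rng(13).normal(0, 1, 200)
        assert dip_statistic(3.5 * x - 7.0) == pytest.approx(dip_statistic(x),
                                                             abs=1e-12)
        assert dip_statistic(-x) == pytest.approx(dip_statistic(x), abs=1e-12)

    def test_n_below_2_rejected(self):
        with pytest.raises(ValueError):
            dip_statistic([1.0])


class TestDipTest:
    def test_fixed_seed_bit_identical(self):
        x = np.random.default_rng(1).uniform(0, 1, 200)
        a = dip_test(x, n_boot=300, seed=9)
        b = dip_test(x, n_boot=300, seed=9)
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_bimodal_rejected(self):
        x = make_bimodal_population(500, 6.0, seed=2)
        assert dip_test(x, n_boot=300, seed=3).p_value < 0.05

    def test_uniform_not_rejected_typically(self):
        x = np.random.default_rng(4).uniform(0, 1, 500)
        assert dip_test(x, n_boot=300, seed=5).p_value > 0.01

    def test_low_boot_warning(self):
        x = np.random.default_rng(6).uniform(0, 1, 50)
        assert dip_test(x, n_boot=50, seed=7).low_boot_warning

    def test_n_too_small(self):
        with pytest.raises(ValueError):
            dip_test([1.0, 2.0, 3.0])


class TestDipTestNd:
    def test_gaussian_2d_not_rejected(self):
        pts = np.random.default_rng(1).standard_normal((400, 2))
        res = dip_test_nd(pts, n_boot=200, seed=2)
        assert res.p_value > 0.05

    def test_bimodal_2d_rejected(self):
        pts = make_bimodal_population(400, 6.0, seed=3, dim=2)
        assert dip_test_nd(pts, n_boot=200, seed=4).p_value < 0.05

    def test_bimodal_3d_rejected(self):
        pts = make_bimodal_population(400, 6.0, seed=5, dim=3)
        assert dip_test_nd(pts, n_boot=200, seed=6).p_value < 0.05

    def test_rotation_near_invariance(self):
        pts = make_bimodal_population(300, 5.0, seed=7, dim=2)
        r1 = dip_test_nd(pts, n_boot=50, seed=8)
        ang = 0.53
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        r2 = dip_test_nd(pts @ rot.T, n_boot=50, seed=8)
        assert r2.statistic == pytest.approx(r1.statistic, rel=0.2)

    def test_rank_deficient_covariance_flagged(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(200)
        pts = np.stack([x, 2.0 * x], axis=1)     # exactly collinear
        res = dip_test_nd(pts, n_boot=50, seed=10)
        assert res.projection_info["covariance_regularized"]

    def test_bad_dimension(self):
        with pytest.raises(ValueError):
            dip_test_nd(np.zeros((50, 4)))


class TestSpearmanWald:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        res = spearman_with_wald(x, np.exp(x))
        assert res.statistic == pytest.approx(1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 80)
        y = x + rng.normal(0, 0.3, 80)
        mine = spearman_with_wald(x, y)
        ref = sps.spearmanr(x, y)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 2, 60)
        y = x**2 + rng.normal(0, 0.1, 60)
        a = spearman_with_wald(x, y)
        b = spearman_with_wald(np.log(x), np.sqrt(np.abs(y)) * np.sign(y))
        assert b.statistic == pytest.approx(a.statistic, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_with_wald([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestComparePopulations:
    def _table(self):
        import pandas as pd
        rng = np.random.default_rng(5)
        a = rng.lognormal(np.log(0.32), 0.5, 120)
        b = rng.lognormal(np.log(0.15), 0.5, 120)
        return pd.DataFrame({
            "species": ["human"] * 120 + ["mouse"] * 120,
            "head_volume_um3": np.concatenate([a, b]),
        })

    def test_direction_matches_construction(self):
        rep = compare_populations(self._table(), "species", ["head_volume_um3"])
        t = rep["features"]["head_volume_um3"]["tests"]["human vs mouse"]
        assert t["direction"] == "x>y"
        assert t["p"] < 0.001 and t["stars"] == "***"

    def test_medians_are_empirical(self):
        table = self._table()
        rep = compare_populations(table, "species", ["head_volume_um3"])
        med = rep["features"]["head_volume_um3"]["groups"]["human"]["median"]
        assert med == pytest.approx(
            np.median(table.loc[table.species == "human", "head_volume_um3"]))

    def test_identical_populations_ns(self):
        import pandas as pd
        x = np.random.default_rng(6).uniform(0, 1, 60)
        table = pd.DataFrame({"g": ["a"] * 60 + ["b"] * 60,
                              "f": np.concatenate([x, x])})
        rep = compare_populations(table, "g", ["f"])
        assert rep["features"]["f"]["tests"]["a vs b"]["stars"] == "n.s."

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            compare_populations(self._table(), "species", ["nope"])


def test_significance_stars():
    assert significance_stars(0.2) == "n.s."
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.0004) == "***"
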