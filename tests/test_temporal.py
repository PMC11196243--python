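import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from vernalphylo.communities import CommunityCollection, CommunityObservation
from vernalphylo.simulate import simulate_climate
from vernalphylo.tables import ClimateSeries, cumulative_rainfall
from vernalphylo.temporal import (
    climate_matrix,
    community_time_distance,
    env_distance,
    factorial_model,
    mantel,
    poly_trend,
    value_distance,
)


class TestPolyTrend:
    def test_linear_data_selects_degree_one(self, rng):
        x = np.arange(30.0)
        y = 2.0 + 0.5 * x + rng.normal(scale=0.01, size=30)
        fit = poly_trend(x, y)
        assert fit.degree == 1
        assert fit.coefficients[1] == pytest.approx(0.5, abs=0.01)

    def test_cubic_with_late_drop_selects_degree_three(self):
        recovered = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = np.tile(np.arange(1.0, 10.0), 3)
            y = 0.2 * x + 0.3 * x**2 - 0.045 * x**3 + r.normal(scale=0.3, size=len(x))
            recovered += poly_trend(x, y).degree == 3
        assert recovered >= 16  # >= 80% of seeds

    def test_aic_selection_consistent_at_large_n(self, rng):
        x = np.linspace(0, 9, 200)
        y = 1.0 + 0.3 * x + rng.normal(scale=0.05, size=200)
        assert poly_trend(x, y).degree == 1

    def test_diagnostics_calibrated_on_homoskedastic_noise(self):
        bps, sws = [], []
        for seed in range(200):
            r = np.random.default_rng(seed)
            x = np.arange(25.0)
            y = 1.0 + 0.2 * x + r.normal(size=25)
            fit = poly_trend(x, y, max_degree=1)
            bps.append(fit.breusch_pagan_p)
            sws.append(fit.shapiro_p)
        # roughly uniform p-values: mean near 0.5, few extremes
        assert abs(np.mean(bps) - 0.5) < 0.1
        assert abs(np.mean(sws) - 0.5) < 0.1

    def test_insufficient_n_names_dropped_degree(self):
        with pytest.raises(ValueError, match="degree"):
            poly_trend(np.arange(5.0), np.arange(5.0))


class TestFactorialModel:
    @staticmethod
    def _frame(rng, effect=0.0):
        rows = []
        for zone in ("bottom", "edge", "upland"):
            for season in ("early", "mid", "late"):
                for rep in range(3):
                    y = rng.normal()
                    if zone == "upland" and season == "mid":
                        y += effect
                    rows.append({"zone": zone, "season": season, "y": y})
        return pd.DataFrame(rows)

    def test_planted_zone_effect_detected(self, rng):
        df = self._frame(rng)
        df["y"] = (df["zone"] == "bottom").astype(float) + rng.normal(
            scale=0.01, size=len(df)
        )
        res = factorial_model(df, "y")
        assert res["p_zone"] < 1e-10
        assert res["p_season"] > 0.05

    def test_planted_interaction_detected(self, rng):
        res = factorial_model(self._frame(rng, effect=8.0), "y")
        assert res["p_interaction"] < 1e-4

    def test_balanced_two_by_two_matches_hand_computed_sums_of_squares(self):
        # 2 zones x 2 seasons x 2 replicates, computed by hand from the
        # classical balanced two-way ANOVA decomposition
        df = pd.DataFrame(
            {
                "zone": ["bottom"] * 4 + ["edge"] * 4,
                "season": (["early"] * 2 + ["mid"] * 2) * 2,
                "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 9.0, 10.0],
            }
        )
        # cell means: 1.5, 3.5, 5.5, 9.5; grand mean 5.0
        # SS_zone = 8 * (2.5)^2 / ... -> computed directly:
        n = 2
        cells = df.groupby(["zone", "season"])['y'].mean()
        zm = df.groupby("zone")["y"].mean()
        sm = df.groupby("season")["y"].mean()
        g = df["y"].mean()
        ss_zone = 2 * n * ((zm - g) ** 2).sum()
        ss_season = 2 * n * ((sm - g) ** 2).sum()
        ss_inter = n * sum(
            (cells[z, s] - zm[z] - sm[s] + g) ** 2
            for z in ("bottom", "edge")
            for s in ("early", "mid")
        )
        res = factorial_model(df, "y")
        anova = res["anova"]
        assert anova.loc["C(zone)", "sum_sq"] == pytest.approx(ss_zone)
        assert anova.loc["C(season)", "sum_sq"] == pytest.approx(ss_season)
        assert anova.loc["C(zone):C(season)", "sum_sq"] == pytest.approx(ss_inter)

    def test_pure_noise_p_values_roughly_uniform(self):
        ps = {"p_zone": [], "p_season": [], "p_interaction": []}
        for seed in range(150):
            df = self._frame(np.random.default_rng(seed))
            res = factorial_model(df, "y")
            for k in ps:
                ps[k].append(res[k])
        for k, vals in ps.items():
            assert abs(np.mean(vals) - 0.5) < 0.12, k

    def test_single_level_rejected(self):
        df = pd.DataFrame(
            {"zone": ["bottom"] * 4, "season": ["early", "mid"] * 2, "y": range(4)}
        )
        with pytest.raises(ValueError):
            factorial_model(df, "y")


class TestMantel:
    @staticmethod
    def _random_dm(rng, n=9):
        x = rng.random((n, n))
        m = (x + x.T) / 2
        np.fill_diagonal(m, 0)
        return DistanceMatrix(m, ids=[str(i) for i in range(n)])

    def test_identical_matrices_attain_minimal_p(self, rng):
        dm = self._random_dm(rng)
        res = mantel(dm, dm, n_perm=999, seed=0)
        assert res.r_statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_z_statistic_on_all_ones(self):
        m = 1.0 - np.eye(4)
        dm = DistanceMatrix(m, ids=list("abcd"))
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.z_statistic == pytest.approx(6.0)

    def test_p_uniform_under_independence(self):
        ps = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            res = mantel(self._random_dm(r), self._random_dm(r), n_perm=199,
                         seed=seed)
            ps.append(res.p_value)
        from scipy import stats

        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_cross_check_against_skbio(self, rng):
        from skbio.stats.distance import mantel as sk_mantel

        a, b = self._random_dm(rng), self._random_dm(rng)
        res = mantel(a, b, n_perm=199, seed=1)
        r_sk, _, _ = sk_mantel(a, b, permutations=0, alternative="greater")
        assert res.r_statistic == pytest.approx(r_sk)

    def test_mismatched_labels_rejected(self, rng):
        a = self._random_dm(rng, 5)
        b = DistanceMatrix(a.data, ids=["9", "8", "7", "6", "5"])
        with pytest.raises(ValueError, match="labels"):
            mantel(a, b)


class TestEnvDistance:
    def test_absolute_differences(self):
        vals = pd.Series([10.0, 12.0, 15.0], index=["x", "y", "z"])
        dm = value_distance(vals)
        assert dm["x", "y"] == 2 and dm["y", "z"] == 3 and dm["x", "z"] == 5
        assert np.allclose(dm.data, dm.data.T)

    def test_annual_grouping_uses_water_years(self):
        cs = simulate_climate(2, seed=0, start_year=2019,
                              annual_totals=[200.0, 300.0])
        dm = env_distance(cs, "annual", "precipitation")
        assert list(dm.ids) == ["2019", "2020"]
        assert dm["2019", "2020"] == pytest.approx(100.0)

    def test_equal_means_give_zero_distance(self):
        dates = pd.date_range("2019-01-01", periods=730, freq="D")
        df = pd.DataFrame(
            {"date": dates, "precipitation": 0.0, "tmin": 5.0, "tmean": 10.0,
             "tmax": 15.0}
        )
        dm = env_distance(ClimateSeries(df), "seasonal", "tmean")
        assert np.allclose(dm.data, 0.0)

    def test_unknown_variable_rejected(self):
        cs = simulate_climate(1, seed=0)
        with pytest.raises(ValueError, match="variable"):
            env_distance(cs, "annual", "humidity")


class TestCommunityTimeDistance:
    @staticmethod
    def _weekly(specs):
        return CommunityCollection(
            [
                CommunityObservation("p1", "edge", 2019, sp, week=w)
                for w, sp in enumerate(specs, start=1)
            ],
            "weekly",
        )

    def test_identical_weeks_give_zero_matrix(self):
        coll = self._weekly([{"a", "b"}] * 5)
        jdm, _, meta = community_time_distance(coll)
        assert np.allclose(jdm.data, 0.0)
        assert list(meta["season"])[:3] == ["early", "early", "early"]

    def test_total_turnover_gives_all_ones(self):
        coll = self._weekly([{f"s{w}"} for w in range(4)])
        jdm, _, _ = community_time_distance(coll)
        off = jdm.data[np.triu_indices(4, 1)]
        assert np.allclose(off, 1.0)

    def test_pd_matrix_is_absolute_difference(self, toy_tree):
        coll = self._weekly([{"A", "B"}, {"A", "B", "C"}, {"C"}, {"A"}])
        _, pdm, _ = community_time_distance(coll, tree=toy_tree)
        # PD values: 3, 5, 2, 2
        labels = list(pdm.ids)
        assert pdm[labels[0], labels[1]] == pytest.approx(2.0)
        assert pdm[labels[2], labels[3]] == pytest.approx(0.0)

    def test_climate_matrix_aligns_with_meta(self):
        coll = self._weekly([{"a"}, {"a", "b"}, {"b"}, {"c"}, {"c", "d"}])
        _, _, meta = community_time_distance(coll)
        cs = simulate_climate(1, seed=1, start_year=2019)
        dm = climate_matrix(meta, cs, "seasonal", "tmean")
        assert list(dm.ids) == list(meta.index)


def test_cumulative_rainfall_window_sums():
    dates = pd.date_range("2019-01-01", periods=10, freq="D")
    cs = ClimateSeries(
        pd.DataFrame({"date": dates, "precipitation": 1.0, "tmin": 0.0,
                      "tmean": 5.0, "tmax": 10.0})
    )
    assert cumulative_rainfall(cs, "2019-01-01", "2019-01-03") == pytest.approx(3.0)
    assert cumulative_rainfall(cs, "2019-01-05", "2019-01-05") == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cumulative_rainfall(cs, "2018-12-01", "2019-01-03")
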