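import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import decade_enm as de
from decade_enm.stats import great_circle_distance


class TestSqueeze:
    def test_boundary_values_squeezed_by_formula(self):
        assert de.squeeze_proportions(np.array([1.0]), 8)[0] == pytest.approx(0.9375)
        assert de.squeeze_proportions(np.array([0.0]), 8)[0] == pytest.approx(0.0625)

    def test_interior_values_pass_through(self):
        y = np.array([0.2, 0.5, 0.9])
        np.testing.assert_array_equal(de.squeeze_proportions(y, 8), y)

    def test_mixed_vector_squeezes_all_entries(self):
        y = np.array([0.0, 0.5, 1.0])
        out = de.squeeze_proportions(y, 8)
        assert out[1] == pytest.approx((0.5 * 7 + 0.5) / 8)
        assert np.all((out > 0) & (out < 1))


def simulate_beta(n, b0, b1, phi, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10, n)
    mu = expit(b0 + b1 * x)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    y = np.clip(y, 1e-9, 1 - 1e-9)
    return x, y


class TestBetaRegression:
    def test_parameter_recovery_within_wald_interval(self):
        x, y = simulate_beta(500, -1.0, 0.5, 20.0, seed=42)
        res = de.beta_regression(x, y)
        assert abs(res.slope - 0.5) < 3 * res.se_slope
        assert res.precision > 0
        assert 0 <= res.p_slope <= 1

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            de.beta_regression(np.ones(10), np.full(10, 0.4))

    def test_boundary_response_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            de.beta_regression(np.arange(5.0), np.array([0.1, 0.5, 1.0, 0.2, 0.3]))

    def test_order_invariance(self):
        x, y = simulate_beta(100, -1.0, 0.5, 20.0, seed=7)
        res1 = de.beta_regression(x, y)
        perm = np.random.default_rng(0).permutation(100)
        res2 = de.beta_regression(x[perm], y[perm])
        assert res1.slope == pytest.approx(res2.slope, rel=1e-6)
        assert res1.loglik == pytest.approx(res2.loglik, rel=1e-8)

    def test_loglik_beats_intercept_only(self):
        from statsmodels.othermod.betareg import BetaModel

        x, y = simulate_beta(200, -0.5, 0.3, 15.0, seed=3)
        res = de.beta_regression(x, y)
        null = BetaModel(y, np.ones((len(y), 1))).fit(disp=False)
        assert res.loglik >= null.llf - 1e-6

    def test_bias_of_slope_shrinks_with_n(self):
        biases = {}
        for n in (50, 200, 500):
            ests = [
                de.beta_regression(*simulate_beta(n, -1.0, 0.5, 20.0, seed=s)).slope
                for s in range(30)
            ]
            biases[n] = abs(np.mean(ests) - 0.5)
        assert biases[500] < biases[50] + 0.01


class TestDecadeEffect:
    def summaries(self, props):
        return pd.DataFrame(
            {
                "window": [f"w{i}" for i in range(len(props))],
                "n_records": [30, 31, 40, 48, 51, 74, 144, 153][: len(props)],
                "proportion_conservative": props,
                "proportion_nonconservative": props,
            }
        )

    def test_eight_windows_one_result_per_mode(self):
        rng = np.random.default_rng(1)
        props = np.clip(np.linspace(0.2, 0.6, 8) + rng.normal(0, 0.01, 8), 0.01, 0.99)
        s = self.summaries(props)
        for mode in ("conservative", "nonconservative"):
            res = de.decade_effect_test(s, mode)
            assert res.mode == mode
            assert res.n == 8

    def test_growing_area_gives_positive_slope(self):
        rng = np.random.default_rng(5)
        mu = expit(-1.5 + 0.015 * np.array([30, 31, 40, 48, 51, 74, 144, 153]))
        props = rng.beta(mu * 100, (1 - mu) * 100)
        res = de.decade_effect_test(self.summaries(props))
        assert res.slope > 0
        assert res.p_slope < 0.05

    def test_constant_area_gives_null_result(self):
        rng = np.random.default_rng(2)
        props = 0.4 + rng.normal(0, 0.005, 8)
        res = de.decade_effect_test(self.summaries(props))
        assert abs(res.slope) < 0.01
        assert res.p_slope > 0.05

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="3 windows"):
            de.decade_effect_test(self.summaries([0.2, 0.3]))

    def test_window_index_predictor(self):
        props = np.linspace(0.25, 0.55, 8)
        res = de.decade_effect_test(self.summaries(props), predictor="window_index")
        assert res.predictor == "window_index"
        assert res.slope > 0


class TestDistances:
    def test_record_on_center_has_zero_distance(self):
        occ = pd.DataFrame({"longitude": [1.0], "latitude": [2.0], "year": [2000]})
        ctr = pd.DataFrame({"id": ["c"], "longitude": [1.0], "latitude": [2.0]})
        assert de.nearest_center_distance(occ, ctr)[0] == 0.0

    def test_three_four_five_triangle(self):
        occ = pd.DataFrame({"longitude": [3.0], "latitude": [4.0], "year": [2000]})
        ctr = pd.DataFrame({"id": ["c"], "longitude": [0.0], "latitude": [0.0]})
        assert de.nearest_center_distance(occ, ctr)[0] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        occ = pd.DataFrame(
            {"longitude": rng.uniform(0, 10, 100), "latitude": rng.uniform(0, 10, 100)}
        )
        ctr = pd.DataFrame(
            {"id": list("abcde"), "longitude": rng.uniform(0, 10, 5),
             "latitude": rng.uniform(0, 10, 5)}
        )
        fast = de.nearest_center_distance(occ, ctr)
        for i in range(100):
            best = min(
                np.hypot(
                    occ.longitude[i] - ctr.longitude[j],
                    occ.latitude[i] - ctr.latitude[j],
                )
                for j in range(5)
            )
            assert fast[i] == pytest.approx(best)

    def test_empty_centers_rejected(self):
        occ = pd.DataFrame({"longitude": [0.0], "latitude": [0.0], "year": [2000]})
        with pytest.raises(ValueError):
            de.nearest_center_distance(occ, occ.iloc[:0])

    def test_great_circle_mode_is_positive_and_bounded(self):
        occ = pd.DataFrame({"longitude": [-49.3], "latitude": [-16.6], "year": [2015]})
        ctr = pd.DataFrame({"id": ["c"], "longitude": [-43.2], "latitude": [-22.9]})
        d = great_circle_distance(occ, ctr)
        assert 700 < d[0] < 1200  # km, plausible intra-Brazil distance


class TestWallacean:
    def make_occ(self, years, dists):
        # place records east of a single center at (0, 0) so the distance
        # to it is exactly the longitude
        return (
            pd.DataFrame({"longitude": dists, "latitude": 0.0, "year": years}),
            pd.DataFrame({"id": ["c"], "longitude": [0.0], "latitude": [0.0]}),
        )

    def test_collinear_maxima_fit_exactly(self):
        years = [2000, 2001, 2002, 2003]
        occ, ctr = self.make_occ(years, [1.0, 2.0, 3.0, 4.0])
        res = de.wallacean_test(occ, ctr)
        assert res.slope == pytest.approx(1.0)
        assert res.adj_r2 == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_weights_are_yearly_record_counts(self):
        occ, ctr = self.make_occ(
            [2000, 2000, 2001, 2002, 2002, 2002], [1, 2, 3, 4, 5, 6]
        )
        res = de.wallacean_test(occ, ctr)
        assert res.per_year.weight.tolist() == [2, 1, 3]
        assert res.per_year.max_distance.tolist() == [2, 3, 6]

    def test_equal_weights_reproduce_ols(self):
        rng = np.random.default_rng(9)
        years = np.arange(1990, 2010)
        dists = rng.uniform(1, 5, len(years))
        occ, ctr = self.make_occ(years, dists)
        res = de.wallacean_test(occ, ctr)  # one record per year => equal weights
        ols = sm.OLS(dists, sm.add_constant(years.astype(float))).fit()
        assert res.slope == pytest.approx(ols.params[1])
        assert res.adj_r2 == pytest.approx(ols.rsquared_adj)
        assert res.p_value == pytest.approx(ols.f_pvalue)

    def test_fewer_than_three_years_rejected(self):
        occ, ctr = self.make_occ([2000, 2001], [1.0, 2.0])
        with pytest.raises(ValueError, match="3 distinct years"):
            de.wallacean_test(occ, ctr)

    def test_sum_weight_option(self):
        occ, ctr = self.make_occ([2000, 2000, 2001, 2002], [1, 2, 3, 4])
        res = de.wallacean_test(occ, ctr, weight="sum")
        assert res.per_year.weight.tolist() == [3, 3, 4]
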