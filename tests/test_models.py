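import numpy as np
import pandas as pd
import pytest

import evoherit as ev
from evoherit.models import DifferenceCorrelation

from oracles import lstsq_fit


class TestAdaptabilityFit:
    def test_constant_increments_give_zero_slope(self):
        fit = ev.fit_adaptability_vs_fitness([2.0] * 10, np.arange(10.0))
        assert fit.params["fitness"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_perfect_line_gives_unit_r2(self):
        x = np.arange(10.0)
        fit = ev.fit_adaptability_vs_fitness(0.3 - 0.5 * x, x)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.params["fitness"] == pytest.approx(-0.5)

    def test_slope_recovery_within_two_standard_errors(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.2, size=230)
        y = 0.05 - 0.5 * x + rng.normal(0, 0.03, size=230)
        fit = ev.fit_adaptability_vs_fitness(y, x)
        assert abs(fit.params["fitness"] + 0.5) < 2 * fit.bse["fitness"]

    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            fit = ev.fit_adaptability_vs_fitness(y, x)
            coef, r2 = lstsq_fit(y, [x])
            assert fit.params["const"] == pytest.approx(coef[0], abs=1e-10)
            assert fit.params["fitness"] == pytest.approx(coef[1], abs=1e-10)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            ev.fit_adaptability_vs_fitness([1, 2, 3], [1, 1, 1])


class TestNoiseRobustness:
    def test_zero_error_matches_noiseless_fit(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = -0.4 * x + rng.normal(0, 0.5, size=50)
        base = ev.fit_adaptability_vs_fitness(y, x)
        nr = ev.noise_robustness_fit(y, x, np.zeros(50), n_draws=10, seed=0)
        assert nr.mean_r2 == pytest.approx(base.r2)
        assert nr.sd_r2 == 0.0

    def test_attenuation_by_half_when_noise_equals_signal(self):
        """Error variance equal to Var(X) attenuates r² by a factor ~1/2."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, size=4000)
        y = -0.5 * x + rng.normal(0, 0.5, size=4000)
        base = ev.fit_adaptability_vs_fitness(y, x).r2
        nr = ev.noise_robustness_fit(y, x, np.full(4000, x.var()), n_draws=40,
                                     seed=1)
        assert nr.mean_r2 == pytest.approx(base / 2, abs=0.05)

    def test_noise_never_increases_mean_r2(self):
        rng = np.random.default_rng(4)
        for s in range(10):
            x = rng.normal(size=100)
            y = -0.3 * x + rng.normal(0, 0.8, size=100)
            nr = ev.noise_robustness_fit(y, x, np.full(100, 0.5), n_draws=30,
                                         seed=s)
            assert nr.mean_r2 <= nr.baseline_r2 + 0.02

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=40), rng.normal(size=40)
        a = ev.noise_robustness_fit(y, x, np.full(40, 0.2), n_draws=20, seed=9)
        b = ev.noise_robustness_fit(y, x, np.full(40, 0.2), n_draws=20, seed=9)
        assert np.array_equal(a.r2_draws, b.r2_draws)


class TestPleiotropyModel:
    def test_away_fitness_drives_detection(self):
        hits_beta, hits_gamma = 0, 0
        for s in range(40):
            rng = np.random.default_rng(400 + s)
            xa = rng.normal(0, 0.2, size=200)
            xh = 0.7 * xa + rng.normal(0, 0.14, size=200)
            y = 0.08 - 0.6 * xa + rng.normal(0, 0.03, size=200)
            fit = ev.fit_pleiotropy_model(y, xa, xh)
            hits_beta += fit.pvalues["fitness_away"] < 0.05
            hits_gamma += fit.pvalues["fitness_home"] < 0.05
        assert hits_beta >= 38
        assert hits_gamma <= 10

    def test_null_calibration_of_coefficients(self):
        false_pos = 0
        n_sims = 100
        for s in range(n_sims):
            rng = np.random.default_rng(900 + s)
            xa = rng.normal(size=100)
            xh = rng.normal(size=100)
            y = rng.normal(size=100)
            fit = ev.fit_pleiotropy_model(y, xa, xh)
            false_pos += fit.pvalues["fitness_away"] < 0.05
        # binomial 95% band around 0.05 with 100 trials
        assert 0 <= false_pos <= 11

    def test_duplicated_predictor_flagged(self):
        x = np.random.default_rng(6).normal(size=30)
        with pytest.warns(UserWarning, match="collinear"):
            fit = ev.fit_pleiotropy_model(x * 0.5, x, x)
        assert "collinear" in fit.flags


class TestCombinedModel:
    def _dataset(self, seed, interaction=0.06):
        rng = np.random.default_rng(seed)
        n = 230
        gstar = rng.integers(0, 2, size=n) - 0.5
        q1 = rng.integers(0, 2, size=n) - 0.5
        q2 = rng.integers(0, 2, size=n) - 0.5
        x = 0.2 * gstar + rng.normal(0, 0.1, size=n)
        y = (0.05 - 0.5 * x + 0.05 * gstar + 0.04 * q1
             + interaction * gstar * q1 + rng.normal(0, 0.02, size=n))
        return y, x, pd.DataFrame({"q1": q1, "q2": q2}), gstar

    def test_true_interaction_retained_after_refit(self):
        kept = 0
        for s in range(20):
            y, x, q, g = self._dataset(s)
            fit = ev.fit_combined_model(y, x, q, g)
            kept += "focal_x_q1" in fit.significant_terms
        assert kept >= 18

    def test_null_terms_rarely_retained(self):
        spurious = 0
        for s in range(20):
            y, x, q, g = self._dataset(1000 + s, interaction=0.0)
            fit = ev.fit_combined_model(y, x, q, g)
            spurious += "focal_x_q2" in fit.significant_terms
        assert spurious <= 3

    def test_refit_only_contains_significant_terms(self):
        y, x, q, g = self._dataset(3)
        fit = ev.fit_combined_model(y, x, q, g)
        assert set(fit.refit.terms) == set(fit.significant_terms)
        for t in fit.refit.terms:
            assert fit.full.pvalues_adj[t] <= 0.05

    def test_nested_r2_ordering(self):
        for s in range(10):
            y, x, q, g = self._dataset(50 + s)
            fitness_only = ev.fit_adaptability_vs_fitness(y, x)
            combined = ev.fit_combined_model(y, x, q, g)
            assert combined.full.r2 >= fitness_only.r2 - 1e-12

    def test_aliased_term_dropped_with_warning(self):
        y, x, q, g = self._dataset(4)
        q["q2"] = q["q1"]
        with pytest.warns(UserWarning, match="aliased"):
            fit = ev.fit_combined_model(y, x, q, g)
        assert "qtl_q2" not in fit.full.terms


class TestNormalization:
    def test_single_value_maps_correctly(self):
        out = ev.normalize_traits(np.array([1.0, 2.0, 3.0]))
        assert out[2] == pytest.approx(1.0)  # (3-2)/1

    def test_output_standardized(self):
        rng = np.random.default_rng(7)
        v = rng.normal(3, 2.5, size=100)
        out = ev.normalize_traits(v)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_stratified_groups_each_standardized(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=60)
        strata = np.array(["RM"] * 30 + ["BY"] * 30)
        out = ev.normalize_traits(v, strata)
        for s in ("RM", "BY"):
            assert out[strata == s].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[strata == s].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            ev.normalize_traits(np.ones(5))


class TestDifferenceCorrelation:
    def test_exact_negative_relation(self):
        rng = np.random.default_rng(9)
        d = rng.normal(size=50)
        res = ev.difference_correlation(d, -d, n_boot=200, seed=0)
        assert res.r == pytest.approx(-1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.p_negative < 0.01

    def test_independent_vectors_not_significant(self):
        sig = 0
        for s in range(40):
            rng = np.random.default_rng(600 + s)
            res = ev.difference_correlation(
                rng.normal(size=80), rng.normal(size=80), n_boot=300, seed=s
            )
            sig += res.p_negative < 0.05
        assert sig <= 7  # ≈ one-sided 5% nominal rate

    def test_independent_declining_rules_produce_negative_correlation(self):
        """Founders with disparate fitness across environments adapt faster
        where they are less fit, producing r < 0 at study scale."""
        detections = 0
        for s in range(10):
            rng = np.random.default_rng(700 + s)
            n = 230
            x = rng.normal(0, 1, size=n)
            y = 0.7 * x + rng.normal(0, 0.7, size=n)
            dx = -0.5 * x + rng.normal(0, 0.5, size=n)
            dy = -0.5 * y + rng.normal(0, 0.5, size=n)
            xt, yt = ev.normalize_traits(x), ev.normalize_traits(y)
            dxt, dyt = ev.normalize_traits(dx), ev.normalize_traits(dy)
            res = ev.difference_correlation(xt - yt, dxt - dyt, n_boot=500, seed=s)
            detections += (res.r < 0) and (res.p_negative < 0.05)
        assert detections >= 9


class TestGroupMeans:
    def _table(self, value=0.07):
        rows = []
        i = 0
        for allele in ("RM", "BY"):
            for ee in ("OT", "HT"):
                for me in ("OT", "HT"):
                    for _ in range(5):
                        rows.append(
                            {"population_id": f"p{i}", "focal_allele": allele,
                             "evolved_env": ee, "measured_env": me,
                             "fitness": value}
                        )
                        i += 1
        return pd.DataFrame(rows)

    def test_constant_fitness_gives_constant_cells(self):
        gm = ev.group_mean_increments(self._table(0.07), n_boot=100, seed=0)
        assert len(gm) == 8
        assert np.allclose(gm["mean"], 0.07)
        assert np.allclose(gm["ci_lo"], 0.07)
        assert np.allclose(gm["ci_hi"], 0.07)

    def test_home_exceeds_away_when_constructed(self):
        df = self._table()
        home = (df["evolved_env"] == df["measured_env"])
        df.loc[home, "fitness"] = 0.2
        gm = ev.group_mean_increments(df, n_boot=100, seed=0)
        home_cells = gm[gm["evolved_env"] == gm["measured_env"]]
        away_cells = gm[gm["evolved_env"] != gm["measured_env"]]
        assert home_cells["mean"].min() > away_cells["mean"].max()

    def test_fixed_seed_reproducible(self):
        df = self._table()
        a = ev.group_mean_increments(df, n_boot=100, seed=3)
        b = ev.group_mean_increments(df, n_boot=100, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cell_flagged(self):
        df = self._table()
        df = df[~((df["focal_allele"] == "RM") & (df["evolved_env"] == "OT")
                  & (df["measured_env"] == "OT"))]
        with pytest.warns(UserWarning, match="empty cell"):
            gm = ev.group_mean_increments(df, n_boot=50, seed=0)
        assert gm["mean"].isna().sum() == 1
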