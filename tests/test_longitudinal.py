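import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hrvaging import longitudinal as lg
from hrvaging.synth import LMETruth, SynthConfig, simulate_metric_table

from oracles import pitman_morgan_regression_oracle


def make_table(rows):
    return pd.DataFrame(rows, columns=["mouse_id", "age_months", "state", "metric", "value"])


def quadratic_table(n_mice=20, ages=(6, 9, 12, 15, 18, 21), beta=(10.0, 3.0, 0.0),
                    noise=0.0, seed=0, state="abk", metric="m"):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_mice):
        for a in ages:
            y = beta[0] + beta[1] * a + beta[2] * a**2 + noise * rng.standard_normal()
            rows.append((f"M{i:02d}", float(a), state, metric, y))
    return make_table(rows)


class TestSplitPeriods:
    def test_standard_grid(self):
        tab = quadratic_table(n_mice=2, ages=(6, 9, 12, 15, 18, 21, 24, 27, 30))
        early, late = lg.split_periods(tab)
        assert sorted(early["age_months"].unique()) == [6, 9, 12, 15, 18, 21]
        assert sorted(late["age_months"].unique()) == [21, 24, 27, 30]

    def test_boundary_age_in_both(self):
        tab = quadratic_table(n_mice=2, ages=(21,))
        early, late = lg.split_periods(tab)
        assert not early.empty and not late.empty

    def test_only_late_age(self):
        tab = quadratic_table(n_mice=2, ages=(24,))
        early, late = lg.split_periods(tab)
        assert early.empty and set(late["age_months"]) == {24.0}


class TestFitLME:
    def test_noise_free_line_recovered_exactly(self):
        tab = quadratic_table(beta=(10.0, 3.0, 0.0), noise=0.0)
        fit = lg.fit_lme(tab, "m", "abk", period="early")
        assert fit.beta1 == pytest.approx(3.0, abs=1e-5)
        assert fit.beta2 == pytest.approx(0.0, abs=1e-6)

    def test_two_distinct_ages_forces_linear(self):
        tab = quadratic_table(ages=(6, 9), noise=0.5)
        fit = lg.fit_lme(tab, "m", "abk", period="early")
        assert fit.model_form == "linear"
        assert fit.beta2 == 0.0

    def test_parameter_recovery_within_2se(self):
        cfg = SynthConfig(n_mice=30, seed=11, lme_truth={
            "m": LMETruth(400.0, 2.0, 0.5, sd_b0=20.0, sd_b1=1.0, sd_b2=0.0, sigma_eps=5.0)})
        tab, _ = simulate_metric_table(cfg, ages=(6, 9, 12, 15, 18, 21))
        fit = lg.fit_lme(tab, "m", "abk", period="early", allow_random_quad=False)
        for est, true, se in zip((fit.beta0, fit.beta1, fit.beta2),
                                 (400.0, 2.0, 0.5), fit.se_beta):
            assert abs(est - true) < 2.5 * se

    def test_too_few_mice_raises(self):
        tab = quadratic_table(n_mice=3)
        with pytest.raises(lg.FitFailureError):
            lg.fit_lme(tab, "m", "abk", period="early")


class TestMouseRates:
    def test_fixed_effect_plugin(self):
        tab = quadratic_table(beta=(10.0, 1.0, 0.5), noise=0.0,
                              ages=(21, 24, 27, 30))
        fit = lg.fit_lme(tab, "m", "abk", period="late")
        rates = lg.mouse_rates(fit, age_at_eval=24.0)
        # derivative of 10 + x + 0.5 x^2 at 24 is 1 + 24 = 25
        assert all(r.rate == pytest.approx(25.0, abs=1e-3) for r in rates)

    def test_linear_form_rate_age_independent(self):
        tab = quadratic_table(beta=(10.0, 3.0, 0.0), ages=(6, 9), noise=0.2, seed=3)
        fit = lg.fit_lme(tab, "m", "abk", period="early")
        r6 = {r.mouse_id: r.rate for r in lg.mouse_rates(fit, age_at_eval=6.0)}
        r21 = {r.mouse_id: r.rate for r in lg.mouse_rates(fit, age_at_eval=21.0)}
        assert r6 == r21

    def test_rates_match_numerical_derivative_of_predict(self):
        cfg = SynthConfig(n_mice=12, seed=4, lme_truth={
            "m": LMETruth(100.0, 1.0, 0.2, sd_b0=5.0, sd_b1=0.5, sd_b2=0.0, sigma_eps=1.0)})
        tab, _ = simulate_metric_table(cfg, ages=(6, 9, 12, 15, 18, 21))
        fit = lg.fit_lme(tab, "m", "abk", period="early", allow_random_quad=False)
        h = 1e-4
        for r in lg.mouse_rates(fit, age_at_eval=12.0):
            num = (fit.predict(r.mouse_id, 12.0 + h) - fit.predict(r.mouse_id, 12.0 - h)) / (2 * h)
            assert r.rate == pytest.approx(float(num), abs=1e-6)

    def test_recovery_of_individual_slopes(self):
        cfg = SynthConfig(n_mice=30, seed=7, lme_truth={
            "m": LMETruth(50.0, 2.0, 0.0, sd_b0=5.0, sd_b1=1.0, sd_b2=0.0, sigma_eps=2.0)})
        tab, truth = simulate_metric_table(cfg, ages=(6, 9, 12, 15, 18, 21))
        fit = lg.fit_lme(tab, "m", "abk", period="early", allow_random_quad=False)
        est = {r.mouse_id: r.rate for r in lg.mouse_rates(fit, age_at_eval=6.0)}
        t = truth.set_index("mouse_id")
        true_rates = {m: 2.0 + t.loc[m, "b1"] for m in est}
        rho = stats.spearmanr(list(true_rates.values()),
                              [est[m] for m in true_rates])[0]
        assert rho >= 0.8


class TestSignatureAndNormalisation:
    def test_signature_is_abk_minus_basal(self):
        tab = make_table([
            ("m1", 6.0, "basal", "mean_rr", 100.0),
            ("m1", 6.0, "abk", "mean_rr", 120.0),
        ])
        sig = lg.autonomic_signature(tab)
        assert sig.loc[0, "value"] == pytest.approx(20.0)

    def test_identical_states_give_zero(self):
        tab = make_table([
            ("m1", 6.0, "basal", "x", 7.0),
            ("m1", 6.0, "abk", "x", 7.0),
        ])
        assert lg.autonomic_signature(tab)["value"].iloc[0] == 0.0

    def test_qc_failed_pair_omitted(self):
        tab = make_table([
            ("m1", 6.0, "basal", "x", 1.0), ("m1", 6.0, "abk", "x", 2.0),
            ("m1", 9.0, "basal", "x", 1.0), ("m1", 9.0, "abk", "x", 2.0),
        ])
        qc = pd.DataFrame({"mouse_id": ["m1", "m1"], "age_months": [6.0, 9.0],
                           "passed": [True, False]})
        sig = lg.autonomic_signature(tab, qc=qc)
        assert set(sig["age_months"]) == {6.0}

    def test_sign_switch(self):
        tab = make_table([
            ("m1", 6.0, "basal", "x", 1.0), ("m1", 6.0, "abk", "x", 3.0),
        ])
        sig = lg.autonomic_signature(tab, sign="basal_minus_intrinsic")
        assert sig["value"].iloc[0] == pytest.approx(-2.0)

    def test_baseline_normalize(self):
        tab = make_table([
            ("m1", 6.0, "abk", "x", 2.0), ("m1", 30.0, "abk", "x", 4.0),
            ("m2", 9.0, "abk", "x", 5.0),  # missing 6-month baseline -> dropped
        ])
        norm = lg.baseline_normalize(tab)
        m1 = norm[norm["mouse_id"] == "m1"].set_index("age_months")["value"]
        assert m1.loc[6.0] == 1.0 and m1.loc[30.0] == 2.0
        assert "m2" not in set(norm["mouse_id"])

    def test_baseline_normalize_idempotent(self):
        tab = quadratic_table(beta=(10.0, 1.0, 0.0), noise=0.0)
        once = lg.baseline_normalize(tab)
        twice = lg.baseline_normalize(once)
        merged = once.merge(twice, on=["mouse_id", "age_months", "state", "metric"])
        assert np.allclose(merged["value_x"], merged["value_y"])


class TestLoess:
    def test_reproduces_line_exactly(self):
        tab = quadratic_table(beta=(5.0, 2.0, 0.0), noise=0.0)
        traj = lg.loess_trajectory(tab, "m", "abk")
        expect = 5.0 + 2.0 * traj["age"]
        assert np.allclose(traj["fit"], expect, atol=1e-6)

    def test_constant_data_flat_with_tight_band(self):
        tab = quadratic_table(beta=(5.0, 0.0, 0.0), noise=0.0, n_mice=40)
        traj = lg.loess_trajectory(tab, "m", "abk")
        assert np.allclose(traj["fit"], 5.0, atol=1e-9)
        assert np.all(traj["hi95"] - traj["lo95"] < 1e-6)

    def test_hockey_stick_rise_exceeds_band(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(30):
            for a in (6, 9, 12, 15, 18, 21, 24, 27, 30):
                y = (0.0 if a <= 21 else (a - 21) ** 2) + 0.5 * rng.standard_normal()
                rows.append((f"M{i}", float(a), "abk", "m", y))
        traj = lg.loess_trajectory(make_table(rows), "m", "abk").set_index("age")
        gap = traj.loc[30.0, "fit"] - traj.loc[21.0, "fit"]
        band = traj.loc[30.0, "hi95"] - traj.loc[30.0, "fit"]
        assert gap > band

    def test_few_points_fallback(self):
        tab = quadratic_table(n_mice=1, ages=(6, 9, 12))
        traj = lg.loess_trajectory(tab, "m", "abk")
        assert traj["fallback"].all()


class TestMixedANOVA:
    def test_two_ages_equals_paired_t_squared(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(15):
            base = rng.normal(0, 1)
            rows.append((f"M{i}", 6.0, "abk", "m", base + rng.normal(0, 0.5)))
            rows.append((f"M{i}", 9.0, "abk", "m", base + 0.4 + rng.normal(0, 0.5)))
        tab = make_table(rows)
        f, p = lg.mixed_anova(tab, "m", "abk")
        wide = tab.pivot_table(index="mouse_id", columns="age_months", values="value")
        t, pt = stats.ttest_rel(wide[6.0], wide[9.0])
        assert f == pytest.approx(t**2, rel=1e-9)
        assert p == pytest.approx(pt, rel=1e-9)

    def test_strong_age_effect_detected(self):
        tab = quadratic_table(beta=(0.0, 5.0, 0.0), noise=0.5, seed=5)
        f, p = lg.mixed_anova(tab, "m", "abk")
        assert p < 1e-6

    def test_single_age_undefined(self):
        tab = quadratic_table(ages=(6,))
        f, p = lg.mixed_anova(tab, "m", "abk")
        assert math.isnan(f) and math.isnan(p)


class TestClusterRates:
    def _rates(self, n=200, seed=0, blocks=False):
        rng = np.random.default_rng(seed)
        if not blocks:
            return pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        return pd.DataFrame({
            "a1": f1 + 0.2 * rng.standard_normal(n),
            "a2": -f1 + 0.2 * rng.standard_normal(n),  # sign-flipped twin
            "b1": f2 + 0.2 * rng.standard_normal(n),
            "b2": f2 + 0.2 * rng.standard_normal(n),
        })

    def test_perfectly_correlated_merge_at_zero(self):
        x = np.linspace(0, 1, 50)
        rates = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = lg.cluster_rates(rates)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_independent_metrics_merge_near_one(self):
        res = lg.cluster_rates(self._rates())
        assert res.linkage[-1, 2] == pytest.approx(1.0, abs=0.1)

    def test_block_structure_recovered_despite_sign_flip(self):
        res = lg.cluster_rates(self._rates(blocks=True), height_cut=0.5)
        assert res.assignments["a1"] == res.assignments["a2"]
        assert res.assignments["b1"] == res.assignments["b2"]
        assert res.assignments["a1"] != res.assignments["b1"]

    def test_sign_flip_invariance(self):
        rates = self._rates(blocks=True)
        res1 = lg.cluster_rates(rates)
        flipped = rates.copy()
        flipped["a1"] = -flipped["a1"]
        res2 = lg.cluster_rates(flipped)
        assert np.allclose(res1.linkage[:, 2], res2.linkage[:, 2])

    def test_zero_variance_dropped(self):
        rates = self._rates()
        rates["flat"] = 1.0
        res = lg.cluster_rates(rates)
        assert res.dropped == ["flat"]

    def test_newick_well_formed(self):
        res = lg.cluster_rates(self._rates(blocks=True))
        assert res.newick.endswith(";")
        assert res.newick.count("(") == res.newick.count(")")
        for name in res.metrics:
            assert name in res.newick


class TestRateCorrelations:
    def test_diagonal_and_exact_anticorrelation(self):
        x = np.linspace(0, 1, 30)
        rates = pd.DataFrame({"a": x, "b": -x})
        r, p, n = lg.rate_correlations(rates)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert p.loc["a", "b"] < 1e-30

    def test_pairwise_complete_n(self):
        rates = pd.DataFrame({"a": [1.0, 2, 3, 4, np.nan, 6],
                              "b": [2.0, 1, 4, 3, 5, np.nan]})
        _, _, n = lg.rate_correlations(rates)
        assert n.loc["a", "b"] == 4

    def test_triangle_table_layout(self):
        rng = np.random.default_rng(1)
        early = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        late = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        r, p = lg.correlation_triangle_table(early, late)
        r_e, _, _ = lg.rate_correlations(early)
        r_l, _, _ = lg.rate_correlations(late)
        assert r.loc["a", "c"] == pytest.approx(r_e.loc["a", "c"])
        assert r.loc["c", "a"] == pytest.approx(r_l.loc["c", "a"])
        assert (np.diag(r) == 1.0).all()


class TestPitmanMorgan:
    def test_equal_samples_give_t_zero_p_one(self):
        x = np.arange(10.0)
        t, df, p = lg.pitman_morgan(x, x)
        assert t == 0.0 and p == 1.0 and df == 8

    def test_matches_regression_formulation(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x = rng.standard_normal(n)
            y = 0.5 * x + rng.standard_normal(n) * rng.uniform(0.5, 2)
            t, df, p = lg.pitman_morgan(x, y)
            t_o, p_o = pitman_morgan_regression_oracle(x, y)
            assert t == pytest.approx(t_o, rel=1e-9, abs=1e-12)
            assert p == pytest.approx(p_o, rel=1e-9, abs=1e-15)

    def test_power_against_unequal_variances(self):
        rejections = 0
        reps = 300
        for seed in range(reps):
            r = np.random.default_rng(seed)
            x = 2.0 * r.standard_normal(50)
            y = 1.0 * r.standard_normal(50)
            _, _, p = lg.pitman_morgan(x, y)
            if p < 0.05:
                rejections += 1
        assert rejections / reps > 0.5
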