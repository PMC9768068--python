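import numpy as np
import pytest

from hrvaging import hrv_metrics as hm
from hrvaging import spectral, synth
from hrvaging.io_preprocess import make_windows, preprocess_series, select_stationary_segment


def _pas_of(cfg, mouse, age, state="abk"):
    rec = synth.simulate_rr(cfg, mouse, age, state)
    cleaned, _, _ = preprocess_series(rec)
    seg = select_stationary_segment(cleaned)
    return hm.fragmentation(seg.intervals)[3]


def _hf_pct_of(cfg, mouse, age, state):
    rec = synth.simulate_rr(cfg, mouse, age, state)
    cleaned, _, _ = preprocess_series(rec)
    vals = [spectral.estimate_psd(w).hf_pct for w in make_windows(cleaned)]
    return float(np.mean(vals))


class TestFractionalNoise:
    def test_white_noise_case(self):
        rng = np.random.default_rng(0)
        x = synth.fractional_gaussian_noise(4096, 0.5, rng)
        assert abs(np.std(x) - 1.0) < 0.1

    def test_invalid_hurst_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            synth.fractional_gaussian_noise(100, 1.2, rng)

    @pytest.mark.parametrize("alpha", [0.6, 0.9, 1.2, 1.4])
    def test_dfa_roundtrip_monotone_and_close(self, alpha):
        a2s = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = synth.longrange_noise(2**13, alpha, rng)
            _, a2 = hm.dfa(100 + 5 * x)
            a2s.append(a2)
        assert np.mean(a2s) == pytest.approx(alpha, abs=0.25)

    def test_dfa_monotone_in_target(self):
        means = []
        for alpha in (0.6, 0.8, 1.0, 1.2, 1.4):
            vals = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                _, a2 = hm.dfa(100 + 5 * synth.longrange_noise(2**12, alpha, rng))
                vals.append(a2)
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means[:-1], means[1:]))


class TestSimulateRR:
    def test_deterministic_given_seed(self):
        cfg = synth.SynthConfig(seed=9)
        a = synth.simulate_rr(cfg, "M001", 12.0, "basal")
        b = synth.simulate_rr(cfg, "M001", 12.0, "basal")
        assert np.array_equal(a.intervals, b.intervals)

    def test_distinct_streams_per_context(self):
        cfg = synth.SynthConfig(seed=9)
        a = synth.simulate_rr(cfg, "M001", 12.0, "basal")
        b = synth.simulate_rr(cfg, "M002", 12.0, "basal")
        c = synth.simulate_rr(cfg, "M001", 15.0, "basal")
        assert not np.array_equal(a.intervals[:100], b.intervals[:100])
        assert not np.array_equal(a.intervals[:100], c.intervals[:100])

    def test_silent_config_gives_constant_series(self):
        cfg = synth.SynthConfig(
            seed=0, hf_amp_basal=0.0, noise_sd=0.0, ectopic_rate=0.0,
            vlf_amp_by_age={6.0: 0.0, 30.0: 0.0},
            alternans_pct_by_age={6.0: 0.0, 30.0: 0.0},
            rr_intercept_sd=0.0, aging_rate_sd=0.0)
        rec = synth.simulate_rr(cfg, "M000", 6.0, "basal")
        assert hm.sdnn(rec.intervals) == pytest.approx(0.0, abs=1e-9)

    def test_blockade_suppresses_hf(self):
        cfg = synth.SynthConfig(seed=2)
        hf_basal = _hf_pct_of(cfg, "M000", 6.0, "basal")
        hf_abk = _hf_pct_of(cfg, "M000", 6.0, "abk")
        assert hf_basal >= 2 * hf_abk

    def test_pas_roundtrip_at_50(self):
        vals = [
            _pas_of(synth.SynthConfig(
                seed=s, alternans_pct_by_age={6.0: 50.0, 30.0: 50.0}), "M000", 27.0)
            for s in range(10)
        ]
        assert abs(float(np.mean(vals)) - 50.0) <= 10.0

    def test_pas_monotone_in_knob(self):
        means = []
        for target in (5.0, 15.0, 25.0, 35.0, 45.0):
            cfg_vals = [
                _pas_of(synth.SynthConfig(
                    seed=s, alternans_pct_by_age={6.0: target, 30.0: target}),
                    "M000", 27.0)
                for s in range(10)
            ]
            means.append(float(np.mean(cfg_vals)))
        assert all(b > a for a, b in zip(means[:-1], means[1:]))

    def test_hf_amp_knob_monotone(self):
        means = []
        for amp in (1.0, 2.0, 4.0, 8.0):
            cfg = synth.SynthConfig(seed=3, hf_amp_basal=amp)
            means.append(_hf_pct_of(cfg, "M000", 6.0, "basal"))
        assert all(b > a for a, b in zip(means[:-1], means[1:]))

    def test_intrinsic_rr_rise_about_50_pct(self):
        cfg = synth.SynthConfig(seed=4, rr_intercept_sd=0.0, aging_rate_sd=0.0)
        mu6 = synth.mean_rr_truth(cfg, "M000", 6.0, "abk")
        mu30 = synth.mean_rr_truth(cfg, "M000", 30.0, "abk")
        assert mu30 / mu6 == pytest.approx(1.5, rel=1e-9)
        # stable before the onset age
        assert synth.mean_rr_truth(cfg, "M000", 21.0, "abk") == mu6


class TestSimulateCohort:
    def test_file_roundtrip_and_determinism(self, tmp_path):
        cfg = synth.SynthConfig(n_mice=2, seed=5, visit_ages=(6, 9))
        c1 = synth.simulate_cohort(cfg, outdir=tmp_path / "a")
        c2 = synth.simulate_cohort(cfg, outdir=tmp_path / "b")
        for f in sorted((tmp_path / "a").glob("*.txt")):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
        from hrvaging.io_preprocess import read_rr_file
        row = c1.manifest.table.iloc[0]
        series = read_rr_file(tmp_path / "a" / row["file"])
        key = (row["mouse_id"], row["age_months"], row["state"])
        assert np.allclose(series.intervals, c1.series[key].intervals, atol=1e-5)

    def test_refuses_nonempty_outdir(self, tmp_path):
        (tmp_path / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            synth.simulate_cohort(synth.SynthConfig(n_mice=1, visit_ages=(6,)),
                                  outdir=tmp_path)

    def test_zero_hazard_keeps_all_mice(self):
        cfg = synth.SynthConfig(n_mice=5, seed=1, dropout_hazard=0.0)
        cohort = synth.simulate_cohort(cfg)
        counts = cohort.manifest.table.groupby("age_months")["mouse_id"].nunique()
        assert (counts == 5).all()

    def test_dropout_only_after_onset(self):
        cfg = synth.SynthConfig(n_mice=40, seed=1, dropout_hazard=0.5)
        cohort = synth.simulate_cohort(cfg)
        counts = cohort.manifest.table.groupby("age_months")["mouse_id"].nunique()
        assert (counts.loc[:24.0] == 40).all()
        assert counts.loc[27.0] < 40
        assert counts.loc[30.0] <= counts.loc[27.0]


class TestSimulateMetricTable:
    def test_deterministic_truth_without_noise(self):
        cfg = synth.SynthConfig(n_mice=4, seed=0, lme_truth={
            "m": synth.LMETruth(10.0, 2.0, 0.1, sigma_eps=0.0)})
        tab, _ = simulate_metric_table_ages(cfg)
        for _, row in tab.iterrows():
            a = row["age_months"]
            assert row["value"] == pytest.approx(10.0 + 2.0 * a + 0.1 * a**2)

    def test_reproducible_given_seed(self):
        cfg = synth.SynthConfig(n_mice=4, seed=3)
        t1, _ = synth.simulate_metric_table(cfg)
        t2, _ = synth.simulate_metric_table(cfg)
        assert t1.equals(t2)


def simulate_metric_table_ages(cfg):
    return synth.simulate_metric_table(cfg, ages=(6, 9, 12))
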