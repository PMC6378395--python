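"""Growth-curve machinery, mERG features, and the Bayesian fits."""

import numpy as np
import pandas as pd
import pytest

from quantos.statmodels import (
    McmcConfig,
    extract_merg_features,
    fit_gompertz,
    fit_merg_gamma,
    fit_robust_t,
    gompertz_curve,
    hdi,
)
from quantos.synthetic import (
    render_merg_trace,
    simulate_growth_counts,
    simulate_merg,
)

FAST = McmcConfig(n_steps=1500, n_burn=600, seed=0)


class TestGompertzCurve:
    def test_saturates_at_capacity(self):
        assert gompertz_curve(320.0, 60.0, 11.0, 1e6) == pytest.approx(320.0, rel=1e-9)

    def test_value_at_onset(self):
        # y(lambda) = A * exp(-e)
        assert gompertz_curve(320.0, 60.0, 11.0, 11.0) == pytest.approx(
            320.0 * np.exp(-np.e), rel=1e-12)

    def test_max_slope_equals_mu(self):
        t = np.linspace(0, 60, 60001)
        y = gompertz_curve(320.0, 60.0, 11.0, t)
        assert np.max(np.gradient(y, t)) == pytest.approx(60.0, rel=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gompertz_curve(-1.0, 60.0, 11.0, 5.0)


class TestGompertzFit:
    def test_recovers_generating_values(self):
        # point recovery on one replicate; interval calibration over many
        # replicates is exercised by the acceptance suite
        data = simulate_growth_counts(320.0, 60.0, 11.0, seed=42)
        fit = fit_gompertz(data, mcmc=McmcConfig(seed=1))
        assert np.median(fit.draws["A[LD]"]) == pytest.approx(320.0, rel=0.10)
        assert np.median(fit.draws["mu_M[LD]"]) == pytest.approx(60.0, rel=0.15)
        assert np.median(fit.draws["lambda[LD]"]) == pytest.approx(11.0, abs=0.5)
        assert fit.diagnostics.converged

    def test_condition_onset_difference_detected(self):
        a = simulate_growth_counts(320.0, 60.0, 10.5, condition="LD", seed=7)
        b = simulate_growth_counts(320.0, 60.0, 11.5, condition="DD", seed=8)
        fit = fit_gompertz(pd.concat([a, b], ignore_index=True),
                           mcmc=McmcConfig(seed=2))
        row = fit.contrasts.query("parameter == 'lambda'").iloc[0]
        assert row["excludes_zero"]
        assert row["mean"] < 0  # LD onset earlier

    def test_all_zero_counts_no_crash(self):
        data = simulate_growth_counts(320.0, 60.0, 11.0, seed=3)
        data["count"] = 0
        fit = fit_gompertz(data, mcmc=FAST)
        # capacity posterior collapses toward small values
        assert np.median(fit.draws["A[LD]"]) < 20.0

    def test_negative_counts_rejected(self):
        data = simulate_growth_counts(320.0, 60.0, 11.0, seed=3)
        data.loc[0, "count"] = -1
        with pytest.raises(ValueError, match="non-negative"):
            fit_gompertz(data)

    def test_single_day_condition_rejected(self):
        data = simulate_growth_counts(320.0, 60.0, 11.0, days=[14.0], seed=3)
        with pytest.raises(ValueError, match="days"):
            fit_gompertz(data)

    def test_reproducible_summaries(self):
        data = simulate_growth_counts(320.0, 60.0, 11.0, seed=5)
        s1 = fit_gompertz(data, mcmc=FAST).summary
        s2 = fit_gompertz(data, mcmc=FAST).summary
        assert np.allclose(s1["mean"], s2["mean"])


class TestMergFeatures:
    def test_constructed_trough_and_peak(self):
        trace, onset = render_merg_trace(40.0, 30.0, 80.0, 90.0)
        f = extract_merg_features(trace, 1000.0, onset)
        assert f.a_amplitude == pytest.approx(40.0, rel=0.02)
        assert f.a_latency_ms == pytest.approx(30.0, abs=3.0)
        # b-wave measured from the a-wave trough
        assert f.b_amplitude == pytest.approx(120.0, rel=0.02)
        assert f.b_latency_ms == pytest.approx(90.0, abs=3.0)

    def test_late_trough_ignored_baseline_referenced_b(self):
        trace, onset = render_merg_trace(40.0, 60.0, 80.0, 120.0)
        f = extract_merg_features(trace, 1000.0, onset)
        assert f.a_amplitude is None  # minima only count within 55 ms
        assert f.b_amplitude == pytest.approx(80.0, rel=0.05)

    def test_flat_trace_reports_no_waves(self):
        f = extract_merg_features(np.zeros(400), 1000.0, 0.1)
        assert f.a_amplitude is None and f.b_amplitude is None

    def test_short_trace_errors(self):
        with pytest.raises(ValueError, match="cover"):
            extract_merg_features(np.zeros(100), 1000.0, 0.02)

    def test_replicates_averaged_before_detection(self):
        trace, onset = render_merg_trace(40.0, 30.0, 80.0, 90.0)
        rng = np.random.default_rng(0)
        reps = np.stack([trace + rng.normal(0, 5, len(trace)) for _ in range(3)])
        f = extract_merg_features(reps, 1000.0, onset)
        assert f.b_amplitude == pytest.approx(120.0, rel=0.1)

    def test_renderer_round_trip(self):
        # generator-specified amplitudes survive the filter chain within 2%
        trace, onset = render_merg_trace(25.0, 35.0, 60.0, 95.0)
        f = extract_merg_features(trace, 1000.0, onset)
        assert f.a_amplitude == pytest.approx(25.0, rel=0.02)
        assert f.b_amplitude == pytest.approx(85.0, rel=0.02)


class TestMergGamma:
    def test_recovery_and_contrast(self):
        amp = simulate_merg({"DD": 30.0, "LD": 60.0}, sigma=20.0, n_mice=4,
                            n_channels=50, seed=5)
        fit = fit_merg_gamma(amp, mcmc=McmcConfig(seed=3))
        mu_dd = np.median(fit.draws["mu[DD]"])
        mu_ld = np.median(fit.draws["mu[LD]"])
        assert mu_dd == pytest.approx(30.0, rel=0.15)
        assert mu_ld == pytest.approx(60.0, rel=0.15)
        row = fit.contrasts.query("parameter == 'mu'").iloc[0]
        assert row["excludes_zero"]

    def test_zero_effect_calibration(self):
        """Null condition effects: the mu contrast HDI contains 0 in >= 85%
        of seeded replications."""
        hits = 0
        n_runs = 20
        for k in range(n_runs):
            amp = simulate_merg({"a": 40.0, "b": 40.0}, sigma=15.0, n_mice=3,
                                n_channels=20, mouse_sd=0.08, seed=600 + k)
            fit = fit_merg_gamma(amp, mcmc=McmcConfig(n_steps=1500, n_burn=600, seed=k))
            row = fit.contrasts.query("parameter == 'mu'").iloc[0]
            hits += not row["excludes_zero"]
        assert hits >= int(0.85 * n_runs)

    def test_nonpositive_amplitude_rejected(self):
        amp = simulate_merg({"DD": 30.0}, seed=1)
        amp.loc[0, "amplitude"] = 0.0
        with pytest.raises(ValueError, match="> 0"):
            fit_merg_gamma(amp)

    def test_gamma_mean_sd_parameterization(self):
        amp = simulate_merg({"DD": 30.0}, sigma=6.0, n_mice=2, n_channels=4000,
                            mouse_sd=1e-9, seed=9)
        assert amp["amplitude"].mean() == pytest.approx(30.0, rel=0.02)
        assert amp["amplitude"].std() == pytest.approx(6.0, rel=0.05)


class TestRobustT:
    @staticmethod
    def _table(shift, n=20, outliers=0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(1.0, 0.3, n)
        b = rng.normal(1.0 + shift, 0.3, n)
        if outliers:
            b[:outliers] += 10.0
        return pd.DataFrame({
            "value": np.r_[a, b],
            "condition": ["a"] * n + ["b"] * n,
            "mouse": [f"a{i % 4}" for i in range(n)] + [f"b{i % 4}" for i in range(n)],
        })

    def test_two_sigma_difference_detected(self):
        fit = fit_robust_t(self._table(0.6, seed=1), mcmc=McmcConfig(seed=1))
        assert fit.contrasts.iloc[0]["excludes_zero"]

    def test_identical_groups_calibration(self):
        hits = 0
        n_runs = 20
        for k in range(n_runs):
            fit = fit_robust_t(self._table(0.0, seed=700 + k),
                               mcmc=McmcConfig(n_steps=1200, n_burn=500, seed=k))
            hits += not fit.contrasts.iloc[0]["excludes_zero"]
        assert hits >= int(0.85 * n_runs)

    def test_outlier_robust_mean(self):
        tab = self._table(0.0, n=20, outliers=3, seed=2)
        fit = fit_robust_t(tab, mcmc=McmcConfig(seed=2))
        clean_mean = 1.0
        naive_shift = tab.query("condition == 'b'")["value"].mean() - clean_mean
        robust_shift = np.median(fit.draws["mu[b]"]) - clean_mean
        assert abs(robust_shift) < 0.5 * abs(naive_shift)

    def test_single_condition_rejected(self):
        tab = self._table(0.0).query("condition == 'a'")
        with pytest.raises(ValueError, match="2 conditions"):
            fit_robust_t(tab)


def test_hdi_matches_arviz():
    rng = np.random.default_rng(4)
    draws = rng.gamma(3.0, 2.0, 20_000)
    import arviz as az

    lo, hi = hdi(draws, 0.89)
    ref = az.hdi(draws, hdi_prob=0.89)
    assert lo == pytest.approx(ref[0], rel=0.02)
    assert hi == pytest.approx(ref[1], rel=0.02)
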