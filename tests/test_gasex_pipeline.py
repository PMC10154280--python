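"""Headspace correction, unit bridging, and the three response-curve fits."""

import numpy as np
import pandas as pd
import pytest

from ccmgasex import gasex_pipeline as gx


def make_records(reference, delta, flow=400.0, subflow=233.0, **overrides):
    n = len(reference)
    base = {
        "sample_id": ["s1"] * n,
        "replicate": [1] * n,
        "temperature_c": [40.0] * n,
        "o2_percent": [21.0] * n,
        "ph": [2.0] * n,
        "reference_co2_ppm": reference,
        "delta_co2_ppm": delta,
        "flow_umol_s": [flow] * n,
        "subsample_flow_umol_s": [subflow] * n,
        "incident_light": [2000.0] * n,
        "assimilation": [1.0] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestHeadspaceCorrection:
    def test_zero_drawdown_returns_reference(self):
        df = gx.headspace_co2(make_records([400.0], [0.0]))
        assert df["headspace_co2_ppm"].iloc[0] == pytest.approx(400.0)
        assert df.attrs["n_clamped"] == 0

    def test_hand_checked_subsample_arithmetic(self):
        # sample chamber 380; delta_sub = 400/233*20 = 34.33; headspace 345.67
        df = gx.headspace_co2(make_records([400.0], [20.0]))
        assert df["headspace_co2_ppm"].iloc[0] == pytest.approx(345.67, abs=0.01)

    def test_negative_raw_value_clamped_and_flagged(self):
        df = gx.headspace_co2(make_records([55.0], [25.0]))
        assert df["headspace_co2_ppm"].iloc[0] == 0.0
        assert bool(df["headspace_clamped"].iloc[0])
        assert df.attrs["n_clamped"] == 1

    def test_nonpositive_flow_rejected(self):
        with pytest.raises(ValueError, match="flow"):
            gx.headspace_co2(make_records([400.0], [0.0], flow=0.0))

    def test_fuzzed_records_never_negative(self):
        """10^4 random records: the clamp guarantees nonnegative output and
        the clamp count matches the flags."""
        rng = np.random.default_rng(7)
        n = 10_000
        df = make_records(
            rng.uniform(0, 2000, n), rng.uniform(-100, 500, n),
            flow=1.0,  # replaced next line with a column
        )
        df["flow_umol_s"] = rng.uniform(50, 800, n)
        df["subsample_flow_umol_s"] = rng.uniform(50, 800, n)
        out = gx.headspace_co2(df)
        assert (out["headspace_co2_ppm"] >= 0).all()
        assert out.attrs["n_clamped"] == int(out["headspace_clamped"].sum())


class TestUnitBridging:
    def test_zero_and_reference_values(self):
        curve = gx.ResponseCurve("headspace_co2_ppm",
                                 np.array([0.0, 400.0]), np.array([0.0, 1.0]))
        out = gx.to_dissolved(curve, 40.0)
        assert out.driver == "dissolved_co2_uM"
        assert out.x[0] == 0.0
        assert out.x[1] == pytest.approx(9.6, rel=0.01)

    def test_order_preserved(self):
        x = np.linspace(0, 2000, 30)
        out = gx.to_dissolved(
            gx.ResponseCurve("headspace_co2_ppm", x, np.zeros_like(x)), 40.0)
        assert np.all(np.diff(out.x) > 0)

    def test_wrong_driver_rejected(self):
        curve = gx.ResponseCurve("incident_light", np.array([10.0, 20.0]),
                                 np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="headspace"):
            gx.to_dissolved(curve, 40.0)

    def test_fit_then_convert_commutes_with_convert_then_fit(self):
        """Gamma fitted in ppm then Henry-converted agrees with Gamma fitted
        on the dissolved curve within 0.5% (near-linear mapping <= 100 ppm)."""
        x = np.array([10.0, 25.0, 50.0, 75.0, 100.0])
        a = 0.1 * x - 4.0  # Gamma = 40 ppm exactly
        ppm_curve = gx.ResponseCurve("headspace_co2_ppm", x, a)
        gamma_ppm = gx.fit_compensation_point(ppm_curve).gamma
        gamma_a = gx.to_dissolved(
            gx.ResponseCurve("headspace_co2_ppm",
                             np.array([gamma_ppm]), np.array([0.0])), 40.0).x[0]
        um_curve = gx.to_dissolved(ppm_curve, 40.0)
        gamma_b = gx.fit_compensation_point(um_curve, threshold=1e9).gamma
        assert gamma_a == pytest.approx(gamma_b, rel=5e-3)


class TestMichaelisMentenFit:
    grid = np.array([25.0, 50.0, 100.0, 200.0, 400.0, 800.0])

    def mm_curve(self, amax=35.0, km=150.0, x=None, noise=None):
        x = self.grid if x is None else x
        a = amax * x / (km + x)
        if noise is not None:
            a = a + noise
        return gx.ResponseCurve("headspace_co2_ppm", x, a)

    def test_exact_recovery_on_noise_free_data(self):
        fit = gx.fit_michaelis_menten(self.mm_curve())
        assert fit.km == pytest.approx(150.0, rel=1e-6)
        assert fit.amax == pytest.approx(35.0, rel=1e-6)

    def test_cutoff_filter_is_strict(self):
        fit = gx.fit_michaelis_menten(self.mm_curve(), max_driver=700.0)
        assert fit.n_points_used == 5
        assert fit.km == pytest.approx(150.0, rel=1e-6)

    def test_point_order_invariance(self):
        perm = np.random.default_rng(1).permutation(len(self.grid))
        shuffled = gx.ResponseCurve("headspace_co2_ppm",
                                    self.grid[perm],
                                    (35.0 * self.grid / (150.0 + self.grid))[perm])
        fit = gx.fit_michaelis_menten(shuffled)
        assert fit.km == pytest.approx(150.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(gx.InsufficientDataError):
            gx.fit_michaelis_menten(self.mm_curve(x=np.array([50.0, 100.0])))

    def test_ci_coverage_over_seeded_simulations(self):
        """True Km inside the 95% CI in >= 90% of 500 noisy fits (sd = 5%
        of Amax)."""
        rng = np.random.default_rng(42)
        x = np.array([10., 25., 50., 75., 100., 150., 200., 300., 400., 700.,
                      1000., 1500.])
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            noise = rng.normal(0, 0.05 * 35.0, size=x.size)
            curve = self.mm_curve(x=x, noise=noise)
            fit = gx.fit_michaelis_menten(curve)
            if abs(fit.km - 150.0) <= fit.ci_km:
                hits += 1
        assert hits / n_sims >= 0.90


class TestCompensationPointFit:
    def test_exact_line(self):
        curve = gx.ResponseCurve("headspace_co2_ppm",
                                 np.array([20.0, 60.0, 100.0]),
                                 np.array([-2.0, 2.0, 6.0]))
        fit = gx.fit_compensation_point(curve)
        assert fit.gamma == pytest.approx(40.0, rel=1e-12)
        assert fit.slope == pytest.approx(0.1, rel=1e-12)

    def test_points_above_threshold_ignored(self):
        base = gx.ResponseCurve("headspace_co2_ppm",
                                np.array([20.0, 60.0, 100.0]),
                                np.array([-2.0, 2.0, 6.0]))
        extended = gx.ResponseCurve("headspace_co2_ppm",
                                    np.array([20.0, 60.0, 100.0, 400.0, 900.0]),
                                    np.array([-2.0, 2.0, 6.0, 30.0, -5.0]))
        assert gx.fit_compensation_point(extended).gamma == pytest.approx(
            gx.fit_compensation_point(base).gamma, rel=1e-12)

    def test_threshold_inclusive(self):
        curve = gx.ResponseCurve("headspace_co2_ppm",
                                 np.array([50.0, 100.0]), np.array([0.0, 5.0]))
        assert gx.fit_compensation_point(curve).n_points_used == 2

    def test_degenerate_slope_rejected(self):
        curve = gx.ResponseCurve("headspace_co2_ppm",
                                 np.array([20.0, 60.0, 100.0]),
                                 np.array([6.0, 2.0, -2.0]))
        with pytest.raises(gx.FitError, match="slope"):
            gx.fit_compensation_point(curve)


class TestKokFit:
    def test_exact_line_recovers_respiration(self):
        curve = gx.ResponseCurve("incident_light",
                                 np.array([10.0, 20.0, 30.0]),
                                 0.05 * np.array([10.0, 20.0, 30.0]) - 3.0)
        fit = gx.fit_kok(curve)
        assert fit.rl == pytest.approx(3.0, rel=1e-12)
        assert fit.slope == pytest.approx(0.05, rel=1e-12)

    def test_points_outside_window_ignored(self):
        x = np.array([5.0, 10.0, 20.0, 30.0, 100.0, 500.0])
        a = 0.05 * x - 3.0
        a[-2:] = [20.0, 34.0]  # saturated points must not leak into the fit
        fit = gx.fit_kok(gx.ResponseCurve("incident_light", x, a))
        assert fit.n_points_used == 3
        assert fit.rl == pytest.approx(3.0, rel=1e-12)

    def test_rl_to_amax_ratio_form(self):
        # ratio of a Kok respiration to a maximal assimilation, as used by
        # the compensation-point model
        assert 3.5 / 27.0 == pytest.approx(0.13, abs=0.002)

    def test_insufficient_window_points_rejected(self):
        curve = gx.ResponseCurve("incident_light",
                                 np.array([50.0, 100.0]), np.array([1.0, 2.0]))
        with pytest.raises(gx.InsufficientDataError):
            gx.fit_kok(curve)


class TestOxygenResponseAnalysis:
    def o2_table(self, slopes, intercept=0.4, noise=None, seed=0):
        o = np.array([20.0, 209.0, 398.0])
        rows = []
        rng = np.random.default_rng(seed)
        for rep, slope in enumerate(slopes):
            eps = rng.normal(0, noise, size=o.size) if noise else np.zeros_like(o)
            for o_uM, e in zip(o, eps):
                rows.append({"replicate": rep, "o2_uM": o_uM,
                             "gamma_uM": slope * o_uM + intercept + e})
        return pd.DataFrame(rows)

    def test_exact_shared_line_gives_zero_se(self):
        res = gx.oxygen_response_analysis(self.o2_table([0.005] * 6))
        assert res.slope_mean_pM_per_uM == pytest.approx(5000.0, rel=1e-9)
        assert res.slope_2se_pM_per_uM == pytest.approx(0.0, abs=1e-6)
        assert res.balanced

    def test_single_replicate_flags_undefined_se(self):
        res = gx.oxygen_response_analysis(self.o2_table([0.005]))
        assert res.n_replicates == 1
        assert not res.se_defined
        assert np.isnan(res.slope_2se_pM_per_uM)

    def test_monte_carlo_recovery_of_measured_scale_slope(self):
        """6 replicates, true slope 5000 pM/uM, Gamma noise sd 0.1 uM:
        the mean +/- 2 SE band over 6 replicate slopes (5 dof) covers
        P(|t5|<2) ~ 0.90 of draws; assert >= 0.87 over 1000 runs."""
        hits = 0
        n_sims = 1000
        for seed in range(n_sims):
            res = gx.oxygen_response_analysis(
                self.o2_table([0.005] * 6, noise=0.1, seed=seed))
            if abs(res.slope_mean_pM_per_uM - 5000.0) <= res.slope_2se_pM_per_uM:
                hits += 1
        assert hits / n_sims >= 0.87

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            gx.oxygen_response_analysis(pd.DataFrame({"o2_uM": [1, 2]}))


class TestPhComparisonTests:
    def test_exact_two_to_one_ratio_centres_half_mean_test(self):
        rep = gx.ph_comparison_tests([200.0, 210.0, 220.0], [100.0, 105.0, 110.0])
        assert rep.half_mean.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.half_mean.pvalue == pytest.approx(0.5, abs=1e-9)

    def test_identical_groups(self):
        vals = [10.0, 12.0, 14.0, 11.0]
        rep = gx.ph_comparison_tests(vals, vals)
        # symmetric null for the plain greater test
        assert rep.greater.pvalue == pytest.approx(0.5, abs=1e-9)
        # pH6 values are double the halved pH2 sample, so the "pH6 is half"
        # alternative is strongly contradicted
        assert rep.half_mean.pvalue > 0.95

    def test_halved_ph6_supports_half_mean_alternative(self):
        rng = np.random.default_rng(3)
        ph2 = 200.0 + rng.normal(0, 5, 6)
        ph6 = 0.4 * ph2  # clearly below half
        rep = gx.ph_comparison_tests(ph2, ph6)
        assert rep.half_mean.pvalue < 0.05

    def test_too_few_replicates_rejected(self):
        with pytest.raises(gx.InsufficientDataError):
            gx.ph_comparison_tests([1.0], [2.0, 3.0])


class TestRecordsRoundTrip:
    def test_read_records_schema_check(self, tmp_path):
        df = make_records([400.0, 300.0], [5.0, 4.0])
        path = tmp_path / "records.csv"
        df.to_csv(path, index=False)
        back = gx.read_records(path)
        assert list(back.columns) == list(df.columns)
        bad = df.drop(columns=["delta_co2_ppm"])
        bad_path = tmp_path / "bad.csv"
        bad.to_csv(bad_path, index=False)
        with pytest.raises(ValueError, match="delta_co2_ppm"):
            gx.read_records(bad_path)

    def test_curves_from_records_groups_by_replicate(self):
        df = pd.concat([
            make_records([400.0, 200.0], [0.0, 0.0]),
            make_records([400.0, 200.0], [0.0, 0.0]).assign(replicate=2),
        ])
        curves = gx.curves_from_records(df)
        assert len(curves) == 2
        assert all(len(c) == 2 for c in curves)
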