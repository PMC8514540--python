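"""4PL dose-response: dilution arithmetic, normalization, fitting,
parameter recovery, potency comparison."""

import numpy as np
import pytest

import hcscreen as h


class TestDilutionSeries:
    def test_sixfold_from_100uM_second_point(self):
        cond = h.TreatmentCondition(components=(("lomustine", 1.0),),
                                    top_concentration=100.0)
        series = h.make_dilution_series(cond)["lomustine"]
        assert series[0] == 100.0
        assert series[1] == pytest.approx(16.7, abs=0.05)

    def test_unit_dilution_factor_is_constant_series(self):
        cond = h.TreatmentCondition(components=(("x", 1.0),),
                                    top_concentration=10.0,
                                    dilution_factor=1.0, n_points=5)
        np.testing.assert_allclose(h.make_dilution_series(cond)["x"], 10.0)

    def test_mixture_ratio_scales_co_component(self):
        cond = h.TreatmentCondition(
            components=(("lomustine", 1.0), ("mln8237", 0.1)),
            top_concentration=10.0, n_points=3)
        series = h.make_dilution_series(cond)
        assert series["mln8237"][0] == pytest.approx(1.0)
        np.testing.assert_allclose(series["mln8237"],
                                   series["lomustine"] * 0.1)

    def test_nonpositive_top_rejected(self):
        with pytest.raises(ValueError):
            h.TreatmentCondition(components=(("x", 1.0),), top_concentration=0.0)


class TestNormalization:
    def test_control_mean_maps_to_100(self):
        out = h.normalize_to_control([200.0], [180.0, 220.0])
        assert out[0] == pytest.approx(100.0)

    def test_zero_maps_to_zero_and_linearity(self):
        out = h.normalize_to_control([0.0, 50.0, 150.0], [100.0, 100.0])
        np.testing.assert_allclose(out, [0.0, 50.0, 150.0])

    def test_idempotent_on_normalized_data(self):
        data = np.array([40.0, 100.0, 160.0])
        again = h.normalize_to_control(data, [100.0])
        np.testing.assert_allclose(again, data)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            h.normalize_to_control([1.0], [0.0])


def _exact_curve(pic50, bottom, hill=1.0, top=100.0, n_points=8,
                 top_conc=100.0, reps=1, noise_sd=0.0, rng=None):
    conc = np.repeat(top_conc / 6.0 ** np.arange(n_points), reps)
    resp = h.four_param_logistic(conc, bottom, top, pic50, hill)
    if noise_sd:
        resp = resp + rng.normal(0.0, noise_sd, conc.size)
    return h.DoseResponseCurve(concentrations=conc, responses=resp)


class TestFit4PL:
    def test_noise_free_self_consistency(self):
        fit = h.fit_4pl(_exact_curve(5.0, 0.0))
        assert fit.converged
        assert fit.pic50 == pytest.approx(5.0, abs=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-5)
        # fitted curve passes through 50% at the IC50
        mid = h.four_param_logistic(h.pIC50_to_IC50(fit.pic50), fit.bottom,
                                    fit.top, fit.pic50, fit.hill)
        assert mid == pytest.approx((fit.top + fit.bottom) / 2, abs=1e-4)

    def test_too_few_concentrations_rejected(self):
        curve = h.DoseResponseCurve(np.array([10.0, 1.0, 0.1]),
                                    np.array([10.0, 60.0, 95.0]))
        with pytest.raises(ValueError, match="4 distinct"):
            h.fit_4pl(curve)

    def test_flat_response_reports_nonconverged_not_exception(self):
        rng = np.random.default_rng(0)
        curve = _exact_curve(9.0, 99.0, noise_sd=0.0)
        curve.responses = 100.0 + rng.normal(0, 1.0, curve.responses.size)
        fit = h.fit_4pl(curve)
        assert not fit.converged
        assert "no measurable dose effect" in fit.status
        assert np.isnan(fit.pic50)

    def test_concentration_rescaling_shifts_pic50_by_one(self):
        base = _exact_curve(5.0, 10.0, hill=1.3)
        shifted = h.DoseResponseCurve(base.concentrations * 10.0, base.responses)
        f0, f1 = h.fit_4pl(base), h.fit_4pl(shifted)
        assert f1.pic50 - f0.pic50 == pytest.approx(-1.0, abs=1e-6)

    def test_zero_dose_points_excluded_from_fit(self):
        base = _exact_curve(5.0, 0.0)
        with_zero = h.DoseResponseCurve(
            np.concatenate([base.concentrations, [0.0, 0.0]]),
            np.concatenate([base.responses, [100.0, 100.0]]))
        f = h.fit_4pl(with_zero)
        assert f.n_obs == base.concentrations.size
        assert f.pic50 == pytest.approx(5.0, abs=1e-6)


class TestParameterRecovery:
    @pytest.mark.parametrize("pic50", [4.5, 5.5, 6.5])
    @pytest.mark.parametrize("bottom", [0.0, 20.0, 50.0])
    def test_bias_and_coverage_over_simulation_grid(self, pic50, bottom):
        """n = 4 replicates with 5% Gaussian noise, 100 seeded simulations:
        |bias| < 0.05 log units and 95% CI coverage within [90%, 99%]."""
        errors, covered = [], 0
        n_sims = 100
        # dose the series so the 8-point sixfold ladder straddles the IC50
        top_conc = 10.0 ** (6.0 - pic50) * 6.0 ** 3.5
        for seed in range(n_sims):
            rng = np.random.default_rng(10_000 + seed)
            curve = _exact_curve(pic50, bottom, reps=4, noise_sd=5.0,
                                 top_conc=top_conc, rng=rng)
            fit = h.fit_4pl(curve)
            assert fit.converged
            errors.append(fit.pic50 - pic50)
            lo, hi = fit.pic50_ci95
            covered += lo <= pic50 <= hi
        assert abs(np.mean(errors)) < 0.05
        assert 0.90 * n_sims <= covered <= 0.99 * n_sims


class TestPotency:
    def test_pic50_to_ic50_table_row(self):
        assert h.pIC50_to_IC50(4.50) == pytest.approx(31.6, abs=0.05)

    @pytest.mark.parametrize("pic50,um", [(6.0, 1.0), (0.0, 1e6)])
    def test_round_powers_of_ten(self, pic50, um):
        assert h.pIC50_to_IC50(pic50) == pytest.approx(um)

    def _fit(self, pic50, rng):
        return h.fit_4pl(_exact_curve(pic50, 0.0, reps=4, noise_sd=3.0, rng=rng))

    def test_identical_fits_compare_as_equal(self):
        fit = self._fit(5.0, np.random.default_rng(1))
        diff, z, p = h.compare_pIC50(fit, fit)
        assert diff == 0 and z == 0 and p == pytest.approx(1.0)

    def test_normal_quantile_identity(self):
        rng = np.random.default_rng(2)
        a, b = self._fit(5.0, rng), self._fit(5.0, rng)
        delta = 1.959963984540054 * np.hypot(a.se_pic50, b.se_pic50)
        a.pic50 = b.pic50 + delta
        _, _, p = h.compare_pIC50(a, b)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_nonconverged_input_rejected(self):
        good = self._fit(5.0, np.random.default_rng(3))
        bad = h.DoseResponseFit(
            pic50=float("nan"), pic50_ci95=(np.nan, np.nan), bottom=np.nan,
            bottom_ci95=(np.nan, np.nan), hill=np.nan, top=100.0,
            converged=False, status="x", rss=np.nan)
        with pytest.raises(ValueError):
            h.compare_pIC50(good, bad)

    def test_true_potency_shift_detected_with_power(self):
        """True delta-pIC50 of 1.0 at modest noise is flagged at P < 0.05
        in at least 95 of 100 seeded simulations."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(20_000 + seed)
            a = self._fit(5.5, rng)
            b = self._fit(4.5, rng)
            diff, _, p = h.compare_pIC50(a, b)
            hits += (p < 0.05) and (diff > 0)
        assert hits >= 95
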