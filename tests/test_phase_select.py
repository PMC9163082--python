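"""Cycle-curve fitting, extreme-phase selection and EF estimation."""

import warnings

import numpy as np
import pytest

from cinephase import (CycleCurve, CycleCurveModel, FitSpec, auto_ef, estimate_ef,
                       fit_curve, generate, select_phases)

from conftest import small_spec


def _curve(values, metric="volume"):
    values = np.asarray(values, dtype=float)
    return CycleCurve(metric, np.arange(len(values)), values)


class TestFitCurve:
    def test_poly4_interpolates_its_own_model_class(self):
        x = np.arange(13, dtype=float)
        y = 0.01 * x**4 - 0.3 * x**3 + 2 * x**2 - x + 500
        xs, ys, diag = fit_curve(_curve(y), FitSpec(method="poly4"))
        assert np.max(np.abs(diag["residuals"])) / np.max(np.abs(y)) < 1e-8

    @pytest.mark.parametrize("method", ["poly4", "gp"])
    def test_constant_values_give_constant_fit(self, method):
        xs, ys, _ = fit_curve(_curve(np.full(11, 42.0)), FitSpec(method=method))
        np.testing.assert_allclose(ys, 42.0, rtol=1e-6)

    def test_gp_mean_tracks_smooth_low_noise_curve(self):
        # cross-check against a direct kernel-ridge solve with the fitted
        # hyperparameters: identical jitter, identical kernel
        x = np.arange(13, dtype=float)
        y = 500 - 200 * np.sin(np.pi * x / 12.0)
        spec = FitSpec(method="gp", gp_jitter=1e-6, seed=0)
        model = CycleCurveModel(_curve(y), spec)
        res = model.fit()
        gp = res.diagnostics["model"]
        K = gp.kernel_(x[:, None]) + spec.gp_jitter * np.eye(len(x))
        z = (y - y.mean()) / y.std()
        alpha = np.linalg.solve(K, z)
        pred = gp.kernel_(x[:, None]) @ alpha * y.std() + y.mean()
        obs_pred = np.interp(x, res.fitted_x, res.fitted_y)
        np.testing.assert_allclose(obs_pred, pred, rtol=1e-5)
        np.testing.assert_allclose(pred, y, rtol=1e-3)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_curve(_curve([1, 2, 3, 4]), FitSpec(method="poly4"))
        with pytest.raises(ValueError, match="at least 3"):
            fit_curve(_curve([1, 2]), FitSpec(method="gp"))

    def test_nonfinite_values_raise(self):
        vals = np.ones(11)
        vals[3] = np.nan
        with pytest.raises(ValueError):
            fit_curve(CycleCurve("volume", np.arange(11), vals), FitSpec())


class TestSelectPhases:
    def test_gp_recovers_cosine_truth(self):
        res = generate(small_spec(seed=2, cycle_shape="cosine"))
        from cinephase import cycle_curve
        sel = select_phases(cycle_curve(res.series, "volume"),
                            FitSpec(method="gp", seed=0))
        assert sel.systole_phase == res.systole_phase
        assert sel.diastole_phase == res.diastole_phase

    def test_monotone_fallback_warns_and_uses_raw_extrema(self):
        sel = select_phases(_curve(np.linspace(100, 200, 11)),
                            FitSpec(method="gp", seed=0))
        assert any("monotone" in w for w in sel.warnings)
        assert sel.diastole_phase == 10
        assert sel.systole_phase == 0

    def test_skewed_gp_matches_data_argminmax(self):
        res = generate(small_spec(seed=4, cycle_shape="skewed"))
        from cinephase import cycle_curve
        curve = cycle_curve(res.series, "volume")
        sel = select_phases(curve, FitSpec(method="gp", seed=0))
        assert sel.systole_phase == int(np.argmin(curve.values))
        assert sel.diastole_phase == int(np.argmax(curve.values))

    def test_fitted_diastole_value_above_systole(self):
        res = generate(small_spec(seed=6))
        from cinephase import cycle_curve
        sel = select_phases(cycle_curve(res.series, "slice_area"), FitSpec(seed=0))
        at = lambda ph: np.interp(ph, sel.fitted_x, sel.fitted_y)
        assert at(sel.diastole_phase) >= at(sel.systole_phase)

    @pytest.mark.parametrize("method", ["poly4", "gp"])
    def test_affine_invariance_of_selection(self, method):
        res = generate(small_spec(seed=3))
        from cinephase import cycle_curve
        curve = cycle_curve(res.series, "volume")
        spec = FitSpec(method=method, seed=0)
        base = select_phases(curve, spec)
        scaled = CycleCurve("volume", curve.phase_indices, 3.7 * curve.values + 120.0)
        sel = select_phases(scaled, spec)
        assert (sel.systole_phase, sel.diastole_phase) == \
               (base.systole_phase, base.diastole_phase)


class TestEstimateEF:
    def test_definition(self, small_result):
        sel = select_phases(
            _curve([v for v in np.linspace(300, 150, 11)][::-1]), FitSpec(seed=0))
        # direct formula check on the synthetic truth phases
        from cinephase import PhaseSelection
        sel = PhaseSelection(systole_phase=small_result.systole_phase,
                             diastole_phase=small_result.diastole_phase,
                             fitted_x=np.array([0.0]), fitted_y=np.array([0.0]),
                             method="gp", metric="volume")
        ef = estimate_ef(small_result.series, sel)
        assert ef.ef_pct == pytest.approx(small_result.ef_pct, abs=1e-12)
        assert ef.edv_ul == pytest.approx(small_result.edv_ul)
        assert ef.esv_ul == pytest.approx(small_result.esv_ul)

    def test_mis_selection_gives_negative_ef_with_warning(self, small_result):
        from cinephase import PhaseSelection
        sel = PhaseSelection(systole_phase=small_result.diastole_phase,
                             diastole_phase=small_result.systole_phase,
                             fitted_x=np.array([0.0]), fitted_y=np.array([0.0]),
                             method="gp", metric="volume")
        with pytest.warns(UserWarning, match="negative"):
            ef = estimate_ef(small_result.series, sel)
        assert ef.ef_pct < 0


class TestAutoEF:
    def test_deterministic_given_seed(self, small_result):
        a = auto_ef(small_result.series, "slice_area", FitSpec(method="gp", seed=11))
        b = auto_ef(small_result.series, "slice_area", FitSpec(method="gp", seed=11))
        assert a[0].ef_pct == b[0].ef_pct
        assert (a[1].systole_phase, a[1].diastole_phase) == \
               (b[1].systole_phase, b[1].diastole_phase)
        np.testing.assert_array_equal(a[1].fitted_y, b[1].fitted_y)

    def test_volume_and_slice_area_agree_on_clean_data(self, small_result):
        _, sel_v, _ = auto_ef(small_result.series, "volume", FitSpec(seed=0))
        _, sel_a, _ = auto_ef(small_result.series, "slice_area", FitSpec(seed=0))
        assert sel_v.systole_phase == sel_a.systole_phase
        assert sel_v.diastole_phase == sel_a.diastole_phase

    def test_ef_identity_holds_to_machine_precision(self, small_result):
        ef, _, _ = auto_ef(small_result.series, "slice_area", FitSpec(seed=0))
        assert ef.ef_pct == pytest.approx(
            100.0 * (1.0 - ef.esv_ul / ef.edv_ul), abs=1e-9)

    def test_summary_mentions_selected_phases(self, small_result):
        from cinephase import cycle_curve
        res = CycleCurveModel(cycle_curve(small_result.series, "volume"),
                              FitSpec(seed=0)).fit()
        text = res.summary()
        assert "diastole phase" in text and "systole phase" in text
        assert str(res.systole_phase) in text
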