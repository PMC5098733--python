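import numpy as np
import pytest
from scipy.signal import fftconvolve

import pdtmri.dce as dce
from pdtmri import (
    AIFModel,
    VoxelGrid,
    build_phantom,
    classify_enhancement,
    compute_auc,
    evaluate_aif,
    simulate_dce_series,
    tk_forward,
)
from pdtmri.containers import ParameterMap
from pdtmri.dce import ConcentrationSeries, TKFitResultMaps, ToftsModel, apply_qc_filters
from pdtmri.errors import ProtocolError


def numeric_tk(ktrans_per_min, ve, aif, t_end_s, dt=0.01):
    """Independent oracle: trapezoidal convolution of the AIF with the kernel.

    Integrates in time since bolus arrival, where both factors are smooth,
    so the trapezoid rule is second-order accurate.
    """
    tp = np.arange(0.0, t_end_s - aif.onset_s, dt)
    cp = aif.a1_mM * np.exp(-tp / aif.tau1_s) + aif.a2_mM * np.exp(-tp / aif.tau2_s)
    kt_s = ktrans_per_min / 60.0
    kern = np.exp(-(kt_s / ve) * tp)
    conv = fftconvolve(cp, kern)[: tp.size]
    # trapezoid rule: discrete convolution minus half the endpoint terms
    trap = conv - 0.5 * (cp[0] * kern + cp * kern[0])
    return aif.onset_s + tp, kt_s * trap * dt


def _series_from_curves(times, curves, injection_s=120.0, r1_pre=0.5):
    curves = np.asarray(curves, dtype=float)
    nvox = curves.shape[0]
    grid = VoxelGrid(nvox, 1, 1, 1.0, 1.0)
    return ConcentrationSeries(
        grid,
        times,
        curves.reshape(nvox, 1, 1, -1),
        np.full(grid.shape, r1_pre),
        injection_s,
    )


class TestAIF:
    def test_peak_at_onset_is_sum_of_amplitudes(self, aif):
        assert evaluate_aif(aif, [aif.onset_s])[0] == pytest.approx(6.63)

    def test_causality_and_decay(self, aif):
        t = np.array([0.0, aif.onset_s - 1e-9, aif.onset_s + 1e4])
        cp = evaluate_aif(aif, t)
        assert cp[0] == 0.0 and cp[1] == 0.0
        assert cp[2] < 1e-4 * (aif.a1_mM + aif.a2_mM)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AIFModel(tau1_s=0.0)


class TestTKForward:
    def test_zero_ktrans_gives_zero_curve(self, aif):
        assert np.all(tk_forward(0.0, 0.3, aif, np.arange(0, 900, 3.5)) == 0.0)

    def test_closed_form_matches_trapezoidal_convolution(self, aif):
        t, oracle = numeric_tk(0.11, 0.3, aif, 900.0)
        closed = tk_forward(0.11, 0.3, aif, t)
        scale = oracle.max()
        assert np.max(np.abs(closed - oracle)) / scale < 1e-3

    def test_ve_zero_with_uptake_rejected(self, aif):
        with pytest.raises(ValueError):
            tk_forward(0.1, 0.0, aif, np.arange(10.0))

    def test_long_time_limit_vanishes(self, aif):
        late = tk_forward(0.2, 0.3, aif, np.array([aif.onset_s + 1e6]))
        assert late[0] < 1e-6

    def test_minute_to_second_unit_conversion_guard(self, aif):
        """K^trans in min^-1 must equal a hand-built s^-1 computation (60x factor)."""
        t = np.arange(0, 900, 3.5)
        kt_min, ve = 0.3, 0.25
        kt_s = kt_min / 60.0
        kep = kt_s / ve
        tp = (t - aif.onset_s).clip(0)
        expected = np.zeros_like(t)
        for amp, tau in ((aif.a1_mM, aif.tau1_s), (aif.a2_mM, aif.tau2_s)):
            expected += kt_s * amp * (np.exp(-tp / tau) - np.exp(-kep * tp)) / (kep - 1 / tau)
        expected *= t >= aif.onset_s
        np.testing.assert_allclose(tk_forward(kt_min, ve, aif, t), expected, rtol=1e-12)


class TestSignalToConcentration:
    def test_noiseless_round_trip_through_simulator(self, study_phantom, protocol, aif):
        gt = study_phantom
        dyn = simulate_dce_series(gt, protocol, aif)
        tissue = gt.tissue_mask
        r1_map = ParameterMap(gt.grid, 1000.0 / gt.t1_ms, "s^-1", tissue)
        zeta_map = ParameterMap(gt.grid, gt.zeta, "dimensionless")
        conc = dce.signal_to_concentration(dyn, r1_map, protocol, zeta_map)
        kt = gt.ktrans_per_min.ravel()
        truth = tk_forward(
            kt, np.where(kt > 0, gt.ve_fraction.ravel(), 1.0), aif, protocol.dce_times_s
        ).reshape(conc.conc_mM.shape)
        err = np.abs(conc.conc_mM - truth)[tissue]
        assert np.nanmax(err) / truth.max() < 1e-6

    def test_known_rate_difference_maps_to_concentration(self):
        # R1(t) = 1.156, R1_pre = 0.45, r1 = 3.53 -> 0.2 mM
        assert (1.156 - 0.45) / 3.53 == pytest.approx(0.2, abs=5e-4)

    def test_flat_signal_gives_zero_concentration(self, protocol):
        grid = VoxelGrid(2, 2, 1, 1.0, 1.0)
        times = protocol.dce_times_s
        from pdtmri.containers import ContrastAxis, ImageStack
        from pdtmri.spgr import spgr_signal

        r1 = 0.5
        sig = spgr_signal(1000.0, np.deg2rad(protocol.dce_flip_deg), protocol.dce_tr_ms, r1)
        dyn = ImageStack(
            grid, np.full(grid.shape + times.shape, sig), ContrastAxis("time", times)
        )
        r1_map = ParameterMap(grid, np.full(grid.shape, r1), "s^-1")
        conc = dce.signal_to_concentration(dyn, r1_map, protocol)
        np.testing.assert_allclose(conc.conc_mM, 0.0, atol=1e-9)

    def test_missing_pre_injection_frames_rejected(self, protocol, study_phantom, aif):
        from pdtmri.containers import ContrastAxis, ImageStack

        dyn = simulate_dce_series(study_phantom, protocol, aif)
        late = ImageStack(
            dyn.grid,
            dyn.frames[..., 40:],
            ContrastAxis("time", dyn.contrast_axis.values[40:]),
        )
        r1_map = ParameterMap(
            study_phantom.grid, 1000.0 / study_phantom.t1_ms, "s^-1"
        )
        with pytest.raises(ProtocolError):
            dce.signal_to_concentration(late, r1_map, protocol)


class TestClassifier:
    times = np.arange(0.0, 900.0, 3.5)

    def test_rule_application(self):
        pre = self.times < 120.0
        rng = np.random.default_rng(0)
        weak = np.where(pre, rng.normal(0, 0.1, self.times.size), 0.05)
        strong = np.where(pre, rng.normal(0, 0.05, self.times.size), 1.0)
        conc = _series_from_curves(self.times, [weak, strong])
        enhanced = classify_enhancement(conc)
        assert not enhanced[0, 0, 0]  # 0.05 < 2 * 0.1
        assert enhanced[1, 0, 0]  # 1.0 >= 2 * 0.05

    def test_false_positive_rate_matches_monte_carlo_null(self):
        """Pure-noise voxels: the median-vs-2SD rule almost never fires."""
        rng = np.random.default_rng(7)
        n = 4000
        curves = rng.normal(0, 0.1, (n, self.times.size))
        conc = _series_from_curves(self.times, curves)
        rate = classify_enhancement(conc).mean()
        # independent Monte-Carlo of the same statistic
        pre = self.times < 120.0
        draws = rng.normal(0, 0.1, (n, self.times.size))
        null = np.median(draws[:, ~pre], axis=1) >= 2 * draws[:, pre].std(axis=1, ddof=1)
        assert abs(rate - null.mean()) < 0.01
        assert rate < 0.05


class TestAUC:
    def test_constant_concentration_rectangle(self):
        times = np.arange(0.0, 903.0, 3.0)  # frames exactly at 120 and 900
        curve = np.where(times >= 120.0, 1.0, 0.0)
        conc = _series_from_curves(times, [curve])
        auc = compute_auc(conc)
        assert auc.values[0, 0, 0] == pytest.approx(780.0)

    def test_linearity(self, aif):
        times = np.arange(0.0, 900.0, 3.5)
        ct = tk_forward(0.2, 0.3, aif, times)
        conc = _series_from_curves(times, [ct, 3.0 * ct])
        auc = compute_auc(conc)
        assert auc.values[1, 0, 0] == pytest.approx(3.0 * auc.values[0, 0, 0], rel=1e-12)

    def test_monotone_in_ktrans(self, aif):
        times = np.arange(0.0, 900.0, 3.5)
        kts = np.array([0.01, 0.05, 0.1, 0.2, 0.5, 1.0])
        curves = tk_forward(kts, np.full_like(kts, 0.3), aif, times)
        conc = _series_from_curves(times, curves)
        aucs = compute_auc(conc).values[:, 0, 0]
        assert np.all(np.diff(aucs) > 0)


class TestToftsFit:
    def test_noiseless_recovery_at_protocol_sampling(self, protocol, aif):
        times = protocol.dce_times_s
        curves = tk_forward(
            np.array([0.11, 0.3]), np.array([0.3, 0.2]), aif, times
        )
        conc = _series_from_curves(times, curves, protocol.injection_time_s)
        res = ToftsModel(conc, aif).fit()
        kt = res.maps.ktrans_per_min.values[:, 0, 0]
        ve = res.maps.ve_fraction.values[:, 0, 0]
        np.testing.assert_allclose(kt, [0.11, 0.3], rtol=0.01)
        np.testing.assert_allclose(ve, [0.3, 0.2], rtol=0.01)
        np.testing.assert_allclose(res.maps.r_squared[:, 0, 0], 1.0, atol=1e-9)

    def test_zero_curve_is_not_included_after_qc(self, protocol, aif):
        times = protocol.dce_times_s
        conc = _series_from_curves(times, [np.zeros_like(times)], protocol.injection_time_s)
        res = ToftsModel(conc, aif).fit()
        enhanced = classify_enhancement(conc)
        included, _ = res.apply_qc(enhanced)
        assert not included.any()


class TestQCFilters:
    def _maps(self, kt, ve, r2, ttp, conv=None):
        n = len(kt)
        grid = VoxelGrid(n, 1, 1, 1.0, 1.0)
        shape = grid.shape
        conv = np.ones(shape, bool) if conv is None else np.asarray(conv).reshape(shape)
        return TKFitResultMaps(
            grid=grid,
            ktrans_per_min=ParameterMap(grid, np.reshape(kt, shape), "min^-1", conv),
            ve_fraction=ParameterMap(grid, np.reshape(ve, shape), "dimensionless", conv),
            r_squared=np.reshape(r2, shape),
            time_to_peak_s=np.reshape(ttp, shape),
            converged=conv,
        )

    def test_per_criterion_bookkeeping_fixture(self):
        # 5 voxels: one fails each criterion, the last passes all
        maps = self._maps(
            kt=[0.1, 0.1, 0.1, -0.1, 0.1],
            ve=[0.3, 0.3, 0.3, 0.3, 0.3],
            r2=[0.95, 0.5, 0.95, 0.95, 0.95],
            ttp=[100.0, 100.0, 900.0, 100.0, 100.0],
        )
        enhanced = np.array([False, True, True, True, True]).reshape(5, 1, 1)
        included, counts = apply_qc_filters(maps, enhanced)
        assert counts == {
            "non_enhanced": 1,
            "low_r_squared": 1,
            "late_peak": 1,
            "nonphysiological": 1,
            "included": 1,
        }
        assert included[4, 0, 0] and included.sum() == 1

    def test_r_squared_boundary_is_strict(self):
        maps = self._maps(kt=[0.1], ve=[0.3], r2=[0.80], ttp=[100.0])
        included, _ = apply_qc_filters(maps, np.ones((1, 1, 1), bool))
        assert not included.any()

    def test_all_pass_reduces_to_enhanced_mask(self):
        maps = self._maps(kt=[0.1] * 4, ve=[0.3] * 4, r2=[0.9] * 4, ttp=[100.0] * 4)
        enhanced = np.array([True, False, True, False]).reshape(4, 1, 1)
        included, _ = apply_qc_filters(maps, enhanced)
        np.testing.assert_array_equal(included, enhanced)

    def test_composition_equals_intersection_of_masks(self, rng):
        n = 200
        maps = self._maps(
            kt=rng.uniform(-0.1, 0.5, n),
            ve=rng.uniform(-0.1, 1.2, n),
            r2=rng.uniform(0.5, 1.0, n),
            ttp=rng.uniform(0.0, 1200.0, n),
        )
        enhanced = rng.random((n, 1, 1)) > 0.3
        included, _ = apply_qc_filters(maps, enhanced)
        kt = maps.ktrans_per_min.values
        ve = maps.ve_fraction.values
        manual = (
            enhanced
            & (maps.r_squared > 0.80)
            & (maps.time_to_peak_s < 800.0)
            & (kt >= 0)
            & (ve >= 0)
            & (ve <= 1)
        )
        np.testing.assert_array_equal(included, manual)
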