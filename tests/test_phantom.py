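import numpy as np
import pytest

from pdtmri import (
    AcquisitionProtocol,
    CompartmentParams,
    NoiseSpec,
    TreatmentEffectSpec,
    VoxelGrid,
    add_noise,
    apply_treatment_effect,
    build_phantom,
    simulate_dce_series,
    simulate_dwi_series,
    simulate_echo_series,
    simulate_vfa_series,
)
from pdtmri.errors import ConfigError
from pdtmri.phantom import DEFAULT_COMPARTMENTS, LABELS
from pdtmri.spgr import spgr_signal


class TestBuildPhantom:
    def test_uniform_table_constant_zeta_gives_exact_values(self, small_grid):
        gt = build_phantom(small_grid, seed=3, zeta_range=(1.0, 1.0))
        tumor = gt.tumor_mask
        p = DEFAULT_COMPARTMENTS["tumor-core"]
        assert np.all(gt.t1_ms[tumor] == p.t1_ms)
        assert np.all(gt.ktrans_per_min[tumor] == p.ktrans_per_min)
        assert np.all(gt.zeta == 1.0)

    def test_seed_determinism_bit_identical(self, study_grid):
        a = build_phantom(study_grid, seed=7)
        b = build_phantom(study_grid, seed=7)
        for name in ("t1_ms", "t2_ms", "adc_mm2_s", "ktrans_per_min", "zeta", "m0"):
            assert np.array_equal(getattr(a, name), getattr(b, name))
        assert np.array_equal(a.labels, b.labels)

    def test_tumor_volume_matches_analytic_ellipsoid(self, study_grid):
        semi = (8.0, 8.0, 3.0)
        gt = build_phantom(study_grid, seed=0, tumor_semiaxes_vox=semi)
        n_tumor = int(gt.tumor_mask.sum())
        analytic = 4.0 / 3.0 * np.pi * semi[0] * semi[1] * semi[2]
        # voxelization error bounded by a one-voxel surface shell
        shell = 4.0 * np.pi * (max(semi) + 0.5) ** 2 / (semi[0] / semi[2])
        assert abs(n_tumor - analytic) < shell

    def test_unknown_compartment_rejected(self, small_grid):
        table = dict(DEFAULT_COMPARTMENTS)
        table["liver"] = CompartmentParams(800, 40, 1e-3, 0.1, 0.2)
        with pytest.raises(ConfigError, match="liver"):
            build_phantom(small_grid, table)

    def test_zeta_field_within_requested_range(self, study_phantom):
        assert study_phantom.zeta.min() >= 0.9 - 1e-12
        assert study_phantom.zeta.max() <= 1.1 + 1e-12


class TestTreatmentEffect:
    def test_identity_effect_preserves_ground_truth(self, small_phantom):
        out = apply_treatment_effect(small_phantom, TreatmentEffectSpec())
        assert np.array_equal(out.ktrans_per_min, small_phantom.ktrans_per_min)
        assert np.array_equal(out.t1_ms, small_phantom.t1_ms)

    def test_full_core_fraction_shuts_down_all_tumor(self, small_phantom):
        out = apply_treatment_effect(
            small_phantom, TreatmentEffectSpec(nonenhanced_core_fraction=1.0)
        )
        assert np.all(out.ktrans_per_min[out.tumor_mask] == 0.0)

    def test_core_voxel_count_matches_requested_fraction(self, study_phantom):
        n_tumor = int(study_phantom.tumor_mask.sum())
        out = apply_treatment_effect(
            study_phantom, TreatmentEffectSpec(nonenhanced_core_fraction=0.77)
        )
        n_core = int((out.ktrans_per_min[out.tumor_mask] == 0).sum())
        assert abs(n_core - 0.77 * n_tumor) <= 1

    def test_input_not_mutated_and_nontumor_untouched(self, small_phantom):
        before = small_phantom.adc_mm2_s.copy()
        out = apply_treatment_effect(
            small_phantom,
            TreatmentEffectSpec(nonenhanced_core_fraction=0.5, adc_scale=1.5),
        )
        assert np.array_equal(small_phantom.adc_mm2_s, before)
        non_tumor = ~small_phantom.tumor_mask
        assert np.array_equal(out.adc_mm2_s[non_tumor], before[non_tumor])

    def test_reciprocal_scales_restore_periphery(self, small_phantom):
        eff = TreatmentEffectSpec(ktrans_scale=0.5, adc_scale=1.3, r1_scale=1.2, r2_scale=1.1)
        inv = TreatmentEffectSpec(
            ktrans_scale=2.0, adc_scale=1 / 1.3, r1_scale=1 / 1.2, r2_scale=1 / 1.1
        )
        out = apply_treatment_effect(apply_treatment_effect(small_phantom, eff), inv)
        tumor = small_phantom.tumor_mask
        np.testing.assert_allclose(
            out.ktrans_per_min[tumor], small_phantom.ktrans_per_min[tumor], rtol=1e-12
        )
        np.testing.assert_allclose(out.t1_ms[tumor], small_phantom.t1_ms[tumor], rtol=1e-12)


class TestSimulators:
    def test_vfa_signal_peaks_near_ernst_angle(self, protocol):
        t1, tr = 1500.0, protocol.tr_ms
        flips = np.asarray(protocol.flip_deg_list)
        signals = spgr_signal(1.0, np.deg2rad(flips), tr, 1000.0 / t1)
        ernst = np.degrees(np.arccos(np.exp(-tr / t1)))
        assert flips[np.argmax(signals)] == flips[np.argmin(np.abs(flips - ernst))]

    def test_zero_flip_angle_gives_zero_signal(self):
        assert spgr_signal(1.0, 0.0, 20.0, 0.5) == 0.0

    def test_vfa_linear_in_m0(self, small_phantom, protocol):
        doubled = small_phantom.copy()
        doubled.m0 = 2.0 * doubled.m0
        np.testing.assert_allclose(
            simulate_vfa_series(doubled, protocol).frames,
            2.0 * simulate_vfa_series(small_phantom, protocol).frames,
        )

    def test_echo_series_definition_and_monotonicity(self, small_phantom, protocol):
        stack = simulate_echo_series(small_phantom, protocol)
        te = np.asarray(protocol.te_list_ms)
        i, j, k = np.argwhere(small_phantom.tumor_mask)[0]
        m0, t2 = small_phantom.m0[i, j, k], small_phantom.t2_ms[i, j, k]
        np.testing.assert_allclose(stack.frames[i, j, k], m0 * np.exp(-te / t2))
        # first TE 0.9 ms at T2 = 30 ms: exp(-0.03)
        assert np.exp(-0.9 / 30.0) == pytest.approx(0.9704455, abs=1e-6)
        assert np.all(np.diff(stack.frames[i, j, k]) < 0)

    def test_dwi_b0_equals_m0_and_known_attenuation(self, protocol):
        grid = VoxelGrid(4, 4, 1, 1.0, 1.0)
        table = {
            name: CompartmentParams(p.t1_ms, p.t2_ms, 1.0e-3, p.ktrans_per_min, p.ve_fraction, p.m0)
            if name != "background"
            else p
            for name, p in DEFAULT_COMPARTMENTS.items()
        }
        gt = build_phantom(grid, table, seed=0)
        stack = simulate_dwi_series(gt, protocol)
        coords = stack.contrast_axis.values
        b0_frames = stack.frames[..., coords[:, 1] == 0]
        tissue = gt.tissue_mask
        assert np.all(b0_frames[tissue] == gt.m0[tissue][:, None])
        b400 = stack.frames[..., (coords[:, 0] == 0) & (coords[:, 1] == 400)][..., 0]
        np.testing.assert_allclose(b400[tissue], gt.m0[tissue] * np.exp(-0.4))
        # isotropic truth: all directions carry identical frames
        for d in (1, 2):
            np.testing.assert_array_equal(
                stack.frames[..., coords[:, 0] == 0], stack.frames[..., coords[:, 0] == d]
            )

    def test_dce_flat_when_no_uptake(self, small_grid, protocol, aif):
        table = {
            name: CompartmentParams(p.t1_ms, p.t2_ms, p.adc_mm2_s, 0.0, p.ve_fraction, p.m0)
            for name, p in DEFAULT_COMPARTMENTS.items()
        }
        gt = build_phantom(small_grid, table, seed=0)
        stack = simulate_dce_series(gt, protocol, aif)
        np.testing.assert_array_equal(
            stack.frames, np.repeat(stack.frames[..., :1], stack.n_frames, axis=-1)
        )

    def test_dce_signal_rises_after_injection(self, small_phantom, protocol, aif):
        stack = simulate_dce_series(small_phantom, protocol, aif)
        times = stack.contrast_axis.values
        pre = int((times < protocol.injection_time_s).sum())
        tumor = small_phantom.tumor_mask
        assert np.all(
            stack.frames[tumor, pre] >= stack.frames[tumor, pre - 1] - 1e-12
        )


class TestNoise:
    def test_zero_sigma_identity(self, small_phantom, protocol):
        stack = simulate_echo_series(small_phantom, protocol)
        out = add_noise(stack, NoiseSpec("gaussian", 0.0, seed=1))
        np.testing.assert_array_equal(out.frames, stack.frames)

    def test_seed_reproducibility(self, small_phantom, protocol):
        stack = simulate_echo_series(small_phantom, protocol)
        a = add_noise(stack, NoiseSpec("rician", 5.0, seed=42))
        b = add_noise(stack, NoiseSpec("rician", 5.0, seed=42))
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_rician_floor_on_zero_signal(self):
        from pdtmri.containers import ContrastAxis, ImageStack

        grid = VoxelGrid(64, 64, 4, 1.0, 1.0)
        stack = ImageStack(grid, np.zeros(grid.shape + (4,)), ContrastAxis("time", np.arange(4)))
        sigma = 3.0
        out = add_noise(stack, NoiseSpec("rician", sigma, seed=5))
        # magnitude of pure complex noise is Rayleigh with mean sigma*sqrt(pi/2)
        assert out.frames.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)
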