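"""R2* log-linear fit, VFA R1, and R2' derivation."""

import numpy as np
import pytest

from wmfp import MGREParams, ParameterMap, VFAParams, derive_r2prime, fit_r1_vfa, fit_r2star
from wmfp.relaxometry import mgre_signal, spgr_signal


class TestR2Star:
    def test_constant_signal_gives_zero_decay(self):
        stack = np.full((2, 2, 2, 8), 100.0)
        r2s, s0 = fit_r2star(stack, MGREParams())
        assert np.allclose(r2s.data, 0.0)
        assert np.allclose(s0.data, 100.0)

    def test_exact_recovery_of_forward_decay(self):
        # truth matches the reported track-WM R2* of 21.7 s^-1
        params = MGREParams()
        truth = np.full((3, 3, 3), 21.7)
        stack = mgre_signal(np.full(truth.shape, 100.0), truth, params)
        r2s, s0 = fit_r2star(stack, params)
        assert np.max(np.abs(r2s.data - 21.7) / 21.7) < 1e-9
        assert np.max(np.abs(s0.data - 100.0) / 100.0) < 1e-9

    def test_monte_carlo_bias_at_snr_100(self, rng):
        params = MGREParams()
        n = 10_000
        truth = np.full((n, 1, 1), 21.7)
        clean = mgre_signal(np.full(truth.shape, 100.0), truth, params)
        noisy = np.abs(clean + rng.normal(0.0, 1.0, clean.shape))
        r2s, _ = fit_r2star(noisy, params)
        bias = abs(np.nanmean(r2s.data) - 21.7) / 21.7
        assert bias < 0.02

    def test_nonpositive_voxel_flagged_nan_not_raised(self):
        stack = np.full((2, 1, 1, 8), 50.0)
        stack[0, 0, 0, 3] = 0.0
        r2s, _ = fit_r2star(stack, MGREParams())
        assert np.isnan(r2s.data[0, 0, 0]) and np.isfinite(r2s.data[1, 0, 0])

    def test_fewer_than_three_echoes_rejected(self):
        with pytest.raises(ValueError):
            MGREParams(echo_times_ms=(2.0, 5.0))
        with pytest.raises(ValueError):
            fit_r2star(np.ones((2, 2, 2, 5)), MGREParams())  # stack/TE mismatch


class TestVFA:
    @pytest.mark.parametrize("t1_s", [0.5, 1.0 / 1.07, 1.0, 2.0])
    def test_round_trip_over_t1_grid(self, t1_s):
        params = VFAParams()
        r1_true = 1.0 / t1_s
        vols = [spgr_signal(100.0, np.full((2, 2, 2), r1_true), fa, params.tr_ms)
                for fa in params.flip_angles_deg]
        r1 = fit_r1_vfa(vols[0], vols[1], params)
        assert np.max(np.abs(r1.data - r1_true) / r1_true) < 1e-9

    def test_b1_corrected_angles_restore_truth(self):
        params = VFAParams()
        b1 = 0.9
        vols = [spgr_signal(100.0, np.full((2, 2, 2), 1.0), fa * b1, params.tr_ms)
                for fa in params.flip_angles_deg]
        biased = fit_r1_vfa(vols[0], vols[1], params)  # no correction
        corrected = fit_r1_vfa(vols[0], vols[1], params, b1=b1)
        assert abs(biased.data[0, 0, 0] - 1.0) > 1e-3
        assert np.max(np.abs(corrected.data - 1.0)) < 1e-9

    def test_spoiling_correction_hook_applies_to_t1(self):
        params = VFAParams()
        vols = [spgr_signal(100.0, np.full((2, 2, 2), 1.0), fa, params.tr_ms)
                for fa in params.flip_angles_deg]
        r1 = fit_r1_vfa(vols[0], vols[1], params,
                        spoiling_correction=lambda t1: 2.0 * t1)
        assert np.allclose(r1.data, 0.5, rtol=1e-9)

    def test_noise_bias_at_snr_100(self, rng):
        params = VFAParams()
        shape = (10_000, 1, 1)
        vols = [spgr_signal(100.0, np.full(shape, 1.0), fa, params.tr_ms)
                for fa in params.flip_angles_deg]
        noisy = [np.abs(v + rng.normal(0.0, v.mean() / 100.0, v.shape)) for v in vols]
        r1 = fit_r1_vfa(noisy[0], noisy[1], params)
        assert abs(np.nanmean(r1.data) - 1.0) < 0.02


class TestR2Prime:
    def test_reported_f_wm_and_c_wm_cells(self):
        # printed R2* and R2 for the frontal and central subtypes
        for r2s_v, r2_v, expected in [(21.1, 17.9, 3.2), (20.4, 17.2, 3.2)]:
            r2s = ParameterMap(np.full((2, 2, 2), r2s_v), "R2star", "s")
            r2 = ParameterMap(np.full((2, 2, 2), r2_v), "R2", "s")
            r2p = derive_r2prime(r2s, r2)
            assert np.allclose(r2p.data, expected, atol=1e-12)

    def test_zero_map_when_equal_and_algebraic_identity(self, rng):
        a = rng.normal(20, 3, (4, 4, 4))
        b = rng.normal(17, 2, (4, 4, 4))
        r2s = ParameterMap(a, "R2star", "s")
        r2 = ParameterMap(b, "R2", "s")
        assert np.allclose(derive_r2prime(r2s, r2.with_data(a, "R2")).data, 0.0)
        assert np.array_equal(derive_r2prime(r2s, r2).data + b, a)

    def test_negative_values_retained_and_counted(self):
        r2s = ParameterMap(np.full((2, 2, 2), 15.0), "R2star", "s")
        r2 = ParameterMap(np.full((2, 2, 2), 17.0), "R2", "s")
        out = derive_r2prime(r2s, r2)
        assert np.all(out.data < 0) and out.n_negative == 8

    def test_grid_mismatch_rejected(self):
        r2s = ParameterMap(np.zeros((2, 2, 2)), "R2star", "s")
        r2 = ParameterMap(np.zeros((3, 3, 3)), "R2", "s")
        with pytest.raises(ValueError, match="grid mismatch"):
            derive_r2prime(r2s, r2)
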