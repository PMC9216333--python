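import numpy as np
import pytest

from conftest import FLIP_ANGLES, TR_MS, vfa_grid_search_oracle
from marrowscope.errors import FitError, SpecValidationError
from marrowscope.relaxometry import (
    ConcentrationCurve,
    DCESeries,
    R1Fit,
    VFASeries,
    concentration_curve,
    concentration_from_r1,
    estimate_fbv_ps,
    fit_permeability,
    fit_vfa_r1,
    parametric_map,
    post_contrast_r1,
    spgr_signal,
)
from marrowscope.synthetic import DCEPhantomSpec, generate_vfa_dce


def _clean_vfa(r1=1.0, s0=1000.0):
    signals = spgr_signal(s0, r1, FLIP_ANGLES, TR_MS)
    return VFASeries(signals=signals, flip_angles=FLIP_ANGLES, tr=TR_MS)


class TestVfaFit:
    def test_noiseless_recovery(self):
        fit = fit_vfa_r1(_clean_vfa(r1=1.0, s0=1000.0))
        assert fit.r1 == pytest.approx(1.0, rel=1e-6)
        assert fit.s0 == pytest.approx(1000.0, rel=1e-6)

    @pytest.mark.parametrize("r1", [0.4, 1.3, 2.8])
    def test_recovery_across_r1_range(self, r1):
        fit = fit_vfa_r1(_clean_vfa(r1=r1))
        assert fit.r1 == pytest.approx(r1, rel=1e-6)

    def test_flat_signals_error(self):
        series = VFASeries(signals=np.full(7, 500.0), flip_angles=FLIP_ANGLES, tr=TR_MS)
        with pytest.raises(FitError):
            fit_vfa_r1(series)

    def test_all_zero_signals_error(self):
        series = VFASeries(signals=np.zeros(7), flip_angles=FLIP_ANGLES, tr=TR_MS)
        with pytest.raises(FitError):
            fit_vfa_r1(series)

    def test_noisy_median_matches_grid_oracle(self):
        # 1% Gaussian noise, 200 replicates at r1 = 1.0 1/s
        truth = spgr_signal(1000.0, 1.0, FLIP_ANGLES, TR_MS)
        rng = np.random.default_rng(42)
        fits, oracles = [], []
        for _ in range(200):
            noisy = np.clip(truth + rng.normal(0.0, 0.01 * truth.max(), truth.shape), 0, None)
            fits.append(fit_vfa_r1(VFASeries(signals=noisy, flip_angles=FLIP_ANGLES, tr=TR_MS)).r1)
            oracles.append(vfa_grid_search_oracle(noisy, FLIP_ANGLES, TR_MS)[0])
        assert np.median(fits) == pytest.approx(1.0, rel=0.02)
        assert np.median(fits) == pytest.approx(np.median(oracles), rel=0.02)

    def test_too_few_angles_rejected(self):
        with pytest.raises(SpecValidationError, match="flip_angles"):
            VFASeries(signals=np.ones(2), flip_angles=np.array([10.0, 30.0]), tr=TR_MS)


class TestPostContrastInversion:
    def test_identity_at_precontrast_signal(self):
        pre = R1Fit(r1=1.2, s0=1000.0, residual_norm=0.0)
        s = spgr_signal(1000.0, 1.2, 50.0, TR_MS)
        assert post_contrast_r1(s, pre, 50.0, TR_MS) == pytest.approx(1.2, abs=1e-9)

    def test_round_trip(self):
        pre = R1Fit(r1=1.0, s0=1000.0, residual_norm=0.0)
        s = spgr_signal(1000.0, 2.5, 50.0, TR_MS)
        assert post_contrast_r1(s, pre, 50.0, TR_MS) == pytest.approx(2.5, rel=1e-9)

    def test_zero_signal_is_error(self):
        pre = R1Fit(r1=1.0, s0=1000.0, residual_norm=0.0)
        with pytest.raises(FitError):
            post_contrast_r1(0.0, pre, 50.0, TR_MS)

    def test_saturation_is_error(self):
        pre = R1Fit(r1=1.0, s0=1000.0, residual_norm=0.0)
        sat = 1000.0 * np.sin(np.deg2rad(50.0))
        with pytest.raises(FitError, match="saturation"):
            post_contrast_r1(sat * 1.01, pre, 50.0, TR_MS)

    def test_monotone_in_signal(self):
        pre = R1Fit(r1=1.0, s0=1000.0, residual_norm=0.0)
        signals = np.linspace(100.0, 700.0, 20)
        r1s = [post_contrast_r1(s, pre, 50.0, TR_MS) for s in signals]
        assert np.all(np.diff(r1s) > 0)


class TestConcentration:
    def test_linear_relation(self):
        c, n = concentration_from_r1(2.45, 1.0, relaxivity=145.0)
        assert c == pytest.approx(0.01)
        assert n == 0

    def test_no_contrast_zero(self):
        c, n = concentration_from_r1(1.0, 1.0, relaxivity=145.0)
        assert c == 0.0 and n == 0

    def test_negative_clamped_and_counted(self):
        c, n = concentration_from_r1(np.array([0.9, 1.1]), 1.0, relaxivity=145.0)
        np.testing.assert_allclose(c, [0.0, 0.1 / 145.0])
        assert n == 1

    def test_bad_relaxivity(self):
        with pytest.raises(SpecValidationError, match="relaxivity"):
            concentration_from_r1(1.0, 1.0, relaxivity=-1.0)


def _curve_from(normalized, relaxivity=145.0):
    normalized = np.asarray(normalized, dtype=float)
    return ConcentrationCurve(
        c_tissue=normalized, c_blood=np.ones_like(normalized), normalized=normalized,
        relaxivity=relaxivity,
    )


class TestPermeabilityFit:
    def test_exact_linear_input(self):
        t = np.arange(25.0, 250.0, 25.0)
        fit = fit_permeability(_curve_from(0.208 + (0.01 / 60.0) * t), t)
        assert fit.fbv == pytest.approx(0.208, rel=1e-12)
        assert fit.ps == pytest.approx(0.01, rel=1e-12)

    def test_constant_input_zero_slope(self):
        t = np.arange(25.0, 250.0, 25.0)
        fit = fit_permeability(_curve_from(np.full_like(t, 0.15)), t)
        assert fit.fbv == pytest.approx(0.15)
        assert fit.ps == pytest.approx(0.0, abs=1e-15)

    def test_time_unit_safety(self):
        t_s = np.arange(25.0, 250.0, 25.0)
        y = 0.2 + 0.005 / 60.0 * t_s
        fit_s = fit_permeability(_curve_from(y), t_s, time_unit="s")
        fit_m = fit_permeability(_curve_from(y), t_s / 60.0, time_unit="min")
        assert fit_s.ps == pytest.approx(fit_m.ps, rel=1e-12)
        assert fit_s.ps == pytest.approx(0.005, rel=1e-12)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_permeability(_curve_from([0.2, np.nan]), np.array([0.0, 25.0]))

    def test_nan_points_dropped_not_imputed(self):
        t = np.array([25.0, 50.0, 75.0, 100.0])
        y = np.array([0.2, np.nan, 0.2, 0.2])
        fit = fit_permeability(_curve_from(y), t)
        assert fit.dropped_points == 1
        assert fit.n_points == 3


class TestFullChain:
    def test_round_trip_noiseless(self):
        spec = DCEPhantomSpec(true_fbv=0.208, true_ps=0.004, noise_sd=0.0)
        vfa, dce, truth = generate_vfa_dce(spec)
        fit = estimate_fbv_ps(vfa, dce)
        assert fit.fbv == pytest.approx(0.208, rel=1e-6)
        assert fit.ps == pytest.approx(0.004, rel=1e-6)

    def test_ps_monotone_in_truth(self):
        estimates = []
        for ps in (0.0, 0.002, 0.004, 0.01):
            vfa, dce, _ = generate_vfa_dce(DCEPhantomSpec(true_ps=ps, noise_sd=0.0))
            estimates.append(estimate_fbv_ps(vfa, dce).ps)
        assert np.all(np.diff(estimates) > 0)

    def test_fbv_invariant_to_common_signal_rescale(self):
        vfa, dce, _ = generate_vfa_dce(DCEPhantomSpec(noise_sd=0.0))
        fit = estimate_fbv_ps(vfa, dce)
        scaled_vfa = VFASeries(signals=vfa.signals * 3.0, flip_angles=vfa.flip_angles, tr=vfa.tr)
        scaled_dce = DCESeries(
            tissue_signals=dce.tissue_signals * 3.0,
            blood_signals=dce.blood_signals * 3.0,
            times=dce.times,
            flip_angle_post=dce.flip_angle_post,
            tr=dce.tr,
        )
        scaled_fit = estimate_fbv_ps(scaled_vfa, scaled_dce)
        assert scaled_fit.fbv == pytest.approx(fit.fbv, rel=1e-9)
        assert scaled_fit.ps == pytest.approx(fit.ps, rel=1e-9)


def _two_region_stacks(ps_left=0.0, ps_right=0.02, shape=(20, 20), snr=50.0, seed=1):
    h, w = shape
    times = np.arange(25.0, 250.0, 25.0)
    c_blood = 0.3
    ps_true = np.full(shape, ps_left)
    ps_true[:, w // 2 :] = ps_right
    s0, r1_pre, relaxivity = 1000.0, 1.0, 145.0
    vfa = spgr_signal(s0, r1_pre, FLIP_ANGLES, TR_MS)[:, None, None] * np.ones((1, h, w))
    c_t = (0.208 + ps_true[None] * times[:, None, None] / 60.0) * c_blood
    dyn = spgr_signal(s0, r1_pre + relaxivity * c_t, 50.0, TR_MS)
    blood = spgr_signal(s0, r1_pre + relaxivity * c_blood, 50.0, TR_MS) * np.ones_like(times)
    rng = np.random.default_rng(seed)
    sd = vfa.max() / snr
    vfa = np.clip(vfa + rng.normal(0, sd, vfa.shape), 0, None)
    dyn = np.clip(dyn + rng.normal(0, sd, dyn.shape), 0, None)
    return vfa, dyn, blood, times, ps_true


class TestParametricMap:
    def test_uniform_phantom_constant_map(self):
        vfa, dyn, blood, times, _ = _two_region_stacks(ps_left=0.01, ps_right=0.01, snr=1e12)
        mask = np.ones(vfa.shape[1:], dtype=bool)
        maps = parametric_map(vfa, dyn, blood, times, FLIP_ANGLES, 50.0, TR_MS, mask)
        assert maps.n_failed == 0
        np.testing.assert_allclose(maps.ps_map, 0.01, rtol=1e-5)
        np.testing.assert_allclose(maps.fbv_map, 0.208, rtol=1e-5)

    def test_two_region_recovery_at_snr_50(self):
        vfa, dyn, blood, times, ps_true = _two_region_stacks()
        mask = np.ones(vfa.shape[1:], dtype=bool)
        maps = parametric_map(vfa, dyn, blood, times, FLIP_ANGLES, 50.0, TR_MS, mask)
        w = mask.shape[1]
        left = np.nanmean(maps.ps_map[:, : w // 2])
        right = np.nanmean(maps.ps_map[:, w // 2 :])
        assert right == pytest.approx(0.02, rel=0.05)
        assert abs(left) < 0.05 * 0.02  # zero region: absolute bound at 5% of the contrast
    def test_mask_mean_is_mean_of_unflagged_pixels(self):
        vfa, dyn, blood, times, _ = _two_region_stacks()
        mask = np.ones(vfa.shape[1:], dtype=bool)
        maps = parametric_map(vfa, dyn, blood, times, FLIP_ANGLES, 50.0, TR_MS, mask)
        good = mask & ~maps.failed
        assert maps.fbv_mean == pytest.approx(np.mean(maps.fbv_map[good]))

    def test_empty_mask_is_error(self):
        vfa, dyn, blood, times, _ = _two_region_stacks()
        with pytest.raises(SpecValidationError, match="mask"):
            parametric_map(vfa, dyn, blood, times, FLIP_ANGLES, 50.0, TR_MS,
                           np.zeros(vfa.shape[1:], dtype=bool))
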