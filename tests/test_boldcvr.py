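import numpy as np
import pytest

from cvrquant.boldcvr import (
    BoldCvrModel,
    BoldStudy,
    adjust_cvr,
    align_etco2,
    compute_cvr_map,
    fit_glm,
    preprocess,
    roi_summary,
)
from cvrquant.capno import EtCO2Curve, EtCO2Summary, detect_envelope, summarize
from cvrquant.errors import AlignmentError, ParameterError, ShapeError
from cvrquant.protocol import bold_protocol
from cvrquant.synthgen import GroundTruth, generate_bold_series, generate_capno_trace


def small_study(data, tr=1.5, mask=None):
    return BoldStudy(data=data, tr=tr, mask=mask)


def block_curve(n=200, tr=1.5, lo=38.0, hi=46.0):
    """Simple two-level regressor resampled onto the frame grid."""
    t = np.arange(n) * tr
    protocol = bold_protocol(tr=tr, n_dynamics=n)
    values = np.where(protocol.is_hypercapnic(t), hi, lo)
    return EtCO2Curve(t, values).resample(t)


class TestPreprocess:
    def test_fwhm_zero_leaves_data_unchanged(self):
        rng = np.random.default_rng(0)
        data = 1000.0 + rng.normal(0, 5, (8, 8, 4, 20))
        out = preprocess(small_study(data), fwhm=0.0)
        np.testing.assert_array_equal(out.data, data)

    def test_uniform_volume_invariant_under_smoothing(self):
        data = np.full((10, 10, 6, 12), 500.0)
        out = preprocess(small_study(data), fwhm=8.0)
        np.testing.assert_allclose(out.data[out.mask], 500.0, rtol=1e-12)

    def test_point_impulse_mass_conserved(self):
        # uniform brain plus an impulse whose kernel support stays interior:
        # smoothing redistributes but conserves the impulse mass
        # (kernel normalization oracle)
        data = np.full((24, 24, 16, 12), 1000.0)
        data[12, 12, 8, :] += 400.0
        study = BoldStudy(data=data, tr=1.5, voxel_size=(3.0, 3.0, 3.0))
        out = preprocess(study, fwhm=8.0)
        mass_in = (data[..., 0] - 1000.0).sum()
        mass_out = (out.data[..., 0] - 1000.0).sum()
        assert mass_out == pytest.approx(mass_in, rel=1e-6)

    def test_air_voxels_excluded_from_mask(self):
        data = np.zeros((8, 8, 4, 12))
        data[2:6, 2:6, 1:3, :] = 800.0
        out = preprocess(small_study(data), fwhm=0.0)
        assert out.mask[3, 3, 1]
        assert not out.mask[0, 0, 0]

    def test_empty_mask_rejected(self):
        data = np.zeros((4, 4, 2, 12))
        with pytest.raises(ParameterError):
            preprocess(small_study(data), fwhm=0.0)


class TestAlign:
    def _study_with_delay(self, delay, noise_sd=0.0, seed=0):
        truth = GroundTruth(
            cvr_map=0.2, etco2_ra=38.0, etco2_hc=46.0,
            bold_delay=delay, noise_sd=noise_sd,
        )
        protocol = bold_protocol()
        trace, env = generate_capno_trace(protocol, truth, seed=seed)
        study = generate_bold_series(protocol, truth, env, seed=seed)
        return study, detect_envelope(trace)

    def test_recovers_imposed_delay(self):
        study, curve = self._study_with_delay(6.0)
        aligned = align_etco2(study, curve, step=0.1)
        assert aligned.shift_s == pytest.approx(6.0, abs=0.1)

    def test_zero_delay(self):
        study, curve = self._study_with_delay(0.0)
        aligned = align_etco2(study, curve, step=0.1)
        assert aligned.shift_s == pytest.approx(0.0, abs=0.1)

    def test_pure_noise_warns_and_falls_back_to_zero(self):
        rng = np.random.default_rng(3)
        data = 1000.0 + rng.normal(0, 10, (6, 6, 3, 200))
        study = small_study(data)
        curve = block_curve()
        with pytest.warns(UserWarning, match="correlation"):
            aligned = align_etco2(study, curve, on_low_corr="warn")
        assert aligned.shift_s == 0.0
        with pytest.raises(AlignmentError):
            align_etco2(study, curve, on_low_corr="error")

    def test_constant_global_signal_rejected(self):
        study = small_study(np.full((4, 4, 2, 200), 900.0))
        with pytest.raises(AlignmentError):
            align_etco2(study, block_curve())


class TestGlm:
    def test_exact_recovery_of_constructed_coefficients(self):
        curve = block_curve()
        x = curve.resampled_etco2
        n = x.size
        drift = np.arange(n) - (n - 1) / 2
        series = 100.0 + 2.0 * (x - x.mean()) + 0.01 * drift
        data = np.tile(series, (4, 4, 2, 1))
        fits = fit_glm(small_study(data), curve)
        np.testing.assert_allclose(fits.beta0[fits.mask], 100.0, rtol=1e-10)
        np.testing.assert_allclose(fits.beta1[fits.mask], 2.0, rtol=1e-10)
        np.testing.assert_allclose(fits.beta2[fits.mask], 0.01, rtol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        curve = block_curve()
        x = curve.resampled_etco2
        n = x.size
        data = 1000.0 + rng.normal(0, 20, (5, 1, 1, n))
        fits = fit_glm(small_study(data), curve)
        # independent oracle: explicit normal equations per voxel
        drift = np.arange(n) - (n - 1) / 2
        X = np.column_stack([np.ones(n), x - x.mean(), drift])
        XtX_inv = np.linalg.inv(X.T @ X)
        for i in range(5):
            beta = XtX_inv @ X.T @ data[i, 0, 0]
            assert fits.beta0[i, 0, 0] == pytest.approx(beta[0], abs=1e-8)
            assert fits.beta1[i, 0, 0] == pytest.approx(beta[1], abs=1e-8)
            assert fits.beta2[i, 0, 0] == pytest.approx(beta[2], abs=1e-8)

    def test_zero_cvr_voxel_beta1_unbiased(self):
        curve = block_curve()
        n = curve.resampled_etco2.size
        betas = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            data = 1000.0 + rng.normal(0, 10, (1, 1, 1, n))
            fits = fit_glm(small_study(data), curve)
            betas.append(fits.beta1[0, 0, 0])
        betas = np.asarray(betas)
        se = betas.std(ddof=1) / np.sqrt(betas.size)
        assert abs(betas.mean()) < 2 * se + 1e-12

    def test_constant_regressor_rejected(self):
        t = np.arange(200) * 1.5
        curve = EtCO2Curve(t, np.full(200, 40.0)).resample(t)
        data = np.ones((2, 2, 2, 200))
        with pytest.raises(ParameterError):
            fit_glm(small_study(data), curve)

    def test_length_mismatch_rejected(self):
        curve = block_curve(n=100)
        data = np.ones((2, 2, 2, 200))
        with pytest.raises(ShapeError):
            fit_glm(small_study(data), curve)


class TestCvrMap:
    def _fits(self, beta0, beta1, shape=(2, 2, 1)):
        from cvrquant.boldcvr import GlmFitField

        mask = np.ones(shape, bool)
        return GlmFitField(
            beta0=np.full(shape, beta0), beta1=np.full(shape, beta1),
            beta2=np.zeros(shape), residual_sd=np.zeros(shape),
            mask=mask, shift_s=0.0,
        )

    def test_hand_value(self):
        s = EtCO2Summary(mean_etco2=43.0, baseline_etco2=38.0, delta_etco2=5.0)
        cvr_map = compute_cvr_map(self._fits(1000.0, 2.0), s)
        np.testing.assert_allclose(
            cvr_map.cvr, 2.0 / 990.0 * 100.0, rtol=1e-12
        )

    def test_mean_equals_baseline_limit(self):
        s = EtCO2Summary(40.0, 40.0, 0.0)
        cvr_map = compute_cvr_map(self._fits(800.0, 1.6), s)
        np.testing.assert_allclose(cvr_map.cvr, 1.6 / 800.0 * 100.0)

    def test_zero_beta1_gives_zero(self):
        s = EtCO2Summary(43.0, 38.0, 5.0)
        cvr_map = compute_cvr_map(self._fits(1000.0, 0.0), s)
        np.testing.assert_array_equal(cvr_map.cvr, 0.0)

    def test_nonpositive_denominator_flagged_invalid(self):
        s = EtCO2Summary(mean_etco2=48.0, baseline_etco2=38.0, delta_etco2=10.0)
        fits = self._fits(10.0, 2.0)  # denominator 10 - 20 < 0
        cvr_map = compute_cvr_map(fits, s)
        assert cvr_map.n_invalid == fits.beta0.size
        np.testing.assert_array_equal(cvr_map.cvr, 0.0)

    def test_map_invariant_to_signal_rescaling(self):
        truth = GroundTruth(cvr_map=0.17, noise_sd=0.0)
        protocol = bold_protocol()
        trace, env = generate_capno_trace(protocol, truth, seed=0)
        study = generate_bold_series(protocol, truth, env, seed=0)
        curve = detect_envelope(trace)
        res_a = BoldCvrModel(study, curve).fit()
        scaled = BoldStudy(
            data=study.data * 3.5, tr=study.tr, mask=study.mask,
            protocol=study.protocol, voxel_size=study.voxel_size,
        )
        res_b = BoldCvrModel(scaled, curve).fit()
        np.testing.assert_allclose(
            res_a.cvr_map.cvr, res_b.cvr_map.cvr, rtol=1e-9
        )


class TestAdjust:
    def test_reference_state_is_identity(self):
        assert adjust_cvr(0.17, 38.1, 8.0) == pytest.approx(0.17)

    def test_one_mmhg_above_reference_baseline(self):
        assert adjust_cvr(0.17, 39.1, 8.0) == pytest.approx(0.1734)

    def test_monotone_in_baseline_etco2(self):
        vals = [adjust_cvr(0.17, b, 8.0) for b in (36.0, 38.0, 40.0, 42.0)]
        assert np.all(np.diff(vals) > 0)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ParameterError):
            adjust_cvr(0.17, 38.1 - 60.0, 8.0)


class TestRoiSummary:
    def _map(self, values):
        from cvrquant.boldcvr import CvrMap

        s = EtCO2Summary(43.0, 38.0, 5.0)
        return CvrMap(
            cvr=values, valid=np.ones(values.shape, bool), shift_s=0.0, summary=s
        )

    def test_uniform_map(self):
        cvr_map = self._map(np.full((4, 4, 2), 0.17))
        rois = {"a": np.ones((4, 4, 2), bool), "b": np.zeros((4, 4, 2), bool)}
        rois["b"][0, 0, 0] = True
        table = roi_summary(cvr_map, rois)
        assert table["a"] == pytest.approx(0.17)
        assert table["b"] == pytest.approx(0.17)

    def test_two_region_map(self):
        values = np.zeros((4, 4, 1))
        values[:2] = 0.1
        values[2:] = 0.3
        cvr_map = self._map(values)
        left = np.zeros((4, 4, 1), bool)
        left[:2] = True
        table = roi_summary(cvr_map, {"left": left, "right": ~left})
        assert table["left"] == pytest.approx(0.1)
        assert table["right"] == pytest.approx(0.3)

    def test_partition_identity(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0.17, 0.05, (6, 6, 2))
        cvr_map = self._map(values)
        half = np.zeros((6, 6, 2), bool)
        half[:3] = True
        table = roi_summary(
            cvr_map, {"whole": np.ones((6, 6, 2), bool), "a": half, "b": ~half}
        )
        n_a, n_b = half.sum(), (~half).sum()
        weighted = (table["a"] * n_a + table["b"] * n_b) / (n_a + n_b)
        assert table["whole"] == pytest.approx(weighted, rel=1e-12)

    def test_empty_roi_omitted_with_warning(self):
        cvr_map = self._map(np.full((4, 4, 1), 0.17))
        empty = np.zeros((4, 4, 1), bool)
        with pytest.warns(UserWarning, match="omitted"):
            table = roi_summary(cvr_map, {"none": empty})
        assert "none" not in table.index


def test_noiseless_end_to_end_map_recovery():
    """The fitted map reproduces the configured CVR field voxelwise."""
    rng = np.random.default_rng(8)
    grid = (16, 16, 8)
    cvr_field = rng.uniform(0.05, 0.3, grid)
    truth = GroundTruth(
        cvr_map=cvr_field, etco2_ra=38.0, etco2_hc=46.0,
        noise_sd=0.0, drift_slope=0.03, bold_delay=6.0,
    )
    protocol = bold_protocol()
    trace, env = generate_capno_trace(protocol, truth, seed=2)
    study = generate_bold_series(protocol, truth, env, seed=2)
    res = BoldCvrModel(study, detect_envelope(trace)).fit()
    mask = res.cvr_map.valid
    rel = np.abs(res.cvr_map.cvr[mask] - cvr_field[mask]) / cvr_field[mask]
    assert rel.max() < 0.005


def test_summary_text_reports_fit(capsys):
    truth = GroundTruth(cvr_map=0.17, noise_sd=0.0)
    protocol = bold_protocol()
    trace, env = generate_capno_trace(protocol, truth, seed=0)
    study = generate_bold_series(protocol, truth, env, seed=0)
    res = BoldCvrModel(study, detect_envelope(trace)).fit()
    text = res.summary()
    assert "whole-brain CVR" in text and "%/mmHg" in text
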