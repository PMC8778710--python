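"""m/z drift modelling: series extraction, LOOCV spline, correction."""

import numpy as np
import pandas as pd
import pytest

from dimsqc.drift import (apply_mz_correction, extract_is_mz_series,
                          fit_drift_spline, verify_drift_with_standards)
from dimsqc.synthetic import StudyConfig, generate_study
from dimsqc.mass import ppm_error


def series_from(order, ppm):
    return pd.DataFrame({"order": order, "ppm": ppm})


class TestExtractSeries:
    def test_constant_mz_gives_zero_series(self):
        ids = [f"S{i}" for i in range(12)]
        obs = pd.Series(400.0, index=ids)
        order = pd.Series(range(1, 13), index=ids)
        s = extract_is_mz_series(obs, 400.0, order)
        assert np.allclose(s["ppm"], 0.0)
        assert len(s) == 12

    def test_sample_missing_is_skipped_with_warning(self):
        ids = [f"S{i}" for i in range(12)]
        obs = pd.Series(400.0, index=ids)
        obs.iloc[3] = np.nan
        order = pd.Series(range(1, 13), index=ids)
        with pytest.warns(UserWarning, match="skipped"):
            s = extract_is_mz_series(obs, 400.0, order)
        assert len(s) == 11

    def test_too_few_points_is_hard_error(self):
        ids = [f"S{i}" for i in range(5)]
        obs = pd.Series(400.0, index=ids)
        order = pd.Series(range(1, 6), index=ids)
        with pytest.raises(ValueError, match="insufficient"):
            extract_is_mz_series(obs, 400.0, order)


class TestFitSpline:
    def test_noiseless_quadratic_recovered(self):
        x = np.arange(1.0, 61.0)
        t = (x - 1) / 59
        truth = 4.0 * t**2
        model = fit_drift_spline(series_from(x, truth))
        assert np.max(np.abs(model.predict(x) - truth)) < 0.05

    def test_white_noise_selects_heavy_smoothing(self):
        rng = np.random.default_rng(5)
        x = np.arange(1.0, 81.0)
        y = rng.normal(0, 0.3, size=len(x))
        model = fit_drift_spline(series_from(x, y))
        se = 0.3 / np.sqrt(len(x))
        assert np.max(np.abs(model.predict(x))) < 2 * 0.3
        assert abs(np.mean(model.predict(x))) < 3 * se

    def test_chosen_lambda_minimises_loocv_curve(self):
        rng = np.random.default_rng(6)
        x = np.arange(1.0, 41.0)
        y = 3 * (x / 40) + rng.normal(0, 0.2, size=len(x))
        model = fit_drift_spline(series_from(x, y))
        assert model.loocv_curve.min() == model.loocv_curve[model.lam]

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            fit_drift_spline(series_from([1, 1, 1, 1], [0, 1, 2, 3]))


class TestApplyCorrection:
    def _flat_model(self, value=0.0):
        x = np.arange(1.0, 21.0)
        return fit_drift_spline(series_from(x, np.full(len(x), value)))

    def test_zero_prediction_is_identity(self):
        model = self._flat_model(0.0)
        mz = pd.Series([400.0, 500.0])
        out = apply_mz_correction(mz, [5.0, 10.0], model)
        assert np.allclose(out, mz, rtol=1e-12)

    def test_four_ppm_error_corrected_exactly(self):
        model = self._flat_model(4.0)
        out = apply_mz_correction(pd.Series([400.0016]), [10.0], model)
        assert out.iloc[0] == pytest.approx(400.0, abs=1e-6)

    def test_correction_invertible(self):
        rng = np.random.default_rng(7)
        x = np.arange(1.0, 31.0)
        model = fit_drift_spline(series_from(x, 2 * x / 30))
        mz = pd.Series(rng.uniform(100, 700, 30))
        corr = apply_mz_correction(mz, x, model)
        back = corr * (1 + model.predict(x) / 1e6)
        assert np.allclose(back, mz, rtol=1e-12)

    def test_out_of_range_order_extrapolates_constant_with_warning(self):
        model = self._flat_model(4.0)
        with pytest.warns(UserWarning, match="extrapolating"):
            out = apply_mz_correction(pd.Series([400.0016]), [99.0], model)
        assert out.iloc[0] == pytest.approx(400.0, abs=1e-6)


class TestEndToEndDriftRecovery:
    @pytest.mark.parametrize("shape", ["linear", "quadratic", "sinusoidal"])
    def test_residual_median_ppm_small_after_correction(self, shape):
        cfg = StudyConfig(n_features=40, n_plates=2, wells_per_plate=20,
                          n_qc=8, n_blank=2, mz_drift_shape=shape,
                          mz_drift_amplitude=5.0, mz_noise_ppm=0.3, seed=13)
        st = generate_study(cfg)
        obs = st.observed_mz.loc["IS"]
        order = st.pm.samples["acquisition_order"]
        series = extract_is_mz_series(obs, 210.12297, order)
        model = fit_drift_spline(series)
        corrected = apply_mz_correction(st.observed_mz, order.to_numpy(), model)
        resid = ppm_error(corrected.loc["IS"].to_numpy(), 210.12297)
        assert abs(np.median(resid)) < 0.2

    def test_standards_sharing_drift_verify_model(self):
        cfg = StudyConfig(n_features=40, n_plates=2, wells_per_plate=20,
                          n_qc=8, n_blank=2, mz_drift_shape="sinusoidal",
                          mz_drift_amplitude=5.0, mz_noise_ppm=0.0, seed=19)
        st = generate_study(cfg)
        order = st.pm.samples["acquisition_order"]
        series = extract_is_mz_series(st.observed_mz.loc["IS"], 210.12297, order)
        model = fit_drift_spline(series)
        std = {}
        for fid in st.truth.standards_features:
            ref = float(st.observed_mz.loc[fid].median())
            std[fid] = extract_is_mz_series(st.observed_mz.loc[fid], ref, order)
        rep = verify_drift_with_standards(std, model)
        assert (rep["r"] > 0.95).all()
        assert (rep["status"] == "verified").all()

    def test_independent_random_walk_fails_verification(self):
        rng = np.random.default_rng(21)
        x = np.arange(1.0, 61.0)
        model = fit_drift_spline(series_from(x, 5 * np.sin(2 * np.pi * x / 60)))
        walk = np.cumsum(rng.normal(0, 0.5, size=len(x)))
        rep = verify_drift_with_standards(
            {"good": series_from(x, 5 * np.sin(2 * np.pi * x / 60)),
             "rogue": series_from(x, walk)}, model)
        rep = rep.set_index("standard")
        assert rep.at["good", "passed"]
        assert not rep.at["rogue", "passed"]

    def test_single_standard_marks_partial(self):
        x = np.arange(1.0, 21.0)
        model = fit_drift_spline(series_from(x, x / 10))
        rep = verify_drift_with_standards({"only": series_from(x, x / 10)}, model)
        assert list(rep["status"]) == ["partial"]
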