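"""IS-based outlier screening: scaled MAD, thresholds, flags, rerun."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import median_abs_deviation

from dimsqc.screen import (flag_outlier_samples, is_thresholds,
                           remove_flagged_samples, scaled_mad)
from dimsqc.mass import ISConfig, find_internal_standard
from dimsqc.synthetic import StudyConfig, generate_study
from conftest import make_pm


class TestScaledMad:
    def test_constant_values_give_zero(self):
        assert scaled_mad([10, 10, 10, 10, 10]) == 0.0

    def test_hand_computed_example(self):
        # median 3, deviations {2,1,0,1,97}, median deviation 1
        assert scaled_mad([1, 2, 3, 4, 100]) == pytest.approx(1.4826)

    def test_missing_treated_as_recorded_zero(self):
        with_nan = [5.0, np.nan, 7.0, 6.0]
        with_zero = [5.0, 0.0, 7.0, 6.0]
        assert scaled_mad(with_nan) == scaled_mad(with_zero)

    def test_matches_scipy_normal_scaled_mad(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 40))
            # scipy uses 1/Phi^-1(3/4) = 1.4826022; we use the stated 1.4826
            assert scaled_mad(x) == pytest.approx(
                median_abs_deviation(x, scale="normal"), rel=1e-4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            scaled_mad([])


class TestThresholds:
    def test_constant_qc_intensities_collapse_interval(self):
        vals = pd.Series([100.0] * 5 + [100.0] * 6,
                         index=[f"Q{i}" for i in range(5)]
                         + [f"B{i}" for i in range(6)])
        classes = pd.Series(["QC"] * 5 + ["biological"] * 6, index=vals.index)
        th = is_thresholds(vals, classes)
        assert th["QC"].lower == th["QC"].upper == 100.0

    def test_zero_sample_falls_outside_band(self):
        # nine samples at 100 and one failed at 0: median 100, MAD 0
        vals = pd.Series([100.0] * 9 + [0.0],
                         index=[f"S{i}" for i in range(10)])
        classes = pd.Series(["biological"] * 10, index=vals.index)
        th = is_thresholds(vals, classes)
        assert th["biological"].lower == th["biological"].upper == 100.0
        assert 0.0 < th["biological"].lower

    def test_k2_interval_nested_in_k3(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.lognormal(13, 0.1, 20),
                         index=[f"S{i}" for i in range(20)])
        classes = pd.Series(["biological"] * 20, index=vals.index)
        t2 = is_thresholds(vals, classes, k_study=2)["biological"]
        t3 = is_thresholds(vals, classes, k_study=3)["biological"]
        assert t3.lower < t2.lower < t2.upper < t3.upper

    def test_interval_width_is_2k_times_scaled_mad(self):
        rng = np.random.default_rng(2)
        vals = pd.Series(rng.lognormal(13, 0.2, 15),
                         index=[f"S{i}" for i in range(15)])
        classes = pd.Series(["biological"] * 15, index=vals.index)
        t = is_thresholds(vals, classes, k_study=2)["biological"]
        assert t.upper - t.lower == pytest.approx(2 * 2 * scaled_mad(vals))

    def test_small_class_warns(self):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        classes = pd.Series(["QC", "QC"], index=vals.index)
        with pytest.warns(UserWarning, match="fewer than 3"):
            is_thresholds(vals, classes)


class TestFlagging:
    def _study_pm(self, is_vals, classes):
        cols = {f"S{i}": [v, 1.0] for i, v in enumerate(is_vals)}
        return make_pm(cols, classes=classes, mz=[210.12297, 400.0])

    def test_failed_infusion_flagged_among_healthy(self):
        pm = self._study_pm([100, 101, 99, 100, 0.5],
                            ["biological"] * 5)
        th = is_thresholds(pm.intensities.loc["F1"], pm.samples["class"])
        rep = flag_outlier_samples(pm, "F1", th)
        assert list(rep.loc[rep.flagged, "sample_id"]) == ["S4"]

    def test_all_within_band_flags_nothing(self):
        pm = self._study_pm([100, 101, 99, 100], ["biological"] * 4)
        th = is_thresholds(pm.intensities.loc["F1"], pm.samples["class"])
        rep = flag_outlier_samples(pm, "F1", th)
        assert not rep["flagged"].any()

    def test_blanks_never_screened(self):
        pm = self._study_pm([100, 101, 99, 0.0],
                            ["biological"] * 3 + ["blank"])
        th = is_thresholds(pm.intensities.loc["F1"], pm.samples["class"])
        rep = flag_outlier_samples(pm, "F1", th)
        assert "S3" not in set(rep["sample_id"])

    def test_flags_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(3)
        vals = list(rng.lognormal(4, 0.1, 12)) + [0.01]
        pm1 = self._study_pm(vals, ["biological"] * 13)
        pm2 = self._study_pm([v * 137.0 for v in vals], ["biological"] * 13)
        th1 = is_thresholds(pm1.intensities.loc["F1"], pm1.samples["class"])
        th2 = is_thresholds(pm2.intensities.loc["F1"], pm2.samples["class"])
        r1 = flag_outlier_samples(pm1, "F1", th1)
        r2 = flag_outlier_samples(pm2, "F1", th2)
        assert list(r1["flagged"]) == list(r2["flagged"])


class TestRemovalRerun:
    def test_no_flags_is_identity(self, small_study):
        pm = small_study.pm
        isf = find_internal_standard(pm, ISConfig())
        th = is_thresholds(pm.intensities.loc[isf], pm.samples["class"])
        rep = flag_outlier_samples(pm, isf, th)
        rep["flagged"] = False
        out, removed = remove_flagged_samples(pm, rep)
        assert removed == []
        assert out is pm

    def test_second_pass_on_cleaned_planted_failures_flags_nothing(self):
        """Screening is idempotent when the only outliers are planted
        failed infusions (well-separated at factor 0.01)."""
        cfg = StudyConfig(n_features=60, n_plates=2, wells_per_plate=12,
                          n_qc=8, n_blank=2, p_failed_infusion=0.08,
                          failed_infusion_factor=0.01, sigma_analytical=0.02,
                          seed=31)
        st = generate_study(cfg)
        pm = st.pm
        isf = find_internal_standard(pm, ISConfig())
        th = is_thresholds(pm.intensities.loc[isf], pm.samples["class"])
        rep = flag_outlier_samples(pm, isf, th)
        cleaned, removed = remove_flagged_samples(pm, rep)
        assert set(st.truth.failed_samples) <= set(removed)
        th2 = is_thresholds(cleaned.intensities.loc[isf],
                            cleaned.samples["class"])
        rep2 = flag_outlier_samples(cleaned, isf, th2)
        fp2 = set(rep2.loc[rep2.flagged, "sample_id"])
        assert not (fp2 & set(st.truth.failed_samples))

    def test_removing_whole_class_is_hard_error(self):
        pm = make_pm({"S1": [1.0], "S2": [1.0], "S3": [1.0], "S4": [50.0]},
                     classes=["QC", "QC", "QC", "biological"],
                     mz=[210.12297])
        rep = pd.DataFrame({"sample_id": ["S4"], "class": ["biological"],
                            "flagged": [True]})
        with pytest.raises(ValueError, match="every sample of class"):
            remove_flagged_samples(pm, rep)
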