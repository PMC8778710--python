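"""Repeatability metrics and per-feature condition statistics."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from dimsqc.stats import (anova_posthoc, classify_not_repeatable, feature_rsd,
                          geometric_fold_change, is_rsd_report, mrsd,
                          per_plate_mrsd, tukey_kramer, welch_edge_centre,
                          StatResult)
from dimsqc.synthetic import StudyConfig, generate_study
from conftest import make_pm


class TestRSD:
    def test_constant_values_zero(self):
        assert feature_rsd([10, 10, 10]) == 0.0

    def test_hand_computed_two_values(self):
        assert feature_rsd([90, 110]) == pytest.approx(14.142, abs=0.001)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(3, 0.2, 12)
        assert feature_rsd(7.3 * x) == pytest.approx(feature_rsd(x))

    def test_undefined_cases_are_nan(self):
        assert np.isnan(feature_rsd([5.0]))
        assert np.isnan(feature_rsd([1.0, -3.0]))  # non-positive mean

    def test_mrsd_is_median_over_features(self):
        pm = make_pm({"S1": [90.0, 80.0, 10.0], "S2": [110.0, 120.0, 200.0]})
        rsds = sorted(feature_rsd(pm.intensities.loc[f]) for f in
                      pm.intensities.index)
        assert mrsd(pm, ["S1", "S2"]) == pytest.approx(rsds[1])

    def test_mrsd_all_zero_variance(self):
        pm = make_pm({"S1": [1.0, 2.0], "S2": [1.0, 2.0]})
        assert mrsd(pm, ["S1", "S2"]) == 0.0


class TestPerPlateMrsd:
    def test_identical_plates_equal_mrsd_and_boundary_flags(self):
        # plate A tight (~pass), plate B wide (~fail at 30%)
        cols = {}
        for i in range(3):
            cols[f"A{i}"] = [100.0 * (1 + 0.05 * (i - 1))]
            cols[f"B{i}"] = [100.0 * (1 + 0.40 * (i - 1))]
        pm = make_pm(cols, plates=["PA", "PB"] * 3)
        rep = per_plate_mrsd(pm, {"chk": pm})
        rep = rep.set_index("plate_id")
        assert rep.at["PA", "passed"]
        assert not rep.at["PB", "passed"]

    def test_small_plates_skipped(self):
        pm = make_pm({"S1": [1.0]}, plates=["PA"])
        assert len(per_plate_mrsd(pm, {"chk": pm})) == 0


class TestFoldChange:
    def test_hand_computed_geometric_means(self):
        assert geometric_fold_change([2, 8], [8, 32]) == pytest.approx(0.25)

    def test_identical_groups_unity(self):
        assert geometric_fold_change([3, 5, 7], [3, 5, 7]) == pytest.approx(1.0)

    def test_swapping_groups_gives_reciprocal(self):
        fc = geometric_fold_change([2, 8], [5, 9])
        assert geometric_fold_change([5, 9], [2, 8]) == pytest.approx(1 / fc)

    def test_nonpositive_values_excluded(self):
        assert geometric_fold_change([2, 8, 0.0], [8, 32]) == pytest.approx(0.25)
        assert np.isnan(geometric_fold_change([0.0], [1.0]))


class TestTukeyKramer:
    def test_balanced_case_matches_tukey_hsd_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = rng.integers(2, 5)
            n = int(rng.integers(4, 9))
            groups = [rng.normal(rng.normal(0, 1), 1, n) for _ in range(k)]
            ours = tukey_kramer(groups)
            data = np.concatenate(groups)
            labels = np.repeat(np.arange(k), n)
            hsd = pairwise_tukeyhsd(data, labels)
            for (i, j), p_ref in zip(
                    [(a, b) for a in range(k) for b in range(a + 1, k)],
                    hsd.pvalues):
                assert ours[(i, j)] == pytest.approx(p_ref, abs=1e-6)

    def test_zero_within_variance_degenerate(self):
        out = tukey_kramer([np.array([1.0, 1.0]), np.array([1.0, 1.0])])
        assert out[(0, 1)] == 1.0
        out = tukey_kramer([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert out[(0, 1)] == 0.0


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg: sort, scale by m/rank, cummin."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def test_bh_adjustment_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    for _ in range(30):
        p = rng.random(int(rng.integers(1, 400)))
        ref = bh_oracle(p)
        got = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(got, ref, atol=1e-12)


class TestAnovaPosthoc:
    def _study(self, planted=0, seed=0):
        return generate_study(StudyConfig(
            n_features=60, n_plates=2, wells_per_plate=18, n_qc=5, n_blank=0,
            n_groups=2, n_planted_diff=planted, planted_log_fc=np.log(3.0),
            sigma_analytical=0.1, sigma_biological=0.05, plate_effect_sd=0.0,
            dilution_log_sd=0.0, detection_threshold=0.0, seed=seed))

    def test_planted_shift_yields_tiny_pvalues(self):
        st = self._study(planted=5, seed=3)
        res = anova_posthoc(st.pm, st.truth.group_of_sample[
            st.pm.samples["class"] == "biological"])
        by_id = {r.feature_id: r for r in res}
        for fid in st.truth.planted_features:
            assert by_id[fid].anova_p < 1e-3

    def test_null_raw_p_uniformity(self):
        st = self._study(planted=0, seed=4)
        res = anova_posthoc(st.pm, st.truth.group_of_sample[
            st.pm.samples["class"] == "biological"])
        frac = np.mean([r.anova_p <= 0.05 for r in res if r.eligible])
        assert frac <= 0.15

    def test_identical_values_p_one(self):
        pm = make_pm({f"S{i}": [5.0] for i in range(8)})
        grouping = pd.Series(["A"] * 4 + ["B"] * 4,
                             index=[f"S{i}" for i in range(8)])
        res = anova_posthoc(pm, grouping)
        assert res[0].anova_p == 1.0

    def test_eligibility_requires_three_per_group(self):
        vals = {f"S{i}": [1.0 if i != 0 else np.nan] for i in range(6)}
        pm = make_pm(vals)
        grouping = pd.Series(["A"] * 3 + ["B"] * 3,
                             index=[f"S{i}" for i in range(6)])
        res = anova_posthoc(pm, grouping)
        assert not res[0].eligible
        assert np.isnan(res[0].anova_p_adjusted)

    def test_adjusted_p_not_below_raw(self):
        st = self._study(planted=3, seed=5)
        res = anova_posthoc(st.pm, st.truth.group_of_sample[
            st.pm.samples["class"] == "biological"])
        for r in res:
            if r.eligible:
                assert r.anova_p_adjusted >= r.anova_p - 1e-12


class TestClassifyNotRepeatable:
    def _result(self, adj, post, fc):
        r = StatResult(feature_id="F", eligible=True, anova_p=adj,
                       anova_p_adjusted=adj, posthoc_p={("A", "B"): post},
                       fc={("A", "B"): fc})
        return r

    def test_fold_change_gate_blocks_significant_feature(self):
        rep = classify_not_repeatable([self._result(0.01, 0.01, 1.1)])
        assert rep.at[0, "n_flagged"] == 0

    def test_both_gates_open_flags_feature(self):
        rep = classify_not_repeatable([self._result(0.01, 0.03, 1.5)])
        assert rep.at[0, "n_flagged"] == 1

    def test_downward_fold_change_symmetric(self):
        rep = classify_not_repeatable([self._result(0.01, 0.01, 1 / 1.5)])
        assert rep.at[0, "n_flagged"] == 1

    def test_flagged_subset_of_adjusted_significant(self):
        st = generate_study(StudyConfig(
            n_features=80, n_plates=2, wells_per_plate=18, n_qc=5, n_blank=0,
            n_groups=2, n_planted_diff=10, seed=6, detection_threshold=0.0))
        res = anova_posthoc(st.pm, st.truth.group_of_sample[
            st.pm.samples["class"] == "biological"])
        classify_not_repeatable(res)
        for r in res:
            if r.eligible and any(r.not_repeatable.values()):
                assert r.anova_p_adjusted <= 0.05


class TestWelchEdgeCentre:
    def _zone_pm(self, edge_boost=1.0, seed=0, n_feat=40):
        rng = np.random.default_rng(seed)
        wells, cols = [], {}
        edge_wells = ["A1", "A2", "A3", "A4", "A5", "A6"]
        centre_wells = ["B2", "B3", "B4", "B5", "C2", "C3"]
        for i, w in enumerate(edge_wells + centre_wells):
            boost = edge_boost if w in edge_wells else 1.0
            cols[f"S{i}"] = rng.lognormal(5, 0.1, n_feat) * boost
            wells.append(w)
        return make_pm(cols, wells=wells)

    def test_null_zones_flag_nothing_much(self):
        rep = welch_edge_centre(self._zone_pm(1.0, seed=1))
        assert rep.at[0, "percent_flagged"] <= 5.0

    def test_planted_edge_effect_flags_majority(self):
        rep = welch_edge_centre(self._zone_pm(1.5, seed=2))
        assert rep.at[0, "percent_flagged"] > 50.0

    def test_single_feature_bh_with_m_equal_one(self):
        pm = self._zone_pm(1.0, seed=3, n_feat=1)
        rep = welch_edge_centre(pm)
        assert rep.at[0, "n_tested"] == 1

    def test_plate_without_both_zones_skipped(self):
        pm = make_pm({f"S{i}": [1.0] for i in range(6)},
                     wells=["B2"] * 6)
        assert len(welch_edge_centre(pm)) == 0


class TestISRSDReport:
    def test_constant_is_zero_rsd_and_counts(self):
        vals = pd.Series([5.0] * 6 + [5.0] * 4,
                         index=[f"Q{i}" for i in range(6)]
                         + [f"S{i}" for i in range(4)])
        classes = pd.Series(["QC"] * 6 + ["biological"] * 4, index=vals.index)
        rep = is_rsd_report(vals, classes).set_index("class")
        assert rep.at["QC", "rsd"] == 0.0
        assert rep.at["QC", "n"] == 6
        assert rep.at["biological", "n"] == 4

    def test_wider_study_class_has_larger_rsd(self):
        rng = np.random.default_rng(7)
        qc = rng.lognormal(3, 0.03, 10)
        bio = rng.lognormal(3, 0.3, 10)
        vals = pd.Series(np.concatenate([qc, bio]),
                         index=[f"Q{i}" for i in range(10)]
                         + [f"S{i}" for i in range(10)])
        classes = pd.Series(["QC"] * 10 + ["biological"] * 10,
                            index=vals.index)
        rep = is_rsd_report(vals, classes).set_index("class")
        assert rep.at["QC", "rsd"] < rep.at["biological", "rsd"]
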