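"""Group statistics: rank tests, multiplicity control, ROC analysis, DeLong
comparison, logistic models, and the FET-DKI index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetdki import stats as fs
from fetdki.cohort import CohortSimConfig, simulate_feature_cohort


class TestMannWhitney:
    def test_separated_samples_exact_enumeration(self):
        r = fs.mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u == 0
        assert r.p_value == pytest.approx(0.1)
        assert r.method == "exact"

    def test_identical_multisets_symmetric(self):
        r = fs.mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.u == 4.5
        assert r.p_value == pytest.approx(1.0)

    def test_midrank_tie_handling(self):
        r = fs.mann_whitney([1, 2], [1, 2])
        assert r.u == 2.0  # brute force: 0.5 + 0 + 1 + 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fs.mann_whitney([], [1.0])

    def test_asymptotic_agrees_with_scipy(self, rng):
        from scipy.stats import mannwhitneyu
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 25)
        r = fs.mann_whitney(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert r.u == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestBonferroni:
    def test_family_thresholds(self):
        assert fs.bonferroni(0.05, 18) == pytest.approx(0.05 / 18)
        assert round(fs.bonferroni(0.05, 18), 4) == 0.0028
        assert fs.bonferroni(0.05, 4) == 0.0125

    def test_single_comparison_identity(self):
        assert fs.bonferroni(0.07, 1) == 0.07

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            fs.bonferroni(0.05, 0)

    def test_significance_categories(self):
        assert fs.significance_category(0.001, 0.05, 18) == "significant"
        assert fs.significance_category(0.01, 0.05, 18) == \
            "significant prior to correction"
        assert fs.significance_category(0.2, 0.05, 18) == "not significant"


class TestRoc:
    def test_overlapping_samples_brute_force_auc(self):
        r = fs.roc_analysis([1, 2, 3, 0, 1, 2], ["TPR"] * 3 + ["TRC"] * 3)
        assert r.auc == pytest.approx(7 / 9)

    def test_perfect_separation(self):
        r = fs.roc_analysis([10, 11, 12, 1, 2, 3], ["TPR"] * 3 + ["TRC"] * 3)
        assert r.auc == 1.0
        assert r.sensitivity == r.specificity == r.accuracy == 100.0

    def test_shuffled_labels_give_half_auc(self, rng):
        vals = rng.normal(0, 1, 600)
        labels = np.array(["TPR"] * 300 + ["TRC"] * 300)
        rng.shuffle(labels)
        r = fs.roc_analysis(vals, labels, auto_orient=False)
        assert r.auc == pytest.approx(0.5, abs=0.06)
        assert r.p_value > 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fs.roc_analysis([1, 2], ["TPR", "TPR"])

    def test_lower_is_positive_auto_orientation(self):
        r = fs.roc_analysis([1, 2, 3, 7, 8, 9], ["TPR"] * 3 + ["TRC"] * 3)
        assert r.direction == "lower"
        assert r.auc == 1.0

    def test_accuracy_identity_at_reported_cutoff(self, rng):
        vals = np.concatenate([rng.normal(1, 1, 21), rng.normal(0, 1, 11)])
        labels = np.array(["TPR"] * 21 + ["TRC"] * 11)
        r = fs.roc_analysis(vals, labels)
        assert r.accuracy == pytest.approx(
            fs.prevalence_weighted_accuracy(r.sensitivity, r.specificity, 21, 11))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=20),
           st.lists(st.floats(-5, 5), min_size=2, max_size=20))
    def test_auc_equals_u_over_n1n2(self, a, b):
        """Empirical AUC and the Mann-Whitney U statistic are the same object
        up to the n1*n2 normalization."""
        vals = np.array(a + b)
        labels = np.array(["TPR"] * len(a) + ["TRC"] * len(b))
        r = fs.roc_analysis(vals, labels, auto_orient=False)
        u = fs.mann_whitney(np.array(a), np.array(b)).u
        assert abs(r.auc - u / (len(a) * len(b))) < 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_matches_pairwise_enumeration(self, seed):
        """Tie-aware brute force over all (positive, negative) pairs."""
        g = np.random.default_rng(seed)
        pos = np.round(g.normal(1, 1, g.integers(2, 9)), 1)
        neg = np.round(g.normal(0, 1, g.integers(2, 9)), 1)
        vals = np.concatenate([pos, neg])
        labels = np.array(["TPR"] * pos.size + ["TRC"] * neg.size)
        r = fs.roc_analysis(vals, labels, auto_orient=False)
        brute = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert r.auc == pytest.approx(brute, abs=1e-12)


class TestDeLong:
    def test_marker_compared_with_itself(self, rng):
        v = rng.normal(0, 1, 40)
        labels = np.array(["TPR"] * 25 + ["TRC"] * 15)
        a1, a2, z, p = fs.delong_compare(v, v, labels)
        assert a1 == a2
        assert z == 0.0 and p == 1.0

    def test_aucs_match_roc_analysis(self, rng):
        v1 = rng.normal(0, 1, 32)
        v2 = rng.normal(0, 1, 32)
        labels = np.array(["TPR"] * 21 + ["TRC"] * 11)
        a1, a2, _, _ = fs.delong_compare(v1, v2, labels)
        assert a1 == fs.roc_analysis(v1, labels, auto_orient=False).auc
        assert a2 == fs.roc_analysis(v2, labels, auto_orient=False).auc

    def test_independent_markers_variance_adds(self, rng):
        """For independent markers the covariance term vanishes, so the
        variance of the AUC difference is close to var1 + var2."""
        labels = np.array(["TPR"] * 60 + ["TRC"] * 40)
        diffs, vars_sum = [], []
        for _ in range(300):
            v1 = rng.normal(0, 1, 100) + 0.8 * (labels == "TPR")
            v2 = rng.normal(0, 1, 100) + 0.8 * (labels == "TPR")
            a1, a2, *_ = fs.delong_compare(v1, v2, labels)
            diffs.append(a1 - a2)
            vars_sum.append(fs._delong_variance(v1[labels == "TPR"], v1[labels == "TRC"])
                            + fs._delong_variance(v2[labels == "TPR"], v2[labels == "TRC"]))
        assert np.var(diffs) == pytest.approx(np.mean(vars_sum), rel=0.25)

    def test_unpaired_markers_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            fs.delong_compare([1, 2, 3], [1, 2], ["TPR", "TRC", "TPR"])


class TestLogistic:
    def test_two_by_two_equals_log_odds_ratio(self):
        # exposed: 9 TPR / 1 TRC; unexposed: 2 TPR / 8 TRC -> OR = 36
        df = pd.DataFrame({"pred": [1] * 10 + [0] * 10,
                           "group": ["TPR"] * 9 + ["TRC"] + ["TPR"] * 2 + ["TRC"] * 8})
        lm = fs.logistic_fit(df, ["pred"])
        assert lm.coefficients["pred"] == pytest.approx(np.log(36.0), abs=1e-6)
        assert not lm.separation

    def test_uninformative_predictor_has_near_zero_coefficient(self, rng):
        n = 4000
        df = pd.DataFrame({"x": rng.normal(0, 1, n),
                           "group": np.where(rng.random(n) < 0.5, "TPR", "TRC")})
        lm = fs.logistic_fit(df, ["x"])
        assert lm.coefficients["x"] == pytest.approx(0.0, abs=0.12)

    def test_perfect_separation_flagged(self):
        df = pd.DataFrame({"x": [0, 1, 2, 3, 10, 11, 12, 13],
                           "group": ["TRC"] * 4 + ["TPR"] * 4})
        lm = fs.logistic_fit(df, ["x"])
        assert lm.separation

    def test_known_model_coefficients_recovered(self, rng):
        """Data simulated from a known logistic law refit within 3 SEs."""
        n = 5000
        x = rng.normal(0, 1, n)
        eta = -0.4 + 1.2 * x
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        df = pd.DataFrame({"x": x, "group": np.where(y, "TPR", "TRC")})
        lm = fs.logistic_fit(df, ["x"])
        se = np.sqrt(1 / n) * 3  # conservative scale for the slope SE
        assert lm.coefficients["x"] == pytest.approx(1.2, abs=max(3 * 0.04, se))

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"x": [1.0, np.nan], "group": ["TPR", "TRC"]})
        with pytest.raises(ValueError, match="missing"):
            fs.logistic_fit(df, ["x"])


class TestFetDkiIndex:
    def test_reference_tpr_medians_classify_as_progression(self):
        value, call = fs.fet_dki_index(3.30, 0.78)
        assert value == pytest.approx(46.086)
        assert call == "TPR"

    def test_reference_trc_medians_classify_as_treatment_change(self):
        value, call = fs.fet_dki_index(2.50, 0.61)
        assert value == pytest.approx(35.662)
        assert call == "TRC"

    def test_zero_inputs(self):
        value, call = fs.fet_dki_index(0.0, 0.0)
        assert value == 0.0 and call == "TRC"

    def test_strict_cutoff(self):
        _, at = fs.fet_dki_index(41.0 / 4.7, 0.0)
        assert at == "TRC"  # exactly 41 is not "more than 41"

    def test_monotone_in_each_argument(self, rng):
        t = rng.uniform(1, 5, 50)
        m = rng.uniform(0.4, 1.2, 50)
        v0, _ = fs.fet_dki_index(t, m)
        v1, _ = fs.fet_dki_index(t + 0.01, m)
        v2, _ = fs.fet_dki_index(t, m + 0.01)
        assert (v1 > v0).all() and (v2 > v0).all()

    def test_missing_inputs_yield_blank_call(self):
        with pytest.warns(UserWarning, match="missing"):
            vals, calls = fs.fet_dki_index(np.array([3.0, np.nan]),
                                           np.array([0.8, 0.7]))
        assert calls[1] == ""


@pytest.fixture(scope="module")
def cohort():
    return simulate_feature_cohort(CohortSimConfig(n_trc=80, n_tpr=150, seed=21))


class TestGroupAnalysis:
    def test_report_structure_and_thresholds(self, cohort):
        rep = fs.run_group_analysis(cohort)
        assert rep["n_trc"] == 80 and rep["n_tpr"] == 150
        assert rep["bonferroni_thresholds"]["dki"] == pytest.approx(0.05 / 18)
        assert len(rep["features"]) == 22
        assert "MK_C90 + TBR_max" in rep["logistic_multivariate"]

    def test_calibrated_cohort_flags_kurtosis_features(self, cohort):
        rep = fs.run_group_analysis(cohort)
        for name in ("MK_mean", "MK_C90", "MK_C95"):
            assert rep["features"][name]["category"] == "significant"

    def test_single_group_cohort_rejected(self, cohort):
        only_tpr = cohort[cohort.group == "TPR"]
        with pytest.raises(ValueError, match="both groups"):
            fs.run_group_analysis(only_tpr)

    def test_tables_render(self, cohort):
        rep = fs.run_group_analysis(cohort)
        t1 = fs.group_table(rep)
        t2 = fs.roc_table(rep)
        assert len(t1) == 22
        assert t2["marker"].iloc[-1] == "FET-DKI index"

    def test_permuted_labels_control_family_wise_error(self):
        """Under the global null (labels permuted), the Bonferroni screen
        rarely flags anything: family-wise error within Monte-Carlo slack of
        the nominal 5% level per family."""
        base = simulate_feature_cohort(CohortSimConfig(n_trc=16, n_tpr=16, seed=77))
        g = np.random.default_rng(77)
        hits_dki = hits_pet = 0
        n_rep = 150
        for _ in range(n_rep):
            perm = base.copy()
            perm["group"] = g.permutation(perm["group"].to_numpy())
            if set(perm["group"]) != {"TPR", "TRC"}:
                continue
            rep = fs.run_group_analysis(perm)
            cats = {k: v["category"] for k, v in rep["features"].items()}
            if any(c == "significant" for k, c in cats.items()
                   if rep["features"][k]["family"] == "DKI"):
                hits_dki += 1
            if any(c == "significant" for k, c in cats.items()
                   if rep["features"][k]["family"] == "PET"):
                hits_pet += 1
        assert hits_dki / n_rep <= 0.08
        assert hits_pet / n_rep <= 0.08
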