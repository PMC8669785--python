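"""Statistical operations against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from ecgbmi.downstream_stats import (
    bh_adjust,
    binarized_roc,
    comorbidity_or,
    confusion_groups,
    confusion_matrix,
    delta_bmi,
    misclassification_chi2,
    rmse,
    vat_regression,
)


def table_from(**cols):
    return pd.DataFrame(cols)


class TestConfusionMatrix:
    def test_perfect_predictions(self):
        t = table_from(truth_bmi=[20, 27, 31, 24], pred_class=[0, 1, 1, 0])
        mat, acc = confusion_matrix(t, 2)
        assert acc == 1.0
        assert mat[0, 1] == 0 and mat[1, 0] == 0

    def test_hand_counted_accuracy(self):
        # truth classes (1,1,0,0), predictions (1,0,0,0) -> 3/4 correct
        t = table_from(truth_bmi=[27, 28, 20, 21], pred_class=[1, 0, 0, 0])
        _, acc = confusion_matrix(t, 2)
        assert acc == 0.75

    def test_three_class_row_sums_are_truth_counts(self):
        rng = np.random.default_rng(0)
        bmi = rng.uniform(18, 40, 60)
        t = table_from(truth_bmi=bmi, pred_class=rng.integers(0, 3, 60))
        mat, _ = confusion_matrix(t, 3)
        truth = np.where(bmi >= 30, 2, np.where(bmi >= 25, 1, 0))
        np.testing.assert_array_equal(mat.sum(axis=1), np.bincount(truth, minlength=3))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_matrix(table_from(truth_bmi=[], pred_class=[]), 2)

    def test_groups_partition_subjects(self):
        t = table_from(truth_bmi=[27, 28, 20, 21], pred_class=[1, 0, 0, 1])
        g = confusion_groups(t)
        assert list(g) == ["TP", "FN", "TN", "FP"]


class TestDeltaBmi:
    def test_signed_difference(self):
        t = table_from(pred_bmi=[27.0, 25.0], truth_bmi=[25.0, 25.0])
        np.testing.assert_array_equal(delta_bmi(t), [2.0, 0.0])

    def test_missing_predictions_excluded(self):
        t = table_from(pred_bmi=[27.0, np.nan, 24.0], truth_bmi=[25.0, 25.0, 25.0])
        assert len(delta_bmi(t)) == 2


class TestVatRegression:
    def test_exact_recovery_of_noise_free_construction(self):
        rng = np.random.default_rng(1)
        bmi = rng.uniform(20, 35, 100)
        delta = rng.normal(0, 3, 100)
        t = table_from(truth_bmi=bmi, pred_bmi=bmi + delta, truth_vat=0.2 * delta + 0.1 * bmi)
        res = vat_regression(t)
        assert res["beta_per_unit"].estimate == pytest.approx(0.2, abs=1e-10)
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-10)
        assert res["beta_per_unit"].p_value < 1e-10

    def test_per_sd_is_per_unit_times_sample_sd(self):
        rng = np.random.default_rng(2)
        bmi = rng.uniform(20, 35, 80)
        delta = rng.normal(0, 3, 80)
        vat = 0.2 * delta + 0.1 * bmi + rng.normal(0, 0.5, 80)
        t = table_from(truth_bmi=bmi, pred_bmi=bmi + delta, truth_vat=vat)
        res = vat_regression(t)
        assert res["beta_per_sd"].estimate == pytest.approx(
            res["beta_per_unit"].estimate * np.std(delta, ddof=1)
        )

    def test_zero_variance_delta_rejected(self):
        t = table_from(
            truth_bmi=np.linspace(20, 35, 40),
            pred_bmi=np.linspace(20, 35, 40) + 1.0,
            truth_vat=np.linspace(2, 8, 40),
        )
        with pytest.raises(ValueError, match="zero variance"):
            vat_regression(t)

    def test_too_few_vat_subjects_rejected(self):
        t = table_from(truth_bmi=[25.0] * 10, pred_bmi=[26.0] * 10, truth_vat=[5.0] * 10)
        with pytest.raises(ValueError, match=">= 30"):
            vat_regression(t)


def simulate_or_table(n, slope, seed, confounded=False):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    age = rng.uniform(45, 75, n)
    bmi = rng.normal(26, 4, n)
    y = rng.random(n) < expit(-1.0 + slope * z)
    return table_from(index=z, age=age, truth_bmi=bmi, htn=y.astype(int))


class TestComorbidityOr:
    def test_known_slope_recovered(self):
        t = simulate_or_table(20000, 0.5, seed=3)
        res = comorbidity_or(t, "index", "htn")
        assert res.estimate == pytest.approx(np.exp(0.5), abs=0.08)
        assert res.ci_low < np.exp(0.5) < res.ci_high

    def test_null_coverage_over_seeds(self):
        covered = 0
        for seed in range(100):
            t = simulate_or_table(2000, 0.0, seed=seed)
            res = comorbidity_or(t, "index", "htn")
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 90

    def test_invariant_to_affine_rescaling(self):
        t = simulate_or_table(3000, 0.4, seed=5)
        a = comorbidity_or(t, "index", "htn")
        t2 = t.assign(index=5.0 * t["index"] + 3.0)
        b = comorbidity_or(t2, "index", "htn")
        assert a.estimate == pytest.approx(b.estimate, rel=1e-8)

    def test_degenerate_condition_rejected(self):
        t = simulate_or_table(100, 0.0, seed=6).assign(htn=0)
        with pytest.raises(ValueError, match="degenerate"):
            comorbidity_or(t, "index", "htn")

    def test_too_few_cases_rejected(self):
        t = simulate_or_table(100, 0.0, seed=7).assign(htn=[1] * 3 + [0] * 97)
        with pytest.raises(ValueError, match="cases"):
            comorbidity_or(t, "index", "htn")

    def test_delta_bmi_index_derived_when_missing(self):
        t = simulate_or_table(2000, 0.5, seed=8)
        t = t.assign(pred_bmi=t["truth_bmi"] + t["index"])
        res = comorbidity_or(t, "delta_bmi", "htn")
        assert res.extras["index"] == "delta_bmi"
        assert res.estimate > 1.0


def chi2_bruteforce(obs):
    obs = np.asarray(obs, dtype=float)
    row, col, n = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True), obs.sum()
    expected = row @ col / n
    return float(((obs - expected) ** 2 / expected).sum())


def groups_table(counts):
    """Build a table realizing given (group, condition) 2x2 counts."""
    rows = []
    for (group, flag), n in counts.items():
        truth, pred = {"TP": (27, 1), "FN": (27, 0), "TN": (22, 0), "FP": (22, 1)}[group]
        rows += [{"truth_bmi": truth, "pred_class": pred, "htn": flag,
                  "chd": 0, "dm": 0, "dyslip": 0}] * n
    # ensure every group is populated for the other conditions' tests
    for g in ("TP", "FN", "TN", "FP"):
        if not any(k[0] == g for k in counts):
            truth, pred = {"TP": (27, 1), "FN": (27, 0), "TN": (22, 0), "FP": (22, 1)}[g]
            rows += [{"truth_bmi": truth, "pred_class": pred, "htn": 0,
                      "chd": 0, "dm": 0, "dyslip": 0}] * 10
    return pd.DataFrame(rows)


class TestMisclassificationChi2:
    def test_matches_bruteforce_definition(self):
        # TP vs FN table [[30,10],[20,40]] on condition flags
        t = groups_table({("TP", 1): 30, ("TP", 0): 10, ("FN", 1): 20, ("FN", 0): 40})
        results = misclassification_chi2(t)
        r = next(x for x in results if x.extras["condition"] == "htn"
                 and x.extras["contrast"] == "TP_vs_FN")
        assert r.estimate == pytest.approx(16.667, abs=5e-4)
        assert r.estimate == pytest.approx(chi2_bruteforce([[30, 10], [20, 40]]), abs=1e-10)

    def test_equal_proportions_give_zero_statistic(self):
        t = groups_table({("TP", 1): 10, ("TP", 0): 30, ("FN", 1): 5, ("FN", 0): 15})
        results = misclassification_chi2(t)
        r = next(x for x in results if x.extras["condition"] == "htn"
                 and x.extras["contrast"] == "TP_vs_FN")
        assert r.estimate == pytest.approx(0.0, abs=1e-10)
        assert r.p_value == pytest.approx(1.0)

    def test_family_size_and_correction_metadata(self):
        t = groups_table({("TP", 1): 30, ("TP", 0): 10, ("FN", 1): 20, ("FN", 0): 40})
        results = misclassification_chi2(t)
        assert len(results) == 8  # 4 conditions x 2 contrasts
        assert all(r.correction == "BH" for r in results)

    def test_small_expected_cell_skipped(self):
        t = groups_table({("TP", 1): 1, ("TP", 0): 200, ("FN", 1): 0, ("FN", 0): 2})
        results = misclassification_chi2(t)
        r = next(x for x in results if x.extras["condition"] == "htn"
                 and x.extras["contrast"] == "TP_vs_FN")
        assert r.extras.get("skipped") is True


class TestBenjaminiHochberg:
    def test_stepup_oracle(self):
        adj = bh_adjust([0.01, 0.02, 0.04, 0.20])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.0533, 0.20], atol=5e-5)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=16))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_adjustment_never_decreases_and_stays_a_pvalue(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(9)
        p = rng.random(20)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestBinarizedRoc:
    def test_perfect_and_reversed(self):
        t = table_from(pred_bmi=[20, 23, 26, 30.0], truth_bmi=[21, 24, 27, 31.0])
        assert binarized_roc(t, "bmi") == 1.0
        t2 = t.assign(pred_bmi=-t["pred_bmi"])
        assert binarized_roc(t2, "bmi") == 0.0

    def test_null_within_3se_of_half(self):
        rng = np.random.default_rng(10)
        n = 2000
        t = table_from(pred_bmi=rng.normal(size=n), truth_bmi=rng.normal(26, 4, n))
        auc = binarized_roc(t, "bmi")
        npos = (t["truth_bmi"] >= 25).sum()
        se = np.sqrt(1 / (12 * npos) + 1 / (12 * (n - npos)))
        assert abs(auc - 0.5) <= 3 * se

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        t = table_from(pred_bmi=rng.normal(26, 3, 200), truth_bmi=rng.normal(26, 4, 200))
        t2 = t.assign(pred_bmi=-t["pred_bmi"])
        assert binarized_roc(t, "bmi") + binarized_roc(t2, "bmi") == pytest.approx(1.0)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_antisymmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        t = table_from(pred_bmi=rng.normal(26, 3, 80), truth_bmi=rng.normal(26, 4, 80))
        if (t["truth_bmi"] >= 25).nunique() < 1 or (t["truth_bmi"] >= 25).all() or not (t["truth_bmi"] >= 25).any():
            return
        t2 = t.assign(pred_bmi=-t["pred_bmi"])
        assert binarized_roc(t, "bmi") + binarized_roc(t2, "bmi") == pytest.approx(1.0)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(12)
        scores = rng.integers(0, 5, 60).astype(float)  # many ties
        labels = rng.integers(0, 2, 60)
        t = table_from(pred_bmi=scores, truth_bmi=np.where(labels == 1, 30.0, 20.0))
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        assert binarized_roc(t, "bmi") == pytest.approx(wins / (len(pos) * len(neg)))

    def test_vat_uses_sample_median(self):
        rng = np.random.default_rng(13)
        vat = rng.uniform(1, 9, 101)
        t = table_from(pred_vat=vat + rng.normal(0, 0.1, 101), truth_vat=vat)
        assert binarized_roc(t, "vat") > 0.9

    def test_single_class_rejected(self):
        t = table_from(pred_bmi=[26.0, 27.0], truth_bmi=[27.0, 30.0])
        with pytest.raises(ValueError, match="empty"):
            binarized_roc(t, "bmi")


class TestRmse:
    def test_perfect_predictions(self):
        t = table_from(pred_bmi=[25.0, 30.0], truth_bmi=[25.0, 30.0])
        assert rmse(t, "bmi").estimate == 0.0

    def test_unit_errors(self):
        t = table_from(pred_bmi=[26, 24, 26, 24.0], truth_bmi=[25.0] * 4)
        assert rmse(t, "bmi").estimate == pytest.approx(1.0)

    def test_constant_predictor_equals_population_sd(self):
        rng = np.random.default_rng(14)
        truth = rng.normal(26, 4, 500)
        t = table_from(pred_bmi=np.full(500, truth.mean()), truth_bmi=truth)
        assert rmse(t, "bmi").estimate == pytest.approx(np.std(truth), rel=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rmse(table_from(pred_bmi=[], truth_bmi=[]), "bmi")
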