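"""ROI/patient aggregation, ROC machinery, cutoff selection, G3 pathway."""

import numpy as np
import pandas as pd
import pytest
from oracles import auc_pairs
from scipy.stats import mannwhitneyu

from nucrisk.riskagg import (
    best_cutoff,
    classify_patients,
    confusion_metrics,
    g3_pathway,
    percent_positive,
    roc_analysis,
    roi_median_nrs,
    select_patient_cutoff,
    split_patients,
)


def scores_frame(nrs, patient="p1", roi=None):
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(nrs))],
        "patient_id": patient if isinstance(patient, list) else [patient] * len(nrs),
        "roi_id": roi or [f"{patient}_r0"] * len(nrs),
        "nrs": nrs,
    })


class TestRoiMedian:
    def test_even_count_median(self):
        out = roi_median_nrs(scores_frame([0.2, 0.8]))
        assert out["median_nrs"].iloc[0] == pytest.approx(0.5)

    def test_constant_scores(self):
        out = roi_median_nrs(scores_frame([0.7] * 5))
        assert out["median_nrs"].iloc[0] == 0.7

    def test_matches_sort_oracle(self, rng):
        vals = rng.random(31)
        out = roi_median_nrs(scores_frame(list(vals)))
        s = np.sort(vals)
        assert out["median_nrs"].iloc[0] == pytest.approx(s[15], abs=1e-12)


class TestPercentPositive:
    @pytest.mark.parametrize("nrs,expected", [
        ([0.6, 0.7, 0.5, 0.3], 75.0),
        ([0.1, 0.2], 0.0),
        ([0.9, 0.5, 1.0], 100.0),
    ])
    def test_fraction_at_cutoff(self, nrs, expected):
        out = percent_positive(scores_frame(nrs))
        assert out["percent_positive"].iloc[0] == pytest.approx(expected)

    def test_missing_patient_is_error(self):
        pats = pd.DataFrame({"patient_id": ["p1", "p2"], "ln_status": ["LN0", "LN+"]})
        with pytest.raises(ValueError, match="0 epithelial cells"):
            percent_positive(scores_frame([0.5]), patients=pats)

    def test_invariant_to_monotone_transform_preserving_boundary(self, rng):
        vals = rng.random(200)
        p1 = percent_positive(scores_frame(list(vals)))["percent_positive"].iloc[0]
        transformed = 0.5 + np.sign(vals - 0.5) * np.abs(vals - 0.5) ** 2
        p2 = percent_positive(scores_frame(list(transformed)))["percent_positive"].iloc[0]
        assert p1 == p2


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0

    def test_null_large_sample(self, rng):
        vals = rng.random(2000)
        labels = rng.random(2000) < 0.5
        assert roc_analysis(vals, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_hand_enumerated_pairs(self):
        assert roc_analysis([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
        assert roc_analysis([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2], [1, 1])

    def test_sensitivity_monotone_in_threshold(self, rng):
        vals = rng.random(100)
        labels = rng.random(100) < 0.4
        roc = roc_analysis(vals, labels)
        assert (np.diff(roc.sensitivity) >= 0).all()  # thresholds descending

    def test_auc_equals_mann_whitney(self, rng):
        """AUC == U/(n0*n1) with tie credit, on random tied instances."""
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(10, 51))
            vals = r.integers(0, 8, n).astype(float)  # heavy ties
            labels = r.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = roc_analysis(vals, labels)
            u = mannwhitneyu(vals[labels], vals[~labels], alternative="two-sided").statistic
            expected = u / (labels.sum() * (~labels).sum())
            assert roc.auc == pytest.approx(expected, abs=1e-12)
            assert roc.auc == pytest.approx(auc_pairs(vals, labels), abs=1e-12)


class TestBestCutoff:
    def test_separated_values_tie_break_to_larger_threshold(self):
        roc = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        res = best_cutoff(roc)
        assert res.youden_j == pytest.approx(1.0)
        assert res.cutoff == 10  # largest separating observed threshold

    def test_confusion_metric_arithmetic(self):
        """TP=11 FN=0 TN=11 FP=1: 100% sens, 91.7% spec/PPV, 100% NPV, 95.7% acc."""
        m = confusion_metrics(tp=11, fn=0, tn=11, fp=1)
        assert 100 * m["sensitivity"] == pytest.approx(100.0)
        assert 100 * m["specificity"] == pytest.approx(91.7, abs=0.05)
        assert 100 * m["ppv"] == pytest.approx(91.7, abs=0.05)
        assert 100 * m["npv"] == pytest.approx(100.0)
        assert 100 * m["accuracy"] == pytest.approx(95.7, abs=0.05)

    def test_strong_cohort_operating_point(self, fitted_results):
        """On a strong-effect synthetic cohort the chosen patient cutoff
        reaches sensitivity and specificity >= 0.85 in training."""
        m = fitted_results.patient_cutoff.metrics
        assert m["sensitivity"] >= 0.85
        assert m["specificity"] >= 0.85


class TestClassifyPatients:
    def _summaries(self, pcts):
        return pd.DataFrame({"patient_id": [f"p{i}" for i in range(len(pcts))],
                             "percent_positive": pcts})

    def test_strict_comparator_at_cutoff(self):
        out = classify_patients(self._summaries([61.0, 61.1, 10.0]), cutoff=61.0, comparator=">")
        assert list(out["risk_group"]) == ["low", "high", "low"]

    def test_ge_comparator(self):
        out = classify_patients(self._summaries([61.0]), cutoff=61.0, comparator=">=")
        assert out["risk_group"].iloc[0] == "high"

    def test_all_below_cutoff(self):
        out = classify_patients(self._summaries([1.0, 2.0]), cutoff=61.0)
        assert (out["risk_group"] == "low").all()


class TestPatientSplit:
    def test_no_overlap_and_stratified(self):
        pats = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(29)],
            "ln_status": ["LN0"] * 15 + ["LN+"] * 14,
        })
        train, test = split_patients(pats, 0.8, seed=0)
        assert not set(train) & set(test)
        assert len(train) == 23 and len(test) == 6  # 12/11 vs 3/3 structure
        ln = pats.set_index("patient_id")["ln_status"]
        assert sum(ln[p] == "LN0" for p in train) == 12
        assert sum(ln[p] == "LN+" for p in train) == 11

    def test_cutoff_frozen_before_test_evaluation(self):
        train = pd.DataFrame({"patient_id": list("abcdef"),
                              "ln_status": ["LN0"] * 3 + ["LN+"] * 3,
                              "percent_positive": [10, 20, 30, 70, 80, 90.0]})
        test = pd.DataFrame({"patient_id": ["x", "y"], "ln_status": ["LN0", "LN+"],
                             "percent_positive": [40.0, 75.0]})
        res = select_patient_cutoff(train, test)
        assert res["cutoff"].cutoff == 70
        assert res["test_metrics"]["accuracy"] == 1.0


class TestG3Pathway:
    def test_printed_configuration_accuracy(self):
        """5 LN+ / 1 LN0; 4 of 5 positives and the negative called correctly
        at the 25% cutoff: 80% sens, 100% spec, 83.3% accuracy."""
        g3 = pd.DataFrame({
            "patient_id": [f"g{i}" for i in range(6)],
            "grade": ["G3"] * 6,
            "ln_status": ["LN+"] * 5 + ["LN0"],
            "percent_positive": [80.0, 60.0, 40.0, 30.0, 10.0, 5.0],
        })
        res, groups = g3_pathway(g3, cutoff=25.0)
        assert 100 * res.metrics["sensitivity"] == pytest.approx(80.0)
        assert 100 * res.metrics["specificity"] == pytest.approx(100.0)
        assert 100 * res.metrics["accuracy"] == pytest.approx(83.3, abs=0.05)

    def test_all_above_cutoff(self):
        g3 = pd.DataFrame({"patient_id": ["a", "b"], "grade": ["G3", "G3"],
                           "ln_status": ["LN+", "LN0"],
                           "percent_positive": [90.0, 80.0]})
        res, _ = g3_pathway(g3, cutoff=25.0)
        assert res.metrics["sensitivity"] == 1.0
        assert res.metrics["specificity"] == 0.0

    def test_zero_cutoff_everyone_high_risk(self):
        g3 = pd.DataFrame({"patient_id": ["a", "b"], "grade": ["G3", "G3"],
                           "ln_status": ["LN+", "LN0"],
                           "percent_positive": [50.0, 1.0]})
        _, groups = g3_pathway(g3, cutoff=0.0)
        assert (groups["risk_group"] == "high").all()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty G3"):
            g3_pathway(pd.DataFrame(columns=["patient_id", "grade", "ln_status",
                                             "percent_positive"]))
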