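"""Scenario assembly, cross-validated classification, and confusion metrics."""

import numpy as np
import pandas as pd
import pytest

from qeeg.classify import (
    SCENARIOS,
    ClassifierSpec,
    TieBreakKNN,
    assemble_features,
    build_estimator,
    crossval_classify,
    metrics_from_confusion,
)
from qeeg.group_stats import GROUP_COL

from ._oracles import one_vs_rest_metrics

#: Highest-accuracy confusion matrix of the three-group study
#: (rows actual normal / MCI / dementia, columns predicted).
STUDY_CM = pd.DataFrame(
    [[17, 1, 0], [0, 19, 0], [0, 1, 12]],
    index=["normal", "stroke_mci", "stroke_dementia"],
    columns=["normal", "stroke_mci", "stroke_dementia"],
)


def fake_feature_sets(rng, subjects=None):
    subjects = subjects or [f"s{i}" for i in range(12)]
    def frame(prefix, k):
        return pd.DataFrame(
            rng.standard_normal((len(subjects), k)),
            index=subjects,
            columns=[f"{prefix}{i}" for i in range(k)],
        )
    return {
        "relative_power": frame("RP", 76),
        "coherence": frame("COH", 64),
        "spec_en": frame("SPECEN", 19),
        "spec_de": frame("SPECDE", 19),
    }


class TestScenarios:
    def test_scenario_definitions(self):
        assert SCENARIOS["A"] == ("relative_power",)
        assert SCENARIOS["B"] == ("coherence",)
        assert SCENARIOS["C"] == ("spec_en",)
        assert SCENARIOS["D"] == ("spec_de",)
        assert SCENARIOS["E"] == ("coherence", "spec_de")

    @pytest.mark.parametrize(
        "scenario, n_cols", [("A", 76), ("B", 64), ("C", 19), ("D", 19), ("E", 83)]
    )
    def test_assembled_column_counts(self, rng, scenario, n_cols):
        fm = assemble_features(fake_feature_sets(rng), scenario)
        assert fm.shape[1] == n_cols

    def test_scenario_e_column_order_coherence_then_specde(self, rng):
        fm = assemble_features(fake_feature_sets(rng), "E")
        assert fm.columns[0].startswith("COH")
        assert fm.columns[-1].startswith("SPECDE")

    def test_missing_subject_named_in_error(self, rng):
        sets = fake_feature_sets(rng)
        sets["spec_de"] = sets["spec_de"].drop(index="s3")
        with pytest.raises(ValueError, match="s3"):
            assemble_features(sets, "E")

    def test_empty_subject_list_rejected(self, rng):
        sets = {k: v.iloc[:0] for k, v in fake_feature_sets(rng).items()}
        with pytest.raises(ValueError, match="no subjects"):
            assemble_features(sets, "C")

    def test_unknown_scenario_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown scenario"):
            assemble_features(fake_feature_sets(rng), "F")


def blobs_matrix(rng, spread=0.1, n_per_class=15):
    """Three well-separated Gaussian blobs; every dimension is informative
    (signal-free dimensions would be amplified into noise by z-scoring)."""
    centers = np.eye(3) * 10
    rows, labels = [], []
    for i, g in enumerate(["normal", "stroke_mci", "stroke_dementia"]):
        rows.append(centers[i] + spread * rng.standard_normal((n_per_class, 3)))
        labels += [g] * n_per_class
    fm = pd.DataFrame(np.vstack(rows), columns=[f"x{i}" for i in range(3)])
    fm[GROUP_COL] = labels
    fm.index = [f"s{i:02d}" for i in range(len(fm))]
    return fm


class TestCrossval:
    @pytest.mark.parametrize("variant", [
        "linear_svm", "quadratic_svm", "cubic_svm", "gaussian_svm",
        "fine_knn", "medium_knn", "cubic_knn",
    ])
    def test_separable_blobs_classified_perfectly(self, rng, variant):
        fm = blobs_matrix(rng)
        res = crossval_classify(fm, variant, k_folds=5, seed=0)
        assert res.accuracy == 100.0
        assert np.trace(res.confusion.to_numpy()) == len(fm)

    def test_each_subject_predicted_exactly_once(self, rng):
        fm = blobs_matrix(rng, spread=5.0)
        res = crossval_classify(fm, "gaussian_svm", k_folds=5, seed=3)
        assert res.confusion.to_numpy().sum() == len(fm)
        assert res.confusion.to_numpy().sum(axis=1).tolist() == [15, 15, 15]
        assert len(res.fold_accuracies) == 5

    def test_null_labels_score_near_chance(self, rng):
        accs = []
        for rep in range(50):
            X = rng.standard_normal((45, 8))
            y = np.array(["normal", "stroke_mci", "stroke_dementia"] * 15)
            rng.shuffle(y)
            fm = pd.DataFrame(X, columns=[f"x{i}" for i in range(8)])
            fm[GROUP_COL] = y
            fm.index = [f"s{i:02d}" for i in range(45)]
            res = crossval_classify(fm, "gaussian_svm", k_folds=5, seed=rep)
            accs.append(res.accuracy)
        assert 20.0 <= np.mean(accs) <= 47.0

    def test_subject_order_invariance(self, rng):
        fm = blobs_matrix(rng, spread=8.0)
        res1 = crossval_classify(fm, "medium_knn", k_folds=5, seed=2)
        res2 = crossval_classify(
            fm.sample(frac=1.0, random_state=9), "medium_knn", k_folds=5, seed=2
        )
        pd.testing.assert_frame_equal(res1.confusion, res2.confusion)

    def test_class_smaller_than_fold_count_rejected(self, rng):
        fm = blobs_matrix(rng, n_per_class=4)
        with pytest.raises(ValueError, match="stratify"):
            crossval_classify(fm, "gaussian_svm", k_folds=5, seed=0)

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierSpec("quartic_svm")


class TestTieBreakKNN:
    def test_tie_goes_to_nearest_class(self):
        # 2 neighbours, one of each class; the nearer one must win
        X = np.array([[0.0], [1.0]])
        y = np.array(["a", "b"])
        clf = TieBreakKNN(n_neighbors=2).fit(X, y)
        assert clf.predict([[0.1]])[0] == "a"
        assert clf.predict([[0.9]])[0] == "b"

    def test_majority_beats_proximity(self):
        X = np.array([[0.0], [0.5], [0.6]])
        y = np.array(["a", "b", "b"])
        clf = TieBreakKNN(n_neighbors=3).fit(X, y)
        assert clf.predict([[0.05]])[0] == "b"

    def test_minkowski_order_three_changes_geometry(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.array(["a", "b", "c"] * 10)
        e = TieBreakKNN(n_neighbors=10, p=2).fit(X, y)
        c = TieBreakKNN(n_neighbors=10, p=3).fit(X, y)
        q = rng.standard_normal((20, 4))
        # both are valid classifiers; predictions come from the same label set
        assert set(e.predict(q)) | set(c.predict(q)) <= {"a", "b", "c"}

    def test_gaussian_kernel_scale_convention(self):
        est = build_estimator(ClassifierSpec("gaussian_svm"), n_features=83)
        assert est.named_steps["clf"].gamma == pytest.approx(1 / 83)


class TestMetrics:
    def test_study_confusion_matrix_reproduces_printed_metrics(self):
        rep = metrics_from_confusion(STUDY_CM)
        assert rep.accuracy == pytest.approx(96.0, abs=0.05)
        assert rep.sensitivity == pytest.approx(95.6, abs=0.05)
        assert rep.precision == pytest.approx(96.8, abs=0.05)
        recalls = rep.per_class["recall"]
        assert recalls["stroke_mci"] == pytest.approx(100.0, abs=1e-9)
        assert recalls["stroke_dementia"] == pytest.approx(92.3, abs=0.05)
        assert recalls["normal"] == pytest.approx(94.4, abs=0.05)

    def test_perfect_diagonal_scores_hundred(self):
        cm = np.diag([18, 19, 13])
        rep = metrics_from_confusion(cm)
        for v in (rep.accuracy, rep.sensitivity, rep.specificity,
                  rep.precision, rep.f1):
            assert v == 100.0

    def test_random_matrices_match_tally_oracle(self, rng):
        for _ in range(25):
            cm = rng.integers(0, 20, size=(3, 3))
            if cm.sum() == 0:
                continue
            rep = metrics_from_confusion(cm)
            ref = one_vs_rest_metrics(cm)
            assert rep.accuracy == pytest.approx(ref["accuracy"], abs=1e-9)
            assert rep.sensitivity == pytest.approx(ref["sensitivity"], abs=1e-9)
            assert rep.specificity == pytest.approx(ref["specificity"], abs=1e-9)
            assert rep.precision == pytest.approx(ref["precision"], abs=1e-9)
            assert rep.f1 == pytest.approx(ref["f1"], abs=1e-9)

    def test_macro_metrics_invariant_to_class_order(self, rng):
        cm = rng.integers(0, 20, size=(3, 3)) + 1
        perm = [2, 0, 1]
        rep1 = metrics_from_confusion(cm)
        rep2 = metrics_from_confusion(cm[np.ix_(perm, perm)])
        assert rep1.sensitivity == pytest.approx(rep2.sensitivity, abs=1e-9)
        assert rep1.specificity == pytest.approx(rep2.specificity, abs=1e-9)
        assert rep1.f1 == pytest.approx(rep2.f1, abs=1e-9)

    def test_never_predicted_class_gets_zero_precision(self):
        cm = np.array([[5, 0, 0], [5, 0, 0], [0, 0, 5]])
        rep = metrics_from_confusion(cm)
        assert rep.per_class["precision"].iloc[1] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics_from_confusion(np.zeros((3, 3)))
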