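"""Classification pipeline: features, L1 selection, SMOTE, LOOCV, C-sweep."""

import numpy as np
import pandas as pd
import pytest

from docnet.classify import (
    ClassifierConfig,
    FeatureVector,
    assemble_features,
    c_sweep,
    cohort_feature_matrix,
    feature_names,
    l1_logistic_select,
    loocv_evaluate,
    performance_from_confusion,
    smote,
)
from docnet.metrics import GLOBAL_METRICS, NODAL_METRICS


def full_auc_table(region_labels, subjects, rng, class_shift=0.0):
    """Complete AUC table; MCS subjects get `class_shift` added everywhere."""
    rows = []
    for sid, group in subjects:
        bump = class_shift if group == "MCS" else 0.0
        for m in GLOBAL_METRICS:
            rows.append((sid, group, m, "global", rng.normal(bump, 1.0)))
        for m in NODAL_METRICS:
            for lab in region_labels:
                rows.append((sid, group, m, lab, rng.normal(bump, 1.0)))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "metric", "scope", "auc"]
    )


def synthetic_features(rng, n_pos=10, n_neg=20, n_feat=30, sep=3.0):
    """Feature vectors with a controllable class separation on feature 0."""
    names = [f"f{i}" for i in range(n_feat)]
    out = []
    for i in range(n_pos + n_neg):
        label = "MCS" if i < n_pos else "VS"
        x = rng.normal(0.0, 1.0, n_feat)
        if label == "MCS":
            x[0] += sep
        out.append(FeatureVector(f"s{i}", label, x, names))
    return out


class TestFeatureAssembly:
    def test_90_region_vector_has_length_544(self, rng):
        labels = [f"r{i}" for i in range(90)]
        table = full_auc_table(labels, [("s0", "MCS")], rng)
        fv = assemble_features(table, "s0", labels)
        assert fv.features.size == 544
        assert len(fv.feature_names) == 544

    def test_10_region_vector_has_length_64(self, rng):
        labels = [f"r{i}" for i in range(10)]
        table = full_auc_table(labels, [("s0", "VS")], rng)
        assert assemble_features(table, "s0", labels).features.size == 64

    def test_ordering_stable_and_global_first(self, rng):
        labels = [f"r{i}" for i in range(3)]
        names = feature_names(labels)
        assert names[:4] == [f"{m}:global" for m in GLOBAL_METRICS]
        assert names[4:7] == [f"nodal_efficiency:{r}" for r in labels]
        table = full_auc_table(labels, [("a", "MCS"), ("b", "VS")], rng)
        fa = assemble_features(table, "a", labels)
        fb = assemble_features(table, "b", labels)
        assert fa.feature_names == fb.feature_names == names

    def test_missing_metric_listed(self, rng):
        labels = [f"r{i}" for i in range(3)]
        table = full_auc_table(labels, [("s0", "MCS")], rng)
        table = table[table["metric"] != "degree_centrality"]
        with pytest.raises(KeyError, match="degree_centrality"):
            assemble_features(table, "s0", labels)

    def test_cohort_matrix_keeps_only_patient_classes(self, rng):
        labels = [f"r{i}" for i in range(3)]
        table = full_auc_table(
            labels, [("a", "MCS"), ("b", "VS"), ("c", "NC")], rng
        )
        feats = cohort_feature_matrix(table, labels)
        assert [f.subject_id for f in feats] == ["a", "b"]


class TestL1Selection:
    def test_tiny_c_selects_nothing(self, rng):
        X = rng.normal(size=(20, 10))
        y = np.array([0, 1] * 10)
        sel = l1_logistic_select(X, y, C=1e-4)
        assert sel.n_selected == 0

    def test_separating_feature_found_among_noise(self, rng):
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        X = rng.normal(size=(n, 25))
        X[:, 7] = y * 4.0 + rng.normal(0, 0.1, n)
        X = (X - X.mean(0)) / X.std(0)
        sel = l1_logistic_select(X, y, C=0.5)
        assert 7 in sel.selected_indices
        assert sel.n_selected <= 5

    def test_coefficient_sign_matches_class_ordering(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        sel = l1_logistic_select(X, y, C=10.0)
        assert sel.weights[0] > 0

    def test_selection_count_shrinks_with_c(self, rng):
        X = rng.normal(size=(30, 40))
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        n_small = l1_logistic_select(X, y, C=0.05).n_selected
        n_large = l1_logistic_select(X, y, C=1.0).n_selected
        assert n_small <= n_large

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            l1_logistic_select(rng.normal(size=(5, 3)), np.zeros(5), C=1.0)


class TestSmote:
    def test_synthetic_points_are_convex_combinations(self, rng):
        X = rng.normal(size=(12, 4))
        synth, parents, delta = smote(X, k=3, n_synthetic=30, rng=rng,
                                      return_parents=True)
        assert synth.shape == (30, 4)
        for row, (i, j), d in zip(synth, parents, delta):
            np.testing.assert_allclose(row, X[i] + d * (X[j] - X[i]),
                                       atol=1e-12)
            assert 0.0 < d < 1.0

    def test_neighbors_are_k_nearest(self, rng):
        X = rng.normal(size=(10, 3))
        _, parents, _ = smote(X, k=2, n_synthetic=40, rng=rng,
                              return_parents=True)
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        for i, j in parents:
            assert i != j
            rank = np.argsort(d2[i])
            assert j in rank[1:3]  # among the 2 nearest excluding self

    def test_one_dimensional_segment_property(self, rng):
        X = np.array([[0.0], [1.0]])
        synth = smote(X, k=1, n_synthetic=20, rng=rng)
        assert np.all(synth >= 0.0) and np.all(synth <= 1.0)

    def test_minority_not_larger_than_k_rejected(self, rng):
        with pytest.raises(ValueError, match="exceed"):
            smote(np.zeros((3, 2)), k=3, n_synthetic=5, rng=rng)

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            smote(np.zeros((5, 2)), k=0, n_synthetic=1, rng=rng)


class TestPerformance:
    def test_worked_confusion_example(self):
        acc, sens, spec = performance_from_confusion(15, 38, 2, 4)
        assert acc == pytest.approx(89.83, abs=0.005)
        assert sens == pytest.approx(78.95, abs=0.005)
        assert spec == pytest.approx(95.00, abs=0.005)

    def test_perfect_and_degenerate_cases(self):
        assert performance_from_confusion(1, 1, 0, 0) == (100.0, 100.0, 100.0)
        acc, sens, spec = performance_from_confusion(0, 1, 0, 1)
        assert (acc, sens, spec) == (50.0, 0.0, 100.0)

    def test_undefined_metrics_rejected(self):
        with pytest.raises(ValueError, match="sensitivity"):
            performance_from_confusion(0, 5, 1, 0)
        with pytest.raises(ValueError, match="specificity"):
            performance_from_confusion(5, 0, 0, 1)
        with pytest.raises(ValueError):
            performance_from_confusion(-1, 1, 1, 1)


class TestLoocv:
    def test_separable_classes_classified_perfectly(self, rng):
        feats = synthetic_features(rng, sep=8.0)
        rec = loocv_evaluate(feats, C=1.0, config=ClassifierConfig(seed=1))
        assert rec["accuracy"] == 100.0
        assert rec["sensitivity"] == 100.0
        assert rec["specificity"] == 100.0

    def test_confusion_identity_holds(self, rng):
        feats = synthetic_features(rng, n_pos=8, n_neg=15, sep=1.0)
        for C in (0.2, 1.0):
            rec = loocv_evaluate(feats, C=C, config=ClassifierConfig(seed=2))
            assert rec["TP"] + rec["FN"] == 8
            assert rec["TN"] + rec["FP"] == 15

    def test_null_labels_near_majority_rate(self, rng):
        feats = synthetic_features(rng, n_pos=10, n_neg=20, sep=0.0)
        rec = loocv_evaluate(feats, C=0.5, config=ClassifierConfig(seed=3))
        # Pure noise: accuracy should sit in a broad band around the
        # majority-class rate (66.7%), far from perfect.
        assert 35.0 <= rec["accuracy"] <= 85.0

    def test_paper_mode_runs_and_keeps_counts(self, rng):
        feats = synthetic_features(rng, n_pos=8, n_neg=14, sep=2.0)
        rec = loocv_evaluate(
            feats, C=0.5, config=ClassifierConfig(seed=4, paper_mode=True)
        )
        assert rec["TP"] + rec["FN"] == 8
        assert rec["TN"] + rec["FP"] == 14

    def test_too_few_subjects_rejected(self, rng):
        feats = synthetic_features(rng, n_pos=1, n_neg=5)
        with pytest.raises(ValueError):
            loocv_evaluate(feats, C=1.0)


class TestCSweep:
    def test_default_grid_size_91(self):
        n = int(round((1.0 - 0.1) / 0.01)) + 1
        assert n == 91

    def test_sweep_reports_and_flags_best(self, rng):
        feats = synthetic_features(rng, n_pos=8, n_neg=12, n_feat=10, sep=4.0)
        report = c_sweep(feats, 0.2, 0.6, 0.2, ClassifierConfig(seed=5))
        assert len(report) == 3
        assert report["best"].any()
        assert (report.loc[report["best"], "accuracy"]
                == report["accuracy"].max()).all()

    def test_degenerate_grid_single_record(self, rng):
        feats = synthetic_features(rng, n_pos=6, n_neg=9, n_feat=8, sep=4.0)
        report = c_sweep(feats, 0.5, 0.5, 0.01, ClassifierConfig(seed=6))
        assert len(report) == 1
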