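"""MCS-vs-VS classification from network-measure AUC features.

Each subject is a 544-dimensional feature vector (4 global measures plus
6 nodal measures x 90 regions in atlas order). The classifier pipeline is:

* embedded feature selection by L1-penalised logistic regression — the
  cross-entropy loss plus ``lambda * ||w||_1`` with ``C = 1/lambda``
  controlling how many coefficients stay nonzero;
* SMOTE oversampling of the minority class (MCS) up to class balance —
  each synthetic sample is ``x_i + delta * (x_hat - x_i)`` with ``x_hat``
  one of the k nearest minority neighbours and ``delta ~ U(0, 1)``;
* a support-vector machine trained on the selected features, evaluated
  under leave-one-out cross-validation;
* accuracy / sensitivity / specificity from the pooled confusion counts,
  with MCS as the positive class and VS as the negative class.

By default standardisation, selection and SMOTE are all fit inside each
training fold (no information from the held-out subject leaks into the
model). A ``paper_mode`` switch instead performs selection and
oversampling once on the whole cohort before cross-validation; this
matches a common but optimistically biased reading of pipeline orderings
in the applied literature and is provided for comparison only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import GLOBAL_METRICS, NODAL_METRICS

__all__ = [
    "POSITIVE_CLASS",
    "NEGATIVE_CLASS",
    "FeatureVector",
    "SelectionModel",
    "ClassifierConfig",
    "feature_names",
    "assemble_features",
    "cohort_feature_matrix",
    "l1_logistic_select",
    "smote",
    "performance_from_confusion",
    "loocv_evaluate",
    "c_sweep",
]

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "MCS"
NEGATIVE_CLASS = "VS"


@dataclass
class FeatureVector:
    subject_id: str
    label: str  # POSITIVE_CLASS or NEGATIVE_CLASS
    features: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 1:
            raise ValueError("features must be a vector")
        if len(self.feature_names) != self.features.size:
            raise ValueError("feature_names must align with features")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")


@dataclass
class SelectionModel:
    C: float
    weights: np.ndarray
    selected_indices: np.ndarray

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)


@dataclass
class ClassifierConfig:
    """Knobs of the LOOCV pipeline (defaults follow the module docstring)."""

    smote_k: int = 5
    svm_kernel: str = "linear"
    svm_cost: float = 1.0
    paper_mode: bool = False
    seed: int = 0


def feature_names(region_labels: list[str]) -> list[str]:
    """Deterministic feature ordering: 4 global, then each nodal measure
    across all regions in atlas order."""
    names = [f"{m}:global" for m in GLOBAL_METRICS]
    for m in NODAL_METRICS:
        names.extend(f"{m}:{r}" for r in region_labels)
    return names


def assemble_features(
    auc_table: pd.DataFrame,
    subject_id: str,
    region_labels: list[str],
) -> FeatureVector:
    """Build one subject's feature vector from the cohort AUC table.

    Length is 4 + 6 * n_regions (544 for a 90-region atlas). Raises with
    the list of missing keys if the subject's AUC entries are incomplete.
    """
    sub = auc_table[auc_table["subject_id"] == subject_id]
    if sub.empty:
        raise KeyError(f"subject {subject_id!r} not in AUC table")
    lookup = {(m, s): v for m, s, v in zip(sub["metric"], sub["scope"], sub["auc"])}
    names = feature_names(region_labels)
    keys = [(m, "global") for m in GLOBAL_METRICS] + [
        (m, r) for m in NODAL_METRICS for r in region_labels
    ]
    missing = [k for k in keys if k not in lookup]
    if missing:
        raise KeyError(
            f"subject {subject_id!r} is missing AUC entries for: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    vec = np.array([lookup[k] for k in keys])
    label = str(sub["group"].iloc[0])
    return FeatureVector(subject_id=subject_id, label=label,
                         features=vec, feature_names=names)


def cohort_feature_matrix(
    auc_table: pd.DataFrame, region_labels: list[str]
) -> list[FeatureVector]:
    """Feature vectors for every MCS/VS subject in the table, stable order."""
    sids = auc_table["subject_id"].drop_duplicates().tolist()
    out = []
    for sid in sids:
        fv = assemble_features(auc_table, sid, region_labels)
        if fv.label in (POSITIVE_CLASS, NEGATIVE_CLASS):
            out.append(fv)
    return out


def l1_logistic_select(
    X: np.ndarray, y: np.ndarray, C: float
) -> SelectionModel:
    """Embedded feature selection by L1-penalised logistic regression.

    Minimises the logistic cross-entropy plus ``(1/C) * ||w||_1`` and
    returns the indices whose coefficients stay nonzero. Features are
    expected standardised. ``C`` is the reciprocal of the regularisation
    strength: smaller C, heavier penalty, fewer survivors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need both classes present for selection")
    if C <= 0:
        raise ValueError("C must be positive")
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-8, max_iter=10_000,
        random_state=0,
    )
    model.fit(X, y)
    w = model.coef_.ravel()
    return SelectionModel(C=C, weights=w, selected_indices=np.flatnonzero(w != 0.0))


def smote(
    minority_X: np.ndarray,
    k: int,
    n_synthetic: int,
    rng: np.random.Generator | int | None = None,
    return_parents: bool = False,
):
    """Synthetic minority oversampling by nearest-neighbour interpolation.

    For each synthetic sample a minority point ``x_i`` is taken (cycling
    through the minority class), one of its k Euclidean nearest minority
    neighbours ``x_hat`` is drawn, and the sample is
    ``x_i + delta * (x_hat - x_i)`` with ``delta ~ Uniform(0, 1)`` — a
    point on the open segment between two real minority points. The
    majority class is never touched.
    """
    minority_X = np.asarray(minority_X, dtype=float)
    m = minority_X.shape[0]
    if k < 1:
        raise ValueError("k must be at least 1")
    if m <= k:
        raise ValueError(f"minority size {m} must exceed k={k}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority_X)
    _, nbr = nn.kneighbors(minority_X)
    nbr = nbr[:, 1:]  # drop self

    base = np.arange(n_synthetic) % m
    pick = rng.integers(0, k, size=n_synthetic)
    partner = nbr[base, pick]
    delta = rng.random(n_synthetic)
    synth = minority_X[base] + delta[:, None] * (
        minority_X[partner] - minority_X[base]
    )
    if return_parents:
        return synth, np.column_stack([base, partner]), delta
    return synth


def performance_from_confusion(
    TP: int, TN: int, FP: int, FN: int
) -> tuple[float, float, float]:
    """Accuracy, sensitivity and specificity (percent) from confusion counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP). Raises when a metric's denominator is zero.
    """
    for name, v in (("TP", TP), ("TN", TN), ("FP", FP), ("FN", FN)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    total = TP + TN + FP + FN
    if total == 0:
        raise ValueError("confusion matrix is empty")
    if TP + FN == 0:
        raise ValueError("sensitivity undefined: no positive cases")
    if TN + FP == 0:
        raise ValueError("specificity undefined: no negative cases")
    return (
        100.0 * (TP + TN) / total,
        100.0 * TP / (TP + FN),
        100.0 * TN / (TN + FP),
    )


def _fit_predict_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    C: float,
    config: ClassifierConfig,
    rng: np.random.Generator,
    select: bool = True,
) -> tuple[np.ndarray, int]:
    """Train select+SMOTE+SVM on one training fold, predict the test rows.

    y is encoded 1 = positive (MCS), 0 = negative (VS). Returns the
    predictions and the selected-feature count.
    """
    scaler = StandardScaler().fit(X_train)
    Xs = scaler.transform(X_train)
    Xt = scaler.transform(X_test)

    if select:
        sel = l1_logistic_select(Xs, y_train, C)
        if sel.n_selected == 0:
            logger.warning("C=%g: empty selection; predicting majority class", C)
            majority = int(np.bincount(y_train).argmax())
            return np.full(X_test.shape[0], majority), 0
        idx = sel.selected_indices
    else:
        idx = np.arange(Xs.shape[1])
    Xs, Xt = Xs[:, idx], Xt[:, idx]

    n_pos = int((y_train == 1).sum())
    n_neg = int((y_train == 0).sum())
    if 0 < n_pos < n_neg and n_pos > config.smote_k:
        synth = smote(Xs[y_train == 1], config.smote_k, n_neg - n_pos, rng)
        Xs = np.vstack([Xs, synth])
        y_train = np.concatenate([y_train, np.ones(len(synth), dtype=int)])

    clf = SVC(kernel=config.svm_kernel, C=config.svm_cost, random_state=0)
    clf.fit(Xs, y_train)
    return clf.predict(Xt), len(idx)


def loocv_evaluate(
    features: list[FeatureVector],
    C: float,
    config: ClassifierConfig | None = None,
) -> dict:
    """Leave-one-out evaluation of the select + SMOTE + SVM pipeline at one C.

    Each subject is held out once; standardisation, L1 selection and SMOTE
    are fit on the remaining subjects (or once on the whole cohort in
    ``paper_mode``). Returns pooled confusion counts, the three
    performance metrics and the median selected-feature count.
    """
    config = config or ClassifierConfig()
    y = np.array([1 if f.label == POSITIVE_CLASS else 0 for f in features])
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    X = np.vstack([f.features for f in features])
    n = len(features)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    preds = np.empty(n, dtype=int)
    n_sel: list[int] = []
    if config.paper_mode:
        # Whole-cohort standardisation, selection and oversampling before
        # cross-validation; synthetic samples always train, never test.
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        sel = l1_logistic_select(Xs, y, C)
        idx = sel.selected_indices if sel.n_selected else np.arange(X.shape[1])
        n_sel.append(sel.n_selected)
        Xf = Xs[:, idx]
        n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
        if 0 < n_pos < n_neg and n_pos > config.smote_k:
            synth = smote(Xf[y == 1], config.smote_k, n_neg - n_pos, rng)
        else:
            synth = np.empty((0, Xf.shape[1]))
        for i in range(n):
            mask = np.arange(n) != i
            Xtr = np.vstack([Xf[mask], synth])
            ytr = np.concatenate([y[mask], np.ones(len(synth), dtype=int)])
            clf = SVC(kernel=config.svm_kernel, C=config.svm_cost, random_state=0)
            clf.fit(Xtr, ytr)
            preds[i] = clf.predict(Xf[i : i + 1])[0]
    else:
        for i in range(n):
            mask = np.arange(n) != i
            fold_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 3, i])
            )
            p, ns = _fit_predict_fold(
                X[mask], y[mask], X[i : i + 1], C, config, fold_rng
            )
            preds[i] = p[0]
            n_sel.append(ns)

    TP = int(((preds == 1) & (y == 1)).sum())
    TN = int(((preds == 0) & (y == 0)).sum())
    FP = int(((preds == 1) & (y == 0)).sum())
    FN = int(((preds == 0) & (y == 1)).sum())
    acc, sens, spec = performance_from_confusion(TP, TN, FP, FN)
    return {
        "C": C,
        "TP": TP,
        "TN": TN,
        "FP": FP,
        "FN": FN,
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "n_selected_features": float(np.median(n_sel)) if n_sel else 0.0,
    }


def c_sweep(
    features: list[FeatureVector],
    c_min: float = 0.1,
    c_max: float = 1.0,
    step: float = 0.01,
    config: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """LOOCV performance across the regularisation grid (91 values at defaults).

    Returns one row per C with confusion counts and performance; the row
    attaining the best accuracy is flagged in the ``best`` column.
    """
    if not (0 < c_min <= c_max):
        raise ValueError("require 0 < c_min <= c_max")
    n = int(round((c_max - c_min) / step)) + 1 if step > 0 else 1
    grid = [round(c_min + i * step, 10) for i in range(n)]
    records = [loocv_evaluate(features, C, config) for C in grid]
    out = pd.DataFrame.from_records(records)
    out["best"] = out["accuracy"] == out["accuracy"].max()
    return out
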