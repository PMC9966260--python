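"""Scenario assembly, cross-validated SVM / k-NN evaluation, and metrics.

Five predictor scenarios are evaluated: A relative power, B coherence,
C spectral entropy, D spectral dispersion entropy, E coherence + SpecDE.
Classifiers follow the clinical-toolbox conventions: SVMs (one-vs-one,
penalty C = 1) with linear / quadratic / cubic / Gaussian kernels, where the
Gaussian kernel scale is sqrt(#predictors); k-NN in fine (k=1, Euclidean),
medium (k=10, Euclidean) and cubic (k=10, Minkowski order 3) variants.

Features are z-scored with training-fold statistics only, folds are
stratified by class, and each subject is predicted exactly once; the
reported accuracy is the average of the per-fold accuracies, and the other
metrics derive from the confusion matrix aggregated over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .group_stats import GROUP_COL
from .montage import GROUP_ORDER

#: Predictor groups per scenario.
SCENARIOS: dict[str, tuple[str, ...]] = {
    "A": ("relative_power",),
    "B": ("coherence",),
    "C": ("spec_en",),
    "D": ("spec_de",),
    "E": ("coherence", "spec_de"),
}

#: All classifier variants evaluated in the benchmark tables.
CLASSIFIER_VARIANTS = (
    "linear_svm", "quadratic_svm", "cubic_svm", "gaussian_svm",
    "fine_knn", "medium_knn", "cubic_knn",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier configuration.

    SVM variants use penalty C = 1; the Gaussian kernel is
    K(x, x') = exp(-||x - x'||^2 / s^2) with scale s = sqrt(#predictors).
    k-NN variants: fine k=1 Euclidean, medium k=10 Euclidean,
    cubic k=10 Minkowski order 3.
    """

    variant: str

    def __post_init__(self) -> None:
        if self.variant not in CLASSIFIER_VARIANTS:
            raise ValueError(
                f"unknown classifier {self.variant!r}; "
                f"expected one of {CLASSIFIER_VARIANTS}"
            )

    @property
    def family(self) -> str:
        return "svm" if self.variant.endswith("svm") else "knn"


class TieBreakKNN(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbour classifier with deterministic tie breaking.

    Majority vote among the k nearest training points; when classes tie,
    the class of the nearest neighbour among the tied classes wins.
    """

    def __init__(self, n_neighbors: int = 1, p: int = 2):
        self.n_neighbors = n_neighbors
        self.p = p

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, self._y_idx = np.unique(y, return_inverse=True)
        self._nn = NearestNeighbors(
            n_neighbors=min(self.n_neighbors, len(y)), p=self.p
        ).fit(X)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        _, idx = self._nn.kneighbors(np.asarray(X, dtype=float))
        preds = np.empty(len(idx), dtype=int)
        for i, neigh in enumerate(idx):
            labels = self._y_idx[neigh]
            counts = np.bincount(labels, minlength=len(self.classes_))
            best = np.flatnonzero(counts == counts.max())
            if len(best) == 1:
                preds[i] = best[0]
            else:  # nearest neighbour among tied classes (neighbours are sorted)
                preds[i] = next(lab for lab in labels if lab in best)
        return self.classes_[preds]


def build_estimator(spec: ClassifierSpec, n_features: int) -> Pipeline:
    """Sklearn pipeline (train-fold z-scoring + classifier) for a spec."""
    if spec.variant == "linear_svm":
        clf = SVC(kernel="linear", C=1.0)
    elif spec.variant == "quadratic_svm":
        clf = SVC(kernel="poly", degree=2, gamma=1.0, coef0=1.0, C=1.0)
    elif spec.variant == "cubic_svm":
        clf = SVC(kernel="poly", degree=3, gamma=1.0, coef0=1.0, C=1.0)
    elif spec.variant == "gaussian_svm":
        # K = exp(-||x-x'||^2 / s^2), s = sqrt(p)  =>  sklearn gamma = 1/p
        clf = SVC(kernel="rbf", gamma=1.0 / n_features, C=1.0)
    elif spec.variant == "fine_knn":
        clf = TieBreakKNN(n_neighbors=1, p=2)
    elif spec.variant == "medium_knn":
        clf = TieBreakKNN(n_neighbors=10, p=2)
    elif spec.variant == "cubic_knn":
        clf = TieBreakKNN(n_neighbors=10, p=3)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(spec.variant)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def assemble_features(
    feature_sets: dict[str, pd.DataFrame],
    scenario: str,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Join the per-method feature frames required by a scenario.

    ``feature_sets`` maps predictor-group names (relative_power, coherence,
    spec_en, spec_de) to subjects x features frames sharing a subject index.
    Column order is deterministic (scenario order, then each frame's own
    order).  A ``group`` column is appended when labels are supplied.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected A-E")
    needed = SCENARIOS[scenario]
    missing = [g for g in needed if g not in feature_sets]
    if missing:
        raise ValueError(f"feature set(s) not computed: {', '.join(missing)}")
    frames = [feature_sets[g] for g in needed]
    subjects = frames[0].index
    if len(subjects) == 0:
        raise ValueError("no subjects in feature set")
    for g, f in zip(needed, frames):
        absent = subjects.difference(f.index)
        if len(absent) or len(f.index.difference(subjects)):
            raise ValueError(
                f"subject mismatch in feature set {g!r}: "
                f"{list(absent) or list(f.index.difference(subjects))}"
            )
    fm = pd.concat([f.loc[subjects] for f in frames], axis=1)
    if fm.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    if groups is not None:
        fm[GROUP_COL] = groups.loc[subjects]
    return fm


@dataclass
class CVResult:
    """Cross-validation outcome: aggregate confusion matrix and fold scores."""

    confusion: pd.DataFrame
    fold_accuracies: list[float]
    predictions: pd.Series

    @property
    def accuracy(self) -> float:
        """Average of per-fold accuracies, in percent."""
        return 100.0 * float(np.mean(self.fold_accuracies))

    @property
    def aggregate_accuracy(self) -> float:
        """Pooled accuracy (trace / total) of the aggregate matrix, percent."""
        cm = self.confusion.to_numpy()
        return 100.0 * float(np.trace(cm)) / float(cm.sum())


def crossval_classify(
    fm: pd.DataFrame,
    clf: ClassifierSpec | str,
    k_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validated classification of a feature matrix.

    ``fm`` holds feature columns plus a ``group`` label column.  Folds
    partition subjects (each predicted exactly once); scaling is fit on the
    training fold only.  Fold assignment depends on the seed and on subject
    labels, not on row order.
    """
    if isinstance(clf, str):
        clf = ClassifierSpec(clf)
    if GROUP_COL not in fm.columns:
        raise ValueError(f"feature matrix must contain a {GROUP_COL!r} column")
    fm = fm.sort_index()  # order-invariance given identical subject ids
    y = fm[GROUP_COL].to_numpy()
    X = fm.drop(columns=[GROUP_COL]).to_numpy(dtype=float)
    labels = [g.value for g in GROUP_ORDER if g.value in set(y)]
    counts = pd.Series(y).value_counts()
    if counts.min() < k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects; cannot stratify "
            f"into {k_folds} folds"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    fold_acc = []
    for train, test in skf.split(X, y):
        est = build_estimator(clf, X.shape[1])
        est.fit(X[train], y[train])
        p = est.predict(X[test])
        pred[test] = p
        fold_acc.append(float(np.mean(p == y[test])))
    cm = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for actual, predicted in zip(y, pred):
        cm.loc[actual, predicted] += 1
    return CVResult(
        confusion=cm,
        fold_accuracies=fold_acc,
        predictions=pd.Series(pred, index=fm.index, name="predicted"),
    )


@dataclass
class MetricReport:
    """Macro-averaged one-vs-rest metrics, in percent."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    per_class: pd.DataFrame = field(repr=False, default=None)


def metrics_from_confusion(cm: pd.DataFrame | np.ndarray) -> MetricReport:
    """Accuracy and macro one-vs-rest sensitivity/specificity/precision/F1.

    Rows are actual classes, columns predicted.  Per class, TP is the
    diagonal entry, FN the rest of its row, FP the rest of its column and TN
    everything else; macro metrics are unweighted means over classes.  A
    class never predicted gets precision 0 (its F1 is then 0 as well).
    """
    if isinstance(cm, pd.DataFrame):
        labels = [str(c) for c in cm.index]
        m = cm.to_numpy(dtype=float)
    else:
        m = np.asarray(cm, dtype=float)
        labels = [f"class_{i}" for i in range(m.shape[0])]
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = m.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(m)
    fn = m.sum(axis=1) - tp
    fp = m.sum(axis=0) - tp
    tn = total - tp - fn - fp

    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        spec = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        f1 = np.where(prec + recall > 0, 2 * prec * recall / (prec + recall), 0.0)

    per_class = pd.DataFrame(
        {
            "recall": 100 * recall,
            "specificity": 100 * spec,
            "precision": 100 * prec,
            "f1": 100 * f1,
        },
        index=labels,
    )
    return MetricReport(
        accuracy=100 * float(tp.sum() / total),
        sensitivity=100 * float(recall.mean()),
        specificity=100 * float(spec.mean()),
        precision=100 * float(prec.mean()),
        f1=100 * float(f1.mean()),
        per_class=per_class,
    )
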