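"""Real-vs-generated classification on descriptor features.

Labels follow the convention real = 1 (positive class), generated = 0.
Four tree-family classifiers mirror the Weka families the detection
literature uses: an information-gain pruned decision tree (C4.5-like), a
fast aggressively pruned tree (REPTree-like), a 100-tree random forest
(the reference family), and a logistic-model-tree approximation (shallow
tree with logistic-regression leaves).  Evaluation pools the out-of-fold
predictions of a seeded stratified 10-fold cross-validation into one
confusion matrix, from which precision, recall, F-measure and accuracy
are computed:

    Precision = TP / (TP + FP)      Recall = TP / (TP + FN)
    F = 2 P R / (P + R)             Accuracy = (TP + TN) / n

Zero-denominator metrics are defined as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_FAMILIES = ("c45_tree", "rep_tree", "random_forest",
                       "logistic_model_tree")
#: CLI short names
CLASSIFIER_ALIASES = {"j48": "c45_tree", "rep": "rep_tree", "rf": "random_forest",
                      "lmt": "logistic_model_tree"}

REAL_LABEL = 1
FAKE_LABEL = 0


# ---------------------------------------------------------------------------
# confusion matrix and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _ratio(num: int, den: int) -> tuple[float, bool]:
    return (0.0, True) if den == 0 else (num / den, False)


def precision(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fp)[0]


def recall(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fn)[0]


def f_measure(cm: ConfusionMatrix) -> float:
    p, r = precision(cm), recall(cm)
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def accuracy(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp + cm.tn, cm.n)[0]


def metrics_from_confusion(cm: ConfusionMatrix) -> dict:
    """All four metrics plus the names of any zero-denominator metrics."""
    p, p_flag = _ratio(cm.tp, cm.tp + cm.fp)
    r, r_flag = _ratio(cm.tp, cm.tp + cm.fn)
    f, f_flag = (0.0, True) if p + r == 0 else (2 * p * r / (p + r), False)
    a, a_flag = _ratio(cm.tp + cm.tn, cm.n)
    flags = [name for name, bad in
             (("precision", p_flag), ("recall", r_flag),
              ("f_measure", f_flag), ("accuracy", a_flag)) if bad]
    return {"precision": p, "recall": r, "f_measure": f, "accuracy": a,
            "degenerate": tuple(flags)}


@dataclass(frozen=True)
class MetricsRecord:
    dataset: str
    filter_id: str
    classifier: str
    epoch: int
    cm: ConfusionMatrix
    precision: float
    recall: float
    f_measure: float
    accuracy: float
    seed: int
    degenerate: tuple = ()

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix, *, dataset: str, filter_id: str,
                       classifier: str, epoch: int, seed: int) -> "MetricsRecord":
        m = metrics_from_confusion(cm)
        return cls(dataset, filter_id, classifier, epoch, cm,
                   m["precision"], m["recall"], m["f_measure"], m["accuracy"],
                   seed, m["degenerate"])


# ---------------------------------------------------------------------------
# feature sets
# ---------------------------------------------------------------------------


@dataclass
class LabeledFeatureSet:
    X: np.ndarray  # (n, L)
    y: np.ndarray  # (n,) in {0, 1}; 1 = real
    filter_id: str
    provenance: dict = field(default_factory=dict)


def assemble_dataset(real_features: np.ndarray, fake_features: np.ndarray,
                     filter_id: str, *, fake_filter_id: str | None = None,
                     seed: int = 0, provenance: dict | None = None
                     ) -> LabeledFeatureSet:
    """Merge real (label 1) and generated (label 0) feature rows and shuffle
    them under the provenance seed."""
    if fake_filter_id is not None and fake_filter_id != filter_id:
        raise ValueError(
            f"filter mismatch: real={filter_id!r}, fake={fake_filter_id!r}")
    real_features = np.atleast_2d(np.asarray(real_features, dtype=np.float64))
    fake_features = np.atleast_2d(np.asarray(fake_features, dtype=np.float64))
    if real_features.size == 0 or fake_features.size == 0:
        raise ValueError("both real and fake feature sets must be non-empty")
    if real_features.shape[1] != fake_features.shape[1]:
        raise ValueError("real and fake feature lengths differ")
    X = np.vstack([real_features, fake_features])
    y = np.concatenate([np.full(len(real_features), REAL_LABEL),
                        np.full(len(fake_features), FAKE_LABEL)])
    order = np.random.default_rng(seed).permutation(len(y))
    return LabeledFeatureSet(X[order], y[order], filter_id,
                             dict(provenance or {}))


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


class LogisticLeafTree(ClassifierMixin, BaseEstimator):
    """Shallow decision tree with a logistic-regression model in each leaf
    that contains both classes (majority vote otherwise)."""

    def __init__(self, max_depth=3, min_samples_leaf=15, random_state=0):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.tree_ = DecisionTreeClassifier(
            criterion="entropy", max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state)
        self.tree_.fit(X, y)
        self.leaf_models_ = {}
        leaves = self.tree_.apply(X)
        for leaf in np.unique(leaves):
            mask = leaves == leaf
            labels = np.unique(y[mask])
            if labels.size == 2 and mask.sum() >= 4:
                model = LogisticRegression(max_iter=500)
                model.fit(X[mask], y[mask])
                self.leaf_models_[int(leaf)] = model
            else:
                counts = [(y[mask] == c).sum() for c in self.classes_]
                self.leaf_models_[int(leaf)] = self.classes_[int(np.argmax(counts))]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        leaves = self.tree_.apply(X)
        out = np.empty(len(X), dtype=self.classes_.dtype)
        for leaf in np.unique(leaves):
            mask = leaves == leaf
            model = self.leaf_models_.get(int(leaf))
            if isinstance(model, LogisticRegression):
                out[mask] = model.predict(X[mask])
            else:
                out[mask] = model
        return out


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = "random_forest"
    seed: int = 0
    hyperparameters: tuple = ()  # (key, value) pairs

    def __post_init__(self):
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}; "
                             f"choose from {CLASSIFIER_FAMILIES}")


def make_classifier(spec: ClassifierSpec):
    params = dict(spec.hyperparameters)
    if spec.family == "c45_tree":
        return DecisionTreeClassifier(criterion="entropy",
                                      random_state=spec.seed, **params)
    if spec.family == "rep_tree":
        params.setdefault("min_samples_leaf", 2)
        params.setdefault("ccp_alpha", 1e-3)
        return DecisionTreeClassifier(criterion="entropy",
                                      random_state=spec.seed, **params)
    if spec.family == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, **params)
    return LogisticLeafTree(random_state=spec.seed, **params)


def resolve_classifier_family(name: str) -> str:
    family = CLASSIFIER_ALIASES.get(name, name)
    if family not in CLASSIFIER_FAMILIES:
        raise ValueError(f"unknown classifier {name!r}")
    return family


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    tp = int(np.sum((y_true == REAL_LABEL) & (y_pred == REAL_LABEL)))
    fp = int(np.sum((y_true == FAKE_LABEL) & (y_pred == REAL_LABEL)))
    fn = int(np.sum((y_true == REAL_LABEL) & (y_pred == FAKE_LABEL)))
    tn = int(np.sum((y_true == FAKE_LABEL) & (y_pred == FAKE_LABEL)))
    return ConfusionMatrix(tp, fp, fn, tn)


def train_and_evaluate(data: LabeledFeatureSet, spec: ClassifierSpec,
                       protocol: str = "cv10") -> ConfusionMatrix:
    """Evaluate one classifier on one labelled feature set.

    ``cv10`` (default): seeded stratified 10-fold cross-validation, pooling
    the out-of-fold predictions into a single confusion matrix.  ``holdout``:
    a stratified 70/30 split evaluated once.
    """
    X, y = data.X, data.y
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present for training")
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("feature matrix and labels are inconsistent")

    if protocol == "cv10":
        n_splits = min(10, int(min(np.bincount(y.astype(int))[classes.astype(int)])))
        if n_splits < 2:
            raise ValueError("too few per-class instances for cross-validation")
        folds = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                random_state=spec.seed)
        y_pred = np.empty_like(y)
        for train_idx, test_idx in folds.split(X, y):
            model = make_classifier(spec)
            model.fit(X[train_idx], y[train_idx])
            y_pred[test_idx] = model.predict(X[test_idx])
        return _confusion(y, y_pred)
    if protocol == "holdout":
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=0.3, stratify=y, random_state=spec.seed)
        model = make_classifier(spec)
        model.fit(X_tr, y_tr)
        return _confusion(y_te, model.predict(X_te))
    raise ValueError(f"unknown protocol {protocol!r}")
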