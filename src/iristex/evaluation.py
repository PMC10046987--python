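"""22 shallow-classifier presets and stratified cross-validated evaluation.

The registry mirrors the preset families common in point-and-click ML
environments: 3 decision trees, 2 naive Bayes variants, 6 SVMs (linear,
quadratic, cubic, and fine/medium/coarse Gaussian kernels), 6 kNN variants,
and 5 small neural networks.  Evaluation is stratified 5-fold
cross-validation; scale-sensitive families (SVM, kNN, NN) are z-scored
inside each training fold.  Reported metrics are the fold means of
accuracy, sensitivity, specificity, precision, F1, the geometric mean of
sensitivity and specificity, and ROC AUC from continuous scores, with the
diseased class (label 1) as positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import StratificationError, UndefinedAUCError

__all__ = [
    "ClassifierConfig",
    "ConfusionMatrix",
    "MetricsReport",
    "classifier_registry",
    "build_estimator",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "stratified_kfold_eval",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1", "gmean", "auc")


@dataclass(frozen=True)
class ClassifierConfig:
    family: str
    preset_name: str
    hyperparameters: dict = field(default_factory=dict)
    standardize_inputs: bool = False


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with the diseased class (1) as positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Fold-averaged metric suite plus the per-fold breakdown."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    gmean: float
    auc: float
    per_fold: tuple
    n_folds: int

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density class likelihoods.

    Each feature's class-conditional density is a kernel density estimate
    with Silverman's bandwidth (floored to avoid degenerate spikes on
    near-constant features); features are treated as independent, and
    prediction maximizes log prior + summed log densities.
    """

    def __init__(self, bandwidth_floor: float = 1e-3):
        self.bandwidth_floor = bandwidth_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.X_by_class_ = []
        self.bw_by_class_ = []
        self.log_priors_ = []
        for c in self.classes_:
            Xc = X[y == c]
            m = len(Xc)
            sd = Xc.std(axis=0, ddof=1) if m > 1 else np.zeros(X.shape[1])
            bw = 1.06 * sd * m ** (-1 / 5)
            scale = np.where(sd > 0, sd, 1.0)
            bw = np.maximum(bw, self.bandwidth_floor * scale)
            bw = np.maximum(bw, self.bandwidth_floor)
            self.X_by_class_.append(Xc)
            self.bw_by_class_.append(bw)
            self.log_priors_.append(np.log(m / len(X)))
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=np.float64)
        out = np.empty((len(X), len(self.classes_)))
        for ci, (Xc, bw, lp) in enumerate(
            zip(self.X_by_class_, self.bw_by_class_, self.log_priors_)
        ):
            # log mean_k N(x | x_k, bw) per feature, summed over features
            z = (X[:, None, :] - Xc[None, :, :]) / bw[None, None, :]
            log_k = -0.5 * z**2 - np.log(bw[None, None, :] * np.sqrt(2 * np.pi))
            with np.errstate(divide="ignore"):
                feat = np.logaddexp.reduce(log_k, axis=1) - np.log(len(Xc))
            out[:, ci] = lp + feat.sum(axis=1)
        return out

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def classifier_registry() -> list[ClassifierConfig]:
    """The 22 presets across 5 families, with documented hyperparameters."""
    configs: list[ClassifierConfig] = []
    for name, splits in (("Fine Tree", 100), ("Medium Tree", 20), ("Coarse Tree", 4)):
        configs.append(
            ClassifierConfig("decision_tree", name, {"max_splits": splits}, False)
        )
    configs.append(ClassifierConfig("naive_bayes", "Gaussian Naive Bayes", {}, False))
    configs.append(ClassifierConfig("naive_bayes", "Kernel Naive Bayes", {}, False))
    configs.append(ClassifierConfig("svm", "Linear SVM", {"kernel": "linear"}, True))
    configs.append(ClassifierConfig("svm", "Quadratic SVM", {"kernel": "poly", "degree": 2}, True))
    configs.append(ClassifierConfig("svm", "Cubic SVM", {"kernel": "poly", "degree": 3}, True))
    # Gaussian kernel scale s relative to sqrt(P) features: K = exp(-||x-y||^2 / s^2)
    for name, factor in (
        ("Fine Gaussian SVM", 0.25),
        ("Medium Gaussian SVM", 1.0),
        ("Coarse Gaussian SVM", 4.0),
    ):
        configs.append(
            ClassifierConfig("svm", name, {"kernel": "rbf", "scale_factor": factor}, True)
        )
    for name, hp in (
        ("Fine KNN", {"n_neighbors": 1}),
        ("Medium KNN", {"n_neighbors": 10}),
        ("Coarse KNN", {"n_neighbors": 100}),
        ("Cosine KNN", {"n_neighbors": 10, "metric": "cosine"}),
        ("Cubic KNN", {"n_neighbors": 10, "metric": "minkowski", "p": 3}),
        ("Weighted KNN", {"n_neighbors": 10, "weights": "distance"}),
    ):
        configs.append(ClassifierConfig("knn", name, hp, True))
    for name, layers in (
        ("Narrow Neural Network", (10,)),
        ("Medium Neural Network", (25,)),
        ("Wide Neural Network", (100,)),
        ("Bilayered Neural Network", (10, 10)),
        ("Trilayered Neural Network", (10, 10, 10)),
    ):
        configs.append(
            ClassifierConfig("neural_network", name, {"hidden_layer_sizes": layers}, True)
        )
    assert len(configs) == 22
    return configs


def build_estimator(
    config: ClassifierConfig, n_features: int, n_train: int, seed: int = 0
):
    """Instantiate the sklearn estimator behind a preset.

    Gaussian-SVM kernel scales depend on the feature count; kNN neighbor
    counts are clamped to the training-set size.
    """
    hp = dict(config.hyperparameters)
    if config.family == "decision_tree":
        est = DecisionTreeClassifier(
            max_leaf_nodes=hp["max_splits"] + 1, random_state=seed
        )
    elif config.family == "naive_bayes":
        est = KernelNaiveBayes() if "Kernel" in config.preset_name else GaussianNB()
    elif config.family == "svm":
        if hp.get("kernel") == "rbf":
            scale = hp["scale_factor"] * np.sqrt(n_features)
            est = SVC(kernel="rbf", gamma=1.0 / scale**2, C=1.0, random_state=seed)
        elif hp.get("kernel") == "poly":
            est = SVC(
                kernel="poly", degree=hp["degree"], gamma=1.0, coef0=1.0, C=1.0,
                random_state=seed,
            )
        else:
            est = SVC(kernel="linear", C=1.0, random_state=seed)
    elif config.family == "knn":
        hp["n_neighbors"] = min(hp["n_neighbors"], n_train)
        est = KNeighborsClassifier(**hp)
    elif config.family == "neural_network":
        est = MLPClassifier(
            hidden_layer_sizes=hp["hidden_layer_sizes"],
            activation="relu",
            solver="lbfgs",
            max_iter=1000,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown family {config.family!r}")
    if config.standardize_inputs:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Binary confusion counts; rows of the conceptual matrix are actuals."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def metrics_from_confusion(cm: ConfusionMatrix) -> dict:
    """Accuracy, sensitivity, specificity, precision, F1 and Gmean.

    Any 0/0 ratio is reported as 0 and listed under ``degenerate``.
    """
    if cm.total <= 0:
        raise ValueError("empty confusion matrix")
    degenerate = []
    sns, d = _safe_div(cm.tp, cm.tp + cm.fn)
    if d:
        degenerate.append("sensitivity")
    spc, d = _safe_div(cm.tn, cm.fp + cm.tn)
    if d:
        degenerate.append("specificity")
    prc, d = _safe_div(cm.tp, cm.tp + cm.fp)
    if d:
        degenerate.append("precision")
    acc = (cm.tp + cm.tn) / cm.total
    f1, d = _safe_div(2 * prc * sns, prc + sns)
    if d:
        degenerate.append("f1")
    gm = float(np.sqrt(sns * spc))
    return {
        "accuracy": acc,
        "sensitivity": sns,
        "specificity": spc,
        "precision": prc,
        "f1": f1,
        "gmean": gm,
        "degenerate": degenerate,
    }


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve (trapezoidal; ties count one half)."""
    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        raise UndefinedAUCError("AUC needs both classes present")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=np.float64)))


def _scores(est, X) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=np.float64)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=np.float64)


def stratified_kfold_eval(
    X, y, config: ClassifierConfig, n_folds: int = 5, seed: int = 0
) -> MetricsReport:
    """Stratified k-fold evaluation of one preset; deterministic given seed."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise StratificationError(
            f"each class needs >= {n_folds} samples for {n_folds}-fold CV, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train, test in skf.split(X, y):
            est = build_estimator(config, X.shape[1], len(train), seed=seed)
            est.fit(X[train], y[train])
            pred = est.predict(X[test])
            fold = metrics_from_confusion(confusion(y[test], pred))
            fold.pop("degenerate")
            fold["auc"] = roc_auc(y[test], _scores(est, X[test]))
            per_fold.append(fold)
    means = {m: float(np.mean([f[m] for f in per_fold])) for m in METRIC_NAMES}
    return MetricsReport(per_fold=tuple(per_fold), n_folds=n_folds, **means)
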