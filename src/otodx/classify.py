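"""Classifier training and macro-averaged evaluation.

Three classical multi-class models are supported — a one-vs-all SVM (RBF
kernel by default), k-nearest neighbors, and a decision tree — evaluated
with the standard 4-class confusion matrix decomposition.  Metrics are
macro-averaged: each class i contributes its one-vs-rest binary TP/TN/FP/FN
counts, and accuracy, sensitivity (recall), specificity and positive
predictive value are averaged over classes with equal weight.  ROC/AUC for
the multi-class problem is obtained by flattening the one-hot label
indicator matrix and the per-class score matrix into a single binary
problem and sweeping thresholds.

The experimental protocol is a stratified 80/20 split of the dataset into
training and validation sets, repeated with fresh seeds (100 repetitions in
the reference protocol), reporting per-repetition metrics and their
means/standard deviations.  An optional fixed held-out test set is scored
by every repetition's model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class DatasetSplit:
    train_indices: np.ndarray
    validation_indices: np.ndarray
    fractions: tuple[float, float]
    seed: int
    stratified: bool


def stratified_split(
    labels,
    fractions: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
    stratified: bool = True,
) -> DatasetSplit:
    """Seeded train/validation partition preserving per-class proportions.

    Per-class training counts use largest-remainder rounding of
    ``fractions[0] * n_class`` so a balanced 4x180 dataset splits exactly
    into 576 training and 144 validation samples (144/36 per class).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise EvaluationError("fractions must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = labels.size

    if not stratified:
        perm = rng.permutation(n)
        n_train = int(round(fractions[0] * n))
        return DatasetSplit(np.sort(perm[:n_train]), np.sort(perm[n_train:]), tuple(fractions), seed, False)

    classes = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    per_class = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in per_class.items():
        if idx.size < 2 and 0 < fractions[0] < 1:
            raise EvaluationError(f"class {c!r} has fewer than 2 members")
    # largest-remainder apportionment of training counts
    quotas = {c: fractions[0] * idx.size for c, idx in per_class.items()}
    n_train_target = int(round(fractions[0] * n))
    base = {c: int(np.floor(q)) for c, q in quotas.items()}
    remainder_order = sorted(classes, key=lambda c: (-(quotas[c] - base[c]), classes.index(c)))
    short = n_train_target - sum(base.values())
    for c in remainder_order[:short]:
        base[c] += 1

    train, val = [], []
    for c in classes:
        idx = per_class[c].copy()
        rng.shuffle(idx)
        train.append(idx[: base[c]])
        val.append(idx[base[c] :])
    return DatasetSplit(
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        tuple(fractions),
        seed,
        True,
    )


@dataclass(frozen=True)
class ModelSpec:
    kind: str  # svm | knn | tree
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "knn", "tree"):
            raise EvaluationError(f"unknown model kind {self.kind!r}")


@dataclass
class TrainedModel:
    """Fitted classifier with aligned per-class decision scores."""

    estimator: object
    classes_: np.ndarray
    kind: str

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n, c) per-class decision scores in ``classes_`` column order.

        SVM: one-vs-all decision values; k-NN and tree: class probabilities.
        Either is monotone in class support, so columns are comparable for
        the flattened ROC construction.
        """
        X = np.asarray(X, dtype=float)
        if self.kind == "svm":
            return self.estimator.decision_function(X)
        return self.estimator.predict_proba(X)


def train_model(features: np.ndarray, labels, spec: ModelSpec) -> TrainedModel:
    """Fit the classifier named by ``spec`` on a feature matrix."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise EvaluationError("features must be (n, d) with one label per row")
    if not np.isfinite(X).all():
        raise EvaluationError("features contain non-finite entries")
    if np.unique(y).size < 2:
        raise EvaluationError("training set contains a single class")

    hp = dict(spec.hyperparameters)
    if spec.kind == "svm":
        est = OneVsRestClassifier(
            SVC(kernel=hp.pop("kernel", "rbf"), C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "scale"), **hp)
        )
    elif spec.kind == "knn":
        est = KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), metric=hp.pop("metric", "euclidean"), **hp)
    else:
        est = DecisionTreeClassifier(
            criterion=hp.pop("criterion", "gini"),
            max_depth=hp.pop("max_depth", None),
            random_state=spec.seed,
            **hp,
        )
    est.fit(X, y)
    return TrainedModel(estimator=est, classes_=np.asarray(est.classes_), kind=spec.kind)


@dataclass
class ConfusionMatrix:
    """c x c counts; rows are actual classes, columns predicted classes."""

    counts: np.ndarray
    class_order: list

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def per_class_binary(self) -> dict:
        """One-vs-rest (TP, TN, FP, FN) per class."""
        out = {}
        n = self.n
        for i, cls in enumerate(self.class_order):
            tp = int(self.counts[i, i])
            fn = int(self.counts[i].sum()) - tp
            fp = int(self.counts[:, i].sum()) - tp
            out[cls] = (tp, n - tp - fn - fp, fp, fn)
        return out


def confusion_matrix(actual, predicted, class_order) -> ConfusionMatrix:
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.size != predicted.size:
        raise EvaluationError("actual and predicted must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    if actual.size == 0:
        warnings.warn("empty label vectors: returning an all-zero confusion matrix")
        return ConfusionMatrix(counts=counts, class_order=list(class_order))
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise EvaluationError(f"label {a!r}/{p!r} not in class order {class_order}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=list(class_order))


@dataclass
class MacroMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    n_classes: int
    auc: float | None = None
    degenerate_classes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def macro_metrics(cm: ConfusionMatrix) -> MacroMetrics:
    """Macro-averaged accuracy, sensitivity, specificity and PPV.

    Each class contributes its one-vs-rest binary metrics and the average is
    taken with equal class weight:

        accuracy    = mean_i (TP_i + TN_i) / n
        sensitivity = mean_i TP_i / (TP_i + FN_i)
        specificity = mean_i TN_i / (TN_i + FP_i)
        ppv         = mean_i TP_i / (TP_i + FP_i)

    A class with a zero denominator contributes 0 to that average and is
    listed in ``degenerate_classes``.
    """
    if cm.n == 0:
        raise EvaluationError("empty confusion matrix")
    acc, sens, spec, ppv = [], [], [], []
    degenerate = []
    for cls, (tp, tn, fp, fn) in cm.per_class_binary().items():
        acc.append((tp + tn) / cm.n)
        for bucket, num, den in ((sens, tp, tp + fn), (spec, tn, tn + fp), (ppv, tp, tp + fp)):
            if den == 0:
                bucket.append(0.0)
                if cls not in degenerate:
                    degenerate.append(cls)
            else:
                bucket.append(num / den)
    c = len(cm.class_order)
    return MacroMetrics(
        accuracy=float(np.mean(acc)),
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(spec)),
        ppv=float(np.mean(ppv)),
        n_classes=c,
        degenerate_classes=degenerate,
    )


def labels_to_indicator(labels, class_order) -> np.ndarray:
    """One-hot (n, c) label indicator matrix in ``class_order`` column order."""
    labels = np.asarray(labels)
    out = np.zeros((labels.size, len(class_order)), dtype=int)
    for j, cls in enumerate(class_order):
        out[labels == cls, j] = 1
    return out


def macro_roc(indicator: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC over the flattened label-indicator matrix.

    Every (sample, class) element of the one-hot indicator matrix is treated
    as one binary ground truth with the matching score; thresholds sweep the
    unique scores and the AUC is the trapezoidal area.  Returns
    ``(fpr, tpr, auc)``.
    """
    indicator = np.asarray(indicator)
    scores = np.asarray(scores, dtype=float)
    if indicator.shape != scores.shape:
        raise EvaluationError("indicator and score matrices must share a shape")
    if not np.all((indicator == 0) | (indicator == 1)) or not np.all(indicator.sum(axis=1) == 1):
        raise EvaluationError("indicator rows must be one-hot")

    y = indicator.ravel().astype(bool)
    s = scores.ravel()
    if np.ptp(s) == 0:
        warnings.warn("constant scores: degenerate ROC (diagonal)")
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    # cut after the last element of each distinct-score run
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    pos, neg = tps[-1], fps[-1]
    if pos == 0 or neg == 0:
        raise EvaluationError("flattened problem needs both positive and negative elements")
    tpr = np.r_[0.0, tps / pos]
    fpr = np.r_[0.0, fps / neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class RepeatedEvaluation:
    per_rep: list[MacroMetrics]
    mean: dict
    std: dict
    test_per_rep: list[MacroMetrics] | None = None
    test_mean: dict | None = None
    test_vote: MacroMetrics | None = None


def _summarize(metrics: list[MacroMetrics]) -> tuple[dict, dict]:
    keys = metrics[0].as_dict().keys()
    table = {k: np.array([m.as_dict()[k] for m in metrics]) for k in keys}
    return ({k: float(v.mean()) for k, v in table.items()}, {k: float(v.std(ddof=0)) for k, v in table.items()})


def evaluate_model(model: TrainedModel, X: np.ndarray, y, class_order) -> MacroMetrics:
    """Confusion-matrix metrics plus flattened-indicator AUC for one model."""
    predicted = model.predict(X)
    cm = confusion_matrix(y, predicted, class_order)
    metrics = macro_metrics(cm)
    cols = [list(model.classes_).index(c) for c in class_order]
    _, _, auc = macro_roc(labels_to_indicator(y, class_order), model.score_matrix(X)[:, cols])
    metrics.auc = auc
    return metrics


def repeated_evaluation(
    features: np.ndarray,
    labels,
    spec: ModelSpec,
    n_reps: int = 100,
    seed: int = 0,
    fractions: tuple[float, float] = (0.8, 0.2),
    test_features: np.ndarray | None = None,
    test_labels=None,
    class_order=None,
) -> RepeatedEvaluation:
    """Repeated stratified-split training and validation.

    Repetition r splits with seed ``seed + r``, trains a fresh model and
    scores the validation fold.  When a fixed held-out test set is given,
    every repetition's model scores it too; the summary reports both the
    per-repetition average and a majority-vote aggregation over the
    repetitions' test predictions.
    """
    if n_reps < 1:
        raise EvaluationError("n_reps must be >= 1")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if class_order is None:
        class_order = sorted(np.unique(y).tolist())

    per_rep, test_per_rep = [], []
    vote_counts = None
    for r in range(n_reps):
        split = stratified_split(y, fractions=fractions, seed=seed + r)
        model = train_model(X[split.train_indices], y[split.train_indices], ModelSpec(spec.kind, spec.hyperparameters, seed=seed + r))
        per_rep.append(evaluate_model(model, X[split.validation_indices], y[split.validation_indices], class_order))
        if test_features is not None:
            test_per_rep.append(evaluate_model(model, test_features, np.asarray(test_labels), class_order))
            pred = model.predict(test_features)
            if vote_counts is None:
                vote_counts = np.zeros((len(pred), len(class_order)), dtype=int)
            for j, cls in enumerate(class_order):
                vote_counts[:, j] += pred == cls

    mean, std = _summarize(per_rep)
    result = RepeatedEvaluation(per_rep=per_rep, mean=mean, std=std)
    if test_features is not None:
        result.test_per_rep = test_per_rep
        result.test_mean, _ = _summarize(test_per_rep)
        voted = np.asarray(class_order)[np.argmax(vote_counts, axis=1)]
        result.test_vote = macro_metrics(confusion_matrix(np.asarray(test_labels), voted, class_order))
    return result
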