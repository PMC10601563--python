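"""Tree-ensemble classification of degenerative / traumatic / control knees.

Random forest (100 trees, entropy splits, max depth 10, minimum node size
1) and gradient boosting (100 trees, max depth 4, learning rate 0.1) are
evaluated with stratified 10-fold cross-validation: the out-of-fold
predictions are pooled into a single confusion structure from which
accuracy and per-class precision, recall and F1 are reported as
percentages:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = TP / (TP + (FP + FN) / 2)

Feature importance is permutation importance on the out-of-fold data
(accuracy drop when one feature is shuffled), averaged over folds and
repeats and normalised so the per-feature shares sum to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import FeatureSchema, build_default_schema

IMPORTANCE_GROUPS = ("2D", "3D", "MRI", "CT", "Bone", "Cartilage")


@dataclass
class ModelSpec:
    """Hyperparameters of one tree-ensemble model."""

    algorithm: str = "RF"  # 'RF' or 'GB'
    n_trees: int = 100
    rf_max_depth: int = 10
    rf_min_node_size: int = 1
    gb_max_depth: int = 4
    gb_learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("number of trees must be >= 1")
        if self.gb_learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.algorithm not in ("RF", "GB"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected 'RF' or 'GB'")

    def build(self):
        if self.algorithm == "RF":
            return RandomForestClassifier(
                n_estimators=self.n_trees,
                criterion="entropy",
                max_depth=self.rf_max_depth,
                min_samples_leaf=self.rf_min_node_size,
                random_state=self.seed,
            )
        return GradientBoostingClassifier(
            n_estimators=self.n_trees,
            max_depth=self.gb_max_depth,
            learning_rate=self.gb_learning_rate,
            random_state=self.seed,
        )


@dataclass
class ConfusionCounts:
    """Pooled multi-class confusion matrix with one-vs-rest views."""

    classes: list[str]
    matrix: np.ndarray  # rows = true class, columns = predicted class

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def one_vs_rest(self, cls: str) -> dict[str, int]:
        i = self.classes.index(cls)
        tp = int(self.matrix[i, i])
        fp = int(self.matrix[:, i].sum() - tp)
        fn = int(self.matrix[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}

    def add(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.classes != other.classes:
            raise ValueError("confusion matrices have different class sets")
        return ConfusionCounts(self.classes, self.matrix + other.matrix)


@dataclass
class MetricSet:
    """Accuracy and per-class precision/recall/F1, all in percent."""

    accuracy: float
    per_class: dict[str, dict[str, float]]  # class -> {precision, recall, f1}


@dataclass
class ImportanceReport:
    """Per-feature and per-group permutation-importance shares (percent)."""

    per_feature: dict[str, float]
    per_group: dict[str, float] = field(default_factory=dict)

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.per_feature.items(), key=lambda kv: -kv[1])


def _check_folds(y: np.ndarray, folds) -> None:
    classes = np.unique(y)
    for i, (train_idx, _) in enumerate(folds):
        present = np.unique(y[train_idx])
        if len(present) < len(classes):
            missing = sorted(set(classes) - set(present))
            raise ValueError(
                f"class(es) {missing} absent from training fold {i}; "
                "use stratified folds or more data per class"
            )


def crossval_classify(
    X: np.ndarray, y: np.ndarray, spec: ModelSpec | None = None, k: int = 10
) -> tuple[ConfusionCounts, MetricSet, np.ndarray]:
    """Stratified k-fold cross-validation with pooled out-of-fold predictions.

    Returns the pooled confusion counts, the metric set and the fold
    assignment of every subject. Deterministic under a fixed spec seed.
    """
    spec = spec or ModelSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if k > len(y):
        raise ValueError(f"cannot run {k}-fold CV with only {len(y)} subjects")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(X, y))
    _check_folds(y, folds)
    fold_of = np.empty(len(y), dtype=int)
    matrix = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        fold_of[test_idx] = fold_id
        model = spec.build()
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        for truth, guess in zip(y[test_idx], pred):
            matrix[index[truth], index[guess]] += 1
    counts = ConfusionCounts(classes, matrix)
    return counts, classification_metrics(counts), fold_of


def classification_metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy and one-vs-rest precision/recall/F1 in percent.

    A zero denominator (e.g. a class never predicted) reports the metric
    as 0 with a warning.
    """
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * np.trace(counts.matrix) / counts.total
    per_class: dict[str, dict[str, float]] = {}
    for cls in counts.classes:
        c = counts.one_vs_rest(cls)
        tp, fp, fn = c["TP"], c["FP"], c["FN"]
        if tp + fp == 0:
            warnings.warn(f"precision undefined for class {cls!r}; reporting 0")
            precision = 0.0
        else:
            precision = 100.0 * tp / (tp + fp)
        if tp + fn == 0:
            warnings.warn(f"recall undefined for class {cls!r}; reporting 0")
            recall = 0.0
        else:
            recall = 100.0 * tp / (tp + fn)
        if tp + (fp + fn) / 2 == 0:
            f1 = 0.0
        else:
            f1 = 100.0 * tp / (tp + (fp + fn) / 2.0)
        per_class[cls] = {"precision": precision, "recall": recall, "f1": f1}
    return MetricSet(accuracy=float(accuracy), per_class=per_class)


def feature_importance(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec | None = None,
    feature_names: list[str] | None = None,
    schema: FeatureSchema | None = None,
    k: int = 10,
    n_repeats: int = 3,
) -> ImportanceReport:
    """Out-of-fold permutation importance, normalised to a 100% budget.

    For every fold the model is fitted on the training part; each feature
    of the held-out part is then shuffled ``n_repeats`` times and the mean
    accuracy drop recorded. Drops are summed over folds, clipped at zero
    (a constant or useless feature gets importance 0) and scaled so the
    per-feature shares total 100. When the feature names match a schema,
    per-group shares (2D/3D/MRI/CT/Bone/Cartilage) are the exact sums of
    their members.
    """
    spec = spec or ModelSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = X.shape[1]
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_features)]
    if len(feature_names) != n_features:
        raise ValueError("feature_names length mismatch")
    rng = np.random.default_rng(spec.seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(X, y))
    _check_folds(y, folds)
    drops = np.zeros(n_features)
    for train_idx, test_idx in folds:
        model = spec.build()
        model.fit(X[train_idx], y[train_idx])
        X_test, y_test = X[test_idx], y[test_idx]
        baseline = (model.predict(X_test) == y_test).mean()
        for j in range(n_features):
            drop = 0.0
            for _ in range(n_repeats):
                shuffled = X_test.copy()
                shuffled[:, j] = rng.permutation(shuffled[:, j])
                drop += baseline - (model.predict(shuffled) == y_test).mean()
            drops[j] += drop / n_repeats
    drops = np.clip(drops, 0.0, None)
    total = drops.sum()
    if total > 0:
        shares = 100.0 * drops / total
    else:  # nothing informative: uniform shares keep the 100% budget
        shares = np.full(n_features, 100.0 / n_features)
    per_feature = dict(zip(feature_names, shares.tolist()))
    per_group: dict[str, float] = {}
    schema = schema or _maybe_default_schema(feature_names)
    if schema is not None:
        for group in IMPORTANCE_GROUPS:
            members = [n for n in schema.subset_names(group) if n in per_feature]
            per_group[group] = float(sum(per_feature[n] for n in members))
    return ImportanceReport(per_feature=per_feature, per_group=per_group)


def _maybe_default_schema(feature_names: list[str]) -> FeatureSchema | None:
    schema = build_default_schema()
    return schema if set(feature_names) == set(schema.names) else None
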