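"""Cross-validated classification of full six-curve profiles.

Four learners are benchmarked on the concatenated six-curve feature vector
(F330, F350, F350/F330 and their derivatives, subsampled along temperature):
logistic regression, a linear polynomial-kernel SVM, a 500-tree random
forest, and AdaBoost with 100 rounds over depth-3 trees.  Evaluation is
stratified 5-fold cross-validation with leakage-safe per-fold z-scoring;
accuracy is summarised as the mean of fold accuracies with a
normal-approximation 95% half-width, and confusion counts are pooled over
out-of-fold predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import InvalidInputError, StratificationError
from .io import DEFAULT_GRID, NanoDSFRun, TemperatureGrid, six_curves

__all__ = [
    "ClassifierConfig",
    "AlgorithmResult",
    "EvaluationReport",
    "ConfusionRates",
    "default_configs",
    "make_estimator",
    "assemble_features",
    "run_cv",
    "confusion_rates",
]

_CURVE_ORDER = ("f330", "f350", "ratio", "d_f330", "d_f350", "d_ratio")
_LABEL_CODES = {"CONTROL": 0, "POAG": 1}


@dataclass(frozen=True)
class ClassifierConfig:
    """One learner with its fixed hyperparameters.

    Defaults follow the benchmarked settings: LR max_iter 1000; SVM with
    polynomial kernel, degree 1, C = 1, gamma "auto"; RF with 500 trees;
    AdaBoost with 100 rounds over depth-3 decision trees.
    """

    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ("LR", "SVM", "RF", "ADABOOST"):
            raise InvalidInputError(f"unknown algorithm {self.algorithm!r}")


def default_configs() -> tuple[ClassifierConfig, ...]:
    return (
        ClassifierConfig("LR", {"max_iter": 1000}),
        ClassifierConfig("SVM", {"kernel": "poly", "degree": 1, "C": 1.0, "gamma": "auto"}),
        ClassifierConfig("RF", {"n_estimators": 500}),
        ClassifierConfig("ADABOOST", {"n_estimators": 100, "max_depth": 3}),
    )


def make_estimator(config: ClassifierConfig, seed: int | None = None):
    hp = dict(config.hyperparameters)
    if config.algorithm == "LR":
        return LogisticRegression(max_iter=int(hp.get("max_iter", 1000)))
    if config.algorithm == "SVM":
        return SVC(
            kernel=str(hp.get("kernel", "poly")),
            degree=int(hp.get("degree", 1)),
            C=float(hp.get("C", 1.0)),
            gamma=hp.get("gamma", "auto"),
        )
    if config.algorithm == "RF":
        return RandomForestClassifier(n_estimators=int(hp.get("n_estimators", 500)), random_state=seed)
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=int(hp.get("max_depth", 3))),
        n_estimators=int(hp.get("n_estimators", 100)),
        random_state=seed,
    )


@dataclass(frozen=True)
class AlgorithmResult:
    fold_accuracies: tuple[float, ...]
    mean_accuracy_pct: float
    ci_halfwidth_pct: float
    confusion: Mapping[str, int]  # pooled out-of-fold TP/FP/TN/FN

    def as_dict(self) -> dict:
        return {
            "fold_accuracies": list(self.fold_accuracies),
            "mean_accuracy_pct": self.mean_accuracy_pct,
            "ci_halfwidth_pct": self.ci_halfwidth_pct,
            "confusion": dict(self.confusion),
        }


@dataclass(frozen=True)
class EvaluationReport:
    """Per-algorithm CV accuracies and pooled confusion, plus audit fields."""

    results: Mapping[str, AlgorithmResult]
    seed: int | None
    n_samples: int
    n_per_class: Mapping[int, int]
    n_folds: int
    feature_description: str

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "n_samples": self.n_samples,
            "n_per_class": {str(k): int(v) for k, v in self.n_per_class.items()},
            "n_folds": self.n_folds,
            "feature_description": self.feature_description,
            "results": {alg: res.as_dict() for alg, res in self.results.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _encode_labels(runs: Sequence[NanoDSFRun]) -> np.ndarray | None:
    if any(r.label is None for r in runs):
        return None
    out = []
    for r in runs:
        if r.label in _LABEL_CODES:
            out.append(_LABEL_CODES[r.label])
        else:
            raise InvalidInputError(f"run {r.sample_id!r}: unknown class label {r.label!r}")
    return np.asarray(out)


def assemble_features(
    runs: Sequence[NanoDSFRun],
    grid_step: float = 0.5,
    base_grid: TemperatureGrid = DEFAULT_GRID,
    smoothing_window_c: float = 5.0,
    polyorder: int = 3,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Build the full-curve feature matrix.

    Each run is resampled and turned into six curves on ``base_grid`` (0.1
    degC by default), then each curve is subsampled every ``grid_step`` degC
    and the six are concatenated in the fixed order F330, F350, ratio,
    dF330/dT, dF350/dT, d(ratio)/dT — with the default 35-95 degC range and
    0.5 degC step that is 121 points x 6 = 726 features.  Labels (CONTROL=0,
    POAG=1) are returned when every run carries one, else ``None``.
    """
    stride = grid_step / base_grid.step
    if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
        raise InvalidInputError(
            f"grid_step {grid_step} must be a positive multiple of the base grid step {base_grid.step}"
        )
    stride = int(round(stride))
    if not runs:
        raise InvalidInputError("need at least one run")
    rows = []
    for run in runs:
        curves = six_curves(run, base_grid, smoothing_window_c=smoothing_window_c, polyorder=polyorder)
        rows.append(np.concatenate([getattr(curves, name)[::stride] for name in _CURVE_ORDER]))
    return np.vstack(rows), _encode_labels(runs)


def run_cv(
    features: np.ndarray,
    labels: np.ndarray,
    configs: Sequence[ClassifierConfig] | None = None,
    seed: int = 0,
    n_folds: int = 5,
    feature_description: str = "six curves, fixed order",
) -> EvaluationReport:
    """Stratified k-fold benchmark of the configured learners.

    The fold split is shuffled once with ``seed`` and shared by all learners;
    z-scoring is fit on each training fold only (no leakage).  The CI
    half-width is 1.96 x SD(fold accuracies)/sqrt(k).  Deterministic given
    the seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise InvalidInputError("features must be (n, p) aligned with labels")
    if len(y) < 10:
        raise InvalidInputError("need >= 10 samples for 5-fold evaluation")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise InvalidInputError("labels must contain exactly 2 classes")
    if counts.min() < n_folds:
        raise StratificationError(
            f"smallest class has {counts.min()} samples; cannot stratify into {n_folds} folds"
        )
    if configs is None:
        configs = default_configs()

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    positive = classes.max()

    results: dict[str, AlgorithmResult] = {}
    for cfg in configs:
        fold_acc = []
        pooled_pred = np.empty(len(y), dtype=y.dtype)
        for train_idx, test_idx in folds:
            scaler = StandardScaler().fit(X[train_idx])
            est = make_estimator(cfg, seed=seed)
            est.fit(scaler.transform(X[train_idx]), y[train_idx])
            pred = est.predict(scaler.transform(X[test_idx]))
            pooled_pred[test_idx] = pred
            fold_acc.append(float(np.mean(pred == y[test_idx])))
        acc = np.asarray(fold_acc)
        mean_pct = float(acc.mean() * 100.0)
        sd = float(acc.std(ddof=1)) if len(acc) > 1 else 0.0
        ci_pct = float(1.96 * sd / np.sqrt(len(acc)) * 100.0)
        tp = int(np.sum((y == positive) & (pooled_pred == positive)))
        fn = int(np.sum((y == positive) & (pooled_pred != positive)))
        fp = int(np.sum((y != positive) & (pooled_pred == positive)))
        tn = int(np.sum((y != positive) & (pooled_pred != positive)))
        results[cfg.algorithm] = AlgorithmResult(
            fold_accuracies=tuple(round(a, 6) for a in fold_acc),
            mean_accuracy_pct=mean_pct,
            ci_halfwidth_pct=ci_pct,
            confusion={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        )
    return EvaluationReport(
        results=results,
        seed=seed,
        n_samples=len(y),
        n_per_class={int(c): int(n) for c, n in zip(classes, counts)},
        n_folds=n_folds,
        feature_description=feature_description,
    )


@dataclass(frozen=True)
class ConfusionRates:
    """Sensitivity and false-positive rate in percent (to 0.1); a zero
    denominator leaves the rate NaN and sets the corresponding flag."""

    sensitivity_pct: float
    false_positive_rate_pct: float
    sensitivity_undefined: bool = False
    fpr_undefined: bool = False


def confusion_rates(confusion: Mapping[str, int] | AlgorithmResult) -> ConfusionRates:
    """Sensitivity = TP/(TP+FN); FPR = FP/(FP+TN), as percentages to 0.1."""
    if isinstance(confusion, AlgorithmResult):
        confusion = confusion.confusion
    tp, fn = int(confusion["TP"]), int(confusion["FN"])
    fp, tn = int(confusion["FP"]), int(confusion["TN"])
    if min(tp, fn, fp, tn) < 0:
        raise InvalidInputError("confusion counts must be >= 0")
    sens_undef = (tp + fn) == 0
    fpr_undef = (fp + tn) == 0
    sens = float("nan") if sens_undef else round(100.0 * tp / (tp + fn), 1)
    fpr = float("nan") if fpr_undef else round(100.0 * fp / (fp + tn), 1)
    return ConfusionRates(sens, fpr, sens_undef, fpr_undef)
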