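"""Subtype classification on module activity scores.

Models are trained on a modules × samples score matrix (samples as
observations, modules as features).  Hyperparameters are tuned by repeated
stratified k-fold cross-validation maximizing subset accuracy; the winning
parameters are then refit on the full training set, and an independent
cohort scored with the same modules serves as the external test set.
Random forests are the reference family because their mean decrease in Gini
impurity ranks modules by predictive importance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import LinearSVC

from .enrichment import ScoreMatrix

logger = logging.getLogger(__name__)

FAMILIES = ("random_forest", "linear_svm", "gradient_boosting")

# model-family parameter naming -> sklearn estimator kwargs
_PARAM_MAP = {
    "random_forest": {"mtry": "max_features"},
    "linear_svm": {"C": "C"},
    "gradient_boosting": {
        "nrounds": "n_estimators",
        "max_depth": "max_depth",
        "eta": "learning_rate",
    },
}


@dataclass
class ModelSpec:
    """Model family plus its hyperparameter grid.

    ``grid`` maps family-conventional parameter names (mtry; C; nrounds,
    max_depth, eta) to candidate lists; None means the default grid for the
    feature count at hand.  ``fixed`` passes extra estimator keyword
    arguments (e.g. ``n_estimators`` for the forest size).
    """

    family: str = "random_forest"
    grid: dict[str, list] | None = None
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")
        if self.grid is not None:
            if not self.grid or any(len(v) == 0 for v in self.grid.values()):
                raise ValueError("hyperparameter grid must be nonempty")
            unknown = set(self.grid) - set(_PARAM_MAP[self.family])
            if unknown:
                raise ValueError(
                    f"parameters {sorted(unknown)} invalid for family {self.family!r}"
                )


def default_grid(family: str, n_features: int) -> dict[str, list]:
    """Small conventional grids.  For forests: mtry in {√p/2, √p, 2√p}
    (rounded, clipped to [1, p])."""
    if family == "random_forest":
        root = np.sqrt(n_features)
        cand = sorted(
            {int(min(max(round(c), 1), n_features)) for c in (root / 2, root, 2 * root)}
        )
        return {"mtry": cand}
    if family == "linear_svm":
        return {"C": [0.1, 1.0, 10.0]}
    if family == "gradient_boosting":
        return {"nrounds": [100, 200], "max_depth": [2, 3], "eta": [0.1, 0.3]}
    raise ValueError(f"unknown model family {family!r}")


def make_model(family: str, params: dict, seed: int, fixed: dict | None = None):
    """Instantiate the sklearn estimator for one grid point."""
    kwargs = {_PARAM_MAP[family][k]: v for k, v in params.items()}
    kwargs.update(fixed or {})
    if family == "random_forest":
        kwargs.setdefault("n_estimators", 500)
        return RandomForestClassifier(criterion="gini", random_state=seed, **kwargs)
    if family == "linear_svm":
        kwargs.setdefault("max_iter", 10000)
        return LinearSVC(random_state=seed, **kwargs)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **kwargs)
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class ClassificationResult:
    """Fitted model plus everything needed to audit and reuse it."""

    model: object
    family: str
    best_params: dict
    cv_subset_accuracy: float
    train_subset_accuracy: float
    cv_results: pd.DataFrame
    module_ids: list[str]
    classes: list[str]
    seed: int
    importance: pd.Series | None = None
    test_subset_accuracy: float | None = None


def subset_accuracy(predicted, truth) -> float:
    """Fraction of samples whose predicted label matches the truth exactly
    (for single-label multiclass this is plain accuracy)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predictions vs {truth.shape} truths"
        )
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(predicted == truth))


def _align_labels(scores: ScoreMatrix, labels) -> np.ndarray:
    sample_ids = scores.sample_ids
    if isinstance(labels, pd.Series):
        missing = [s for s in sample_ids if s not in labels.index]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        return labels.reindex(sample_ids).to_numpy()
    labels = np.asarray(labels)
    if len(labels) != len(sample_ids):
        raise ValueError("label vector length does not match sample count")
    return labels


def cross_validate(
    scores: ScoreMatrix,
    labels,
    spec: ModelSpec | None = None,
    folds: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> ClassificationResult:
    """Tune by repeated stratified k-fold CV, then refit on all samples.

    Stratification preserves the class proportions in every fold.  For each
    grid point the mean subset accuracy over folds × repeats is computed;
    the best grid point wins, with ties broken toward the smallest parameter
    values (grid points are visited in ascending sorted order and only a
    strictly better score replaces the incumbent).  The final model is refit
    on the complete training set with the winning parameters.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    spec = spec or ModelSpec()
    y = _align_labels(scores, labels)
    X = scores.values.to_numpy(dtype=float).T

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than folds={folds}; "
            "reduce the number of folds"
        )

    grid = spec.grid or default_grid(spec.family, X.shape[1])
    names = sorted(grid)
    points = [
        dict(zip(names, combo))
        for combo in itertools.product(*(sorted(grid[n]) for n in names))
    ]

    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    splits = list(splitter.split(X, y))

    best_params, best_acc = None, -np.inf
    rows = []
    for params in points:
        accs = []
        for train_idx, test_idx in splits:
            model = make_model(spec.family, params, seed, spec.fixed)
            model.fit(X[train_idx], y[train_idx])
            accs.append(subset_accuracy(model.predict(X[test_idx]), y[test_idx]))
        mean_acc = float(np.mean(accs))
        rows.append({**params, "cv_subset_accuracy": mean_acc})
        if mean_acc > best_acc:  # strict: earlier (smaller) grid points win ties
            best_acc, best_params = mean_acc, params

    final = make_model(spec.family, best_params, seed, spec.fixed)
    final.fit(X, y)
    train_acc = subset_accuracy(final.predict(X), y)

    importance = None
    if spec.family == "random_forest":
        importance = pd.Series(
            final.feature_importances_, index=scores.module_ids, name="gini_importance"
        )

    logger.info(
        "cross_validate[%s]: best %s, cv=%.3f, train=%.3f",
        spec.family, best_params, best_acc, train_acc,
    )
    return ClassificationResult(
        model=final,
        family=spec.family,
        best_params=best_params,
        cv_subset_accuracy=best_acc,
        train_subset_accuracy=train_acc,
        cv_results=pd.DataFrame(rows),
        module_ids=scores.module_ids,
        classes=[str(c) for c in classes],
        seed=seed,
        importance=importance,
    )


def evaluate_external(result: ClassificationResult, scores: ScoreMatrix, labels) -> float:
    """Subset accuracy on an independent cohort; no refitting, no mutation.

    The external score matrix must contain every training module (extra
    modules are ignored with a warning); rows are reordered to the training
    feature order before prediction.
    """
    missing = [m for m in result.module_ids if m not in scores.values.index]
    if missing:
        raise ValueError(f"external scores lack training module(s): {missing}")
    extra = [m for m in scores.values.index if m not in set(result.module_ids)]
    if extra:
        logger.warning("ignoring %d module(s) absent from training", len(extra))
    aligned = ScoreMatrix(
        values=scores.values.loc[result.module_ids],
        method=scores.method,
        params=scores.params,
    )
    y = _align_labels(aligned, labels)
    X = aligned.values.to_numpy(dtype=float).T
    acc = subset_accuracy(result.model.predict(X), y)
    result.test_subset_accuracy = acc
    return acc


def gini_importance(result: ClassificationResult, top_k: int = 20) -> pd.Series:
    """Top modules by mean decrease in Gini, descending (identifier ascending
    on ties).  Only defined for random forests."""
    if result.family != "random_forest" or result.importance is None:
        raise ValueError("Gini importance is only available for random_forest models")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    imp = result.importance
    order = imp.sort_index().sort_values(ascending=False, kind="mergesort")
    return order.iloc[:top_k]


def save_model(result: ClassificationResult, path) -> None:
    """Persist a fitted result (joblib pickle; params and seed included)."""
    joblib.dump(result, path)


def load_model(path) -> ClassificationResult:
    return joblib.load(path)
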