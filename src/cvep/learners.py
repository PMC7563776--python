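"""The three base-learner contracts: GLM, GBM and DRF.

Each base learner exposes the same surface — fit on a complete design,
predict per-class probabilities in the fixed code order −2…+2 (or a single
real value in gaussian mode), and report a non-negative importance per
feature column.  Behind the contract:

* GLM — regularized multinomial logistic regression
  (scikit-learn ``LogisticRegression``); a linear consensus that favours
  features non-contradictory to the target.
* GBM — stage-wise gradient-boosted trees (LightGBM); sequential feature
  selection with an orthogonality pressure, so its importance list decays
  quickly.
* DRF — bagged randomized decision trees (scikit-learn random forest over
  random row/column samples); credits every feature consistently in line
  with the target.

Importances: mean absolute standardized coefficient across the five class
equations for GLM; split-gain totals for GBM and DRF.  All learners are
deterministic under a fixed seed (single-threaded fits).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
from lightgbm import LGBMClassifier, LGBMRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression, Ridge

from .io_model import CLASS_CODES, N_FEATURES, SCORE_IDS
from .metrics import logloss as _logloss
from .preprocess import TrainingDesign

logger = logging.getLogger("cvep")

KINDS = ("GLM", "GBM", "DRF")

#: Default hyperparameters per learner kind.  The tuned values behind the
#: original models were never published, so these are package defaults,
#: exposed in config — not claims.
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "GLM": {"regularization": 1e-4, "max_iter": 1000},
    "GBM": {
        "ntrees": 150,
        "max_depth": 6,
        "learn_rate": 0.1,
        "sample_rate": 0.8,
        "min_rows": 20,
    },
    "DRF": {
        "ntrees": 150,
        "max_depth": 20,
        "sample_rate": 0.632,
        "min_rows": 1,
        "col_sample": "sqrt",
    },
}


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Declarative description of one base learner.

    ``distribution`` is ``multinomial`` for five-class prediction and
    ``gaussian`` when the class codes are treated as real values.
    """

    kind: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    distribution: str = "multinomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.distribution not in ("multinomial", "gaussian"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    def resolved(self) -> dict[str, Any]:
        hp = dict(DEFAULT_HYPERPARAMETERS[self.kind])
        hp.update(self.hyperparameters)
        return hp

    def with_seed(self, seed: int) -> "BaseLearnerSpec":
        return replace(self, seed=seed)


@dataclass
class TrainedBaseModel:
    """A fitted base learner plus its importance vector."""

    spec: BaseLearnerSpec
    fitted_state: Any
    importance: np.ndarray
    classes: tuple[int, ...] = CLASS_CODES
    n_columns: int = N_FEATURES

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if len(self.importance) != self.n_columns:
            raise ValueError("importance must have one entry per feature column")
        if not np.isfinite(self.importance).all() or (self.importance < 0).any():
            raise ValueError("importance must be non-negative and finite")


def _build_estimator(spec: BaseLearnerSpec):
    hp = spec.resolved()
    if spec.kind == "GLM":
        if spec.distribution == "multinomial":
            return LogisticRegression(
                C=1.0 / max(hp["regularization"], 1e-12),
                max_iter=hp["max_iter"],
                solver="lbfgs",
            )
        return Ridge(alpha=hp["regularization"] * 1000.0)
    if spec.kind == "GBM":
        common = dict(
            n_estimators=hp["ntrees"],
            max_depth=hp["max_depth"],
            learning_rate=hp["learn_rate"],
            subsample=hp["sample_rate"],
            subsample_freq=1,
            min_child_samples=hp["min_rows"],
            random_state=spec.seed,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
        )
        if spec.distribution == "multinomial":
            return LGBMClassifier(objective="multiclass", **common)
        return LGBMRegressor(objective="regression", **common)
    # DRF
    common = dict(
        n_estimators=hp["ntrees"],
        max_depth=hp["max_depth"],
        min_samples_leaf=hp["min_rows"],
        max_features=hp["col_sample"],
        max_samples=hp["sample_rate"],
        bootstrap=True,
        random_state=spec.seed,
        n_jobs=1,
    )
    if spec.distribution == "multinomial":
        return RandomForestClassifier(**common)
    return RandomForestRegressor(**common)


def _glm_importance(est, X: np.ndarray) -> np.ndarray:
    coef = np.atleast_2d(est.coef_)
    stds = X.std(axis=0)
    return np.mean(np.abs(coef), axis=0) * stds


def fit_base(spec: BaseLearnerSpec, design: TrainingDesign) -> TrainedBaseModel:
    """Fit one base learner on a complete training design.

    Class balancing enters through the design's per-row weights.  In
    gaussian mode the ordinal codes are used directly as the real-valued
    target.  Deterministic under the spec's seed.
    """
    X, y, w = design.X, design.y, design.weights
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in design matrix")
    if spec.distribution == "multinomial" and len(np.unique(y)) < 2:
        raise ValueError("multinomial mode requires at least two classes")
    est = _build_estimator(spec)
    target = y.astype(float) if spec.distribution == "gaussian" else y
    est.fit(X, target, sample_weight=w)
    if spec.kind == "GLM":
        importance = _glm_importance(est, X)
    elif spec.kind == "GBM":
        importance = est.booster_.feature_importance(importance_type="gain").astype(float)
    else:
        importance = est.feature_importances_.astype(float)
    return TrainedBaseModel(
        spec=spec, fitted_state=est, importance=importance, n_columns=X.shape[1]
    )


def predict_proba(model: TrainedBaseModel, X: np.ndarray) -> np.ndarray:
    """n×5 class-probability matrix in code order −2…+2; rows sum to 1.

    Classes absent from training get probability 0.  Column count must
    match the training design.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_columns:
        raise ValueError(
            f"column mismatch: model trained on {model.n_columns} columns, got {X.shape[1]}"
        )
    if model.spec.distribution != "multinomial":
        raise ValueError("probability prediction requires multinomial mode")
    est = model.fitted_state
    with warnings.catch_warnings():
        # arrays carry no feature names; the LightGBM sklearn wrapper warns
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        raw = est.predict_proba(X)
    seen = [int(c) for c in est.classes_]
    out = np.zeros((X.shape[0], len(CLASS_CODES)))
    for j, code in enumerate(CLASS_CODES):
        if code in seen:
            out[:, j] = raw[:, seen.index(code)]
    # guard against numeric drift away from a unit row sum
    out /= out.sum(axis=1, keepdims=True)
    return out


def predict_real(model: TrainedBaseModel, X: np.ndarray, clip: bool = True) -> np.ndarray:
    """Gaussian-mode real prediction per row, clipped into [−2, 2]."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_columns:
        raise ValueError(
            f"column mismatch: model trained on {model.n_columns} columns, got {X.shape[1]}"
        )
    if model.spec.distribution != "gaussian":
        raise ValueError("real prediction requires gaussian mode")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        pred = np.asarray(model.fitted_state.predict(X), dtype=float)
    if clip:
        pred = np.clip(pred, CLASS_CODES[0], CLASS_CODES[-1])
    return pred


def real_to_class(pred: np.ndarray) -> np.ndarray:
    """Round a gaussian-mode prediction to the nearest ordinal code."""
    return np.clip(np.rint(pred), CLASS_CODES[0], CLASS_CODES[-1]).astype(int)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


def _fold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    perm = np.random.default_rng(seed).permutation(n)
    return perm % k


def expand_grid(kind: str, grid: Mapping[str, Sequence[Any]], **spec_kwargs) -> list[BaseLearnerSpec]:
    """Cartesian expansion of a hyperparameter grid into specs."""
    keys = list(grid)
    combos = itertools.product(*(grid[k] for k in keys))
    return [
        BaseLearnerSpec(kind=kind, hyperparameters=dict(zip(keys, c)), **spec_kwargs)
        for c in combos
    ]


def grid_search(
    spec_grid: Sequence[BaseLearnerSpec],
    design: TrainingDesign,
    k: int = 5,
    seed: int = 0,
) -> tuple[BaseLearnerSpec, list[dict[str, Any]]]:
    """Exhaustive grid evaluation by k-fold cross-validated mean logloss.

    Returns the argmin spec and the full score table.  Ties break toward
    smaller ``ntrees`` then smaller ``max_depth`` (tree-less specs sort
    first).  Deterministic under the seed.
    """
    if not spec_grid:
        raise ValueError("empty grid")
    if k < 2:
        raise ValueError("k must be >= 2")
    folds = _fold_assignment(design.n, k, seed)
    table: list[dict[str, Any]] = []
    for spec in spec_grid:
        losses = []
        for f in range(k):
            tr = folds != f
            te = ~tr
            sub = TrainingDesign(
                X=design.X[tr], y=design.y[tr], weights=design.weights[tr],
                imputation_state=design.imputation_state,
            )
            model = fit_base(spec.with_seed(seed), sub)
            P = predict_proba(model, design.X[te])
            losses.append(_logloss(design.y[te], P))
        table.append(
            {"spec": spec, "cv_logloss": float(np.mean(losses)), "fold_logloss": losses}
        )

    def tie_key(entry):
        hp = entry["spec"].resolved()
        return (
            round(entry["cv_logloss"], 12),
            hp.get("ntrees", 0),
            hp.get("max_depth", 0),
        )

    best = min(table, key=tie_key)
    return best["spec"], table


def importance_series(model: TrainedBaseModel) -> list[tuple[str, float]]:
    """(feature id, importance) pairs sorted descending by importance."""
    order = np.argsort(-model.importance, kind="stable")
    return [(SCORE_IDS[i], float(model.importance[i])) for i in order]
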