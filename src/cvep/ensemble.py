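"""The super-learner: k-fold out-of-fold stacking with a nonnegative meta-GLM.

Stacking protocol
-----------------
1. Rows are assigned to k folds by the "modulo" rule: a seeded permutation
   π of the row ranks, then fold(i) = π(i) mod k.  The permutation is taken
   over rows in a canonical (content-lexicographic) order, so the fold
   multisets — and every downstream number — are independent of the storage
   order of the training rows.
2. For each fold, each base learner is fit on the other k−1 folds and
   predicts the held-out fold, yielding a complete out-of-fold meta-feature
   matrix (3 learners × 5 class probabilities in categorical mode, 3 real
   predictions in continuous mode).
3. The meta-learner — a multinomial GLM constrained to nonnegative weights
   (free intercepts) — is fit on the out-of-fold meta-features, so it
   combines the base learners according to their genuinely held-out skill.
4. The base learners are refit on all rows for deployment.

Prediction streams in chunks: chunked output is bitwise identical to a
single pass.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from scipy.optimize import lsq_linear, minimize
from scipy.special import softmax

from .io_model import CLASS_CODES, ClassLabel, FeatureMatrix
from .learners import (
    BaseLearnerSpec,
    TrainedBaseModel,
    fit_base,
    predict_proba,
    predict_real,
)
from .metrics import MetricsReport, categorical_report, continuous_report
from .preprocess import (
    ImputationState,
    TrainingDesign,
    fill_mean_scores,
    impute_missing,
)

logger = logging.getLogger("cvep")

BUNDLE_VERSION = 1
_CODES = np.asarray(CLASS_CODES)


# ---------------------------------------------------------------------------
# Fold assignment
# ---------------------------------------------------------------------------


def canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices sorting rows lexicographically by content (features, label).

    Duplicate rows receive adjacent ranks in an arbitrary internal order;
    since duplicates are exchangeable, the fold multisets built on these
    ranks are invariant to the storage order of the input.
    """
    keys = [np.asarray(y)] + [X[:, j] for j in range(X.shape[1] - 1, -1, -1)]
    return np.lexsort(keys)


def modulo_folds(
    n: int, k: int, seed: int, y: np.ndarray | None = None, stratify_check: bool = True
) -> np.ndarray:
    """Fold id per row: seeded permutation π then fold(i) = π(i) mod k.

    If ``y`` is given and some fold's complementary training set would miss
    a class, the assignment is redone with per-class (stratified) modulo
    and a warning — rare, but possible for tiny classes.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % k
    if y is not None and stratify_check:
        y = np.asarray(y)
        classes = np.unique(y)
        ok = all(
            set(classes) <= set(np.unique(y[folds != f])) for f in range(k)
        )
        if not ok:
            logger.warning("a fold's training part misses a class; refolding stratified")
            folds = np.empty(n, dtype=int)
            for c in classes:
                idx = np.flatnonzero(y == c)
                folds[idx] = rng.permutation(len(idx)) % k
    return folds


# ---------------------------------------------------------------------------
# Nonnegative meta-learner
# ---------------------------------------------------------------------------


@dataclass
class NonnegativeMultinomialGLM:
    """Multinomial logistic meta-model with box-constrained weights.

    Class-c logit = b_c + w_c · z with every w_cj ≥ 0 (intercepts free),
    fit by L-BFGS-B on the weighted cross-entropy with a small L2 penalty
    on the weights for conditioning.
    """

    weights: np.ndarray  # K x m, all >= 0
    intercepts: np.ndarray  # K
    l2: float = 1e-6

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        logits = Z @ self.weights.T + self.intercepts[None, :]
        return softmax(logits, axis=1)

    @classmethod
    def fit(
        cls,
        Z: np.ndarray,
        y: np.ndarray,
        sample_weight: np.ndarray | None = None,
        l2: float = 1e-6,
    ) -> "NonnegativeMultinomialGLM":
        Z = np.asarray(Z, dtype=float)
        y = np.asarray(y, dtype=int)
        n, m = Z.shape
        K = len(CLASS_CODES)
        yidx = np.searchsorted(_CODES, y)
        Y = np.zeros((n, K))
        Y[np.arange(n), yidx] = 1.0
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        w = w / w.sum()

        def unpack(theta):
            W = theta[: K * m].reshape(K, m)
            b = theta[K * m:]
            return W, b

        def objective(theta):
            W, b = unpack(theta)
            logits = Z @ W.T + b[None, :]
            logits -= logits.max(axis=1, keepdims=True)
            logZ = np.log(np.exp(logits).sum(axis=1))
            ll = (logits[np.arange(n), yidx] - logZ) * w
            P = np.exp(logits - logZ[:, None])
            loss = -ll.sum() + 0.5 * l2 * np.sum(W**2)
            G = (P - Y) * w[:, None]
            gW = G.T @ Z + l2 * W
            gb = G.sum(axis=0)
            return loss, np.concatenate([gW.ravel(), gb])

        theta0 = np.zeros(K * m + K)
        bounds = [(0.0, None)] * (K * m) + [(None, None)] * K
        res = minimize(
            objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500},
        )
        W, b = unpack(res.x)
        W = np.maximum(W, 0.0)  # exact nonnegativity despite solver tolerance
        return cls(weights=W, intercepts=b, l2=l2)

    #: Ridge-penalty grid searched by :meth:`fit_cv`.  The weighted
    #: cross-entropy is a mean, so a fixed penalty acts relative to one
    #: observation's loss; small samples need visibly more shrinkage.
    L2_GRID: tuple[float, ...] = (1e-6, 1e-4, 1e-3, 1e-2)

    @classmethod
    def fit_cv(
        cls,
        Z: np.ndarray,
        y: np.ndarray,
        sample_weight: np.ndarray | None = None,
        l2_grid: tuple[float, ...] | None = None,
        k: int = 5,
        seed: int = 0,
    ) -> "NonnegativeMultinomialGLM":
        """Fit with the ridge penalty chosen by inner k-fold logloss.

        The meta-model sits on few, highly collinear probability columns;
        an unshrunk fit can run its weights to extreme logits and overfit
        small out-of-fold matrices.  A small internal grid over the
        penalty, scored by held-out logloss, keeps the combination
        calibrated at every sample size.  Deterministic under ``seed``.
        """
        from .metrics import logloss as _ll

        grid = cls.L2_GRID if l2_grid is None else l2_grid
        if len(grid) > 1 and len(y) >= 4 * k:
            folds = np.random.default_rng(seed).permutation(len(y)) % k
            losses = []
            for l2 in grid:
                P = np.zeros((len(y), len(CLASS_CODES)))
                for f in range(k):
                    tr = folds != f
                    sw = None if sample_weight is None else sample_weight[tr]
                    m = cls.fit(Z[tr], y[tr], sample_weight=sw, l2=l2)
                    P[~tr] = m.predict_proba(Z[~tr])
                losses.append(_ll(y, P))
            best = grid[int(np.argmin(losses))]
        else:
            best = grid[0] if len(grid) == 1 else 1e-3
        return cls.fit(Z, y, sample_weight=sample_weight, l2=best)


@dataclass
class NonnegativeLinearMeta:
    """Continuous-mode meta-model: nonnegative least squares with a free
    intercept over the base learners' real predictions."""

    weights: np.ndarray
    intercept: float

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.weights + self.intercept

    @classmethod
    def fit(
        cls, Z: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
    ) -> "NonnegativeLinearMeta":
        Z = np.asarray(Z, dtype=float)
        y = np.asarray(y, dtype=float)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        sw = np.sqrt(w / w.sum())
        A = np.hstack([Z * sw[:, None], sw[:, None]])
        lb = np.r_[np.zeros(Z.shape[1]), -np.inf]
        res = lsq_linear(A, y * sw, bounds=(lb, np.full(Z.shape[1] + 1, np.inf)))
        return cls(weights=np.maximum(res.x[:-1], 0.0), intercept=float(res.x[-1]))


# ---------------------------------------------------------------------------
# Stacked model
# ---------------------------------------------------------------------------


@dataclass
class StackedModel:
    """Three refit base learners plus the fitted nonnegative meta-learner."""

    base_models: list[TrainedBaseModel]
    meta: NonnegativeMultinomialGLM | NonnegativeLinearMeta
    folds: int
    seed: int
    mode: str
    preprocessing_state: ImputationState | None = None

    @property
    def kinds(self) -> list[str]:
        return [m.spec.kind for m in self.base_models]


def _meta_features_cat(models, X: np.ndarray) -> np.ndarray:
    return np.hstack([predict_proba(m, X) for m in models])


def _meta_features_cont(models, X: np.ndarray) -> np.ndarray:
    return np.column_stack([predict_real(m, X) for m in models])


def _oof_meta_features(
    design: TrainingDesign,
    specs: list[BaseLearnerSpec],
    folds: np.ndarray,
    k: int,
    seed: int,
    mode: str,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Out-of-fold meta-feature matrix plus per-learner OOF blocks."""
    n = design.n
    width = len(CLASS_CODES) if mode == "categorical" else 1
    blocks = [np.zeros((n, width)) for _ in specs]
    for f in range(k):
        tr = folds != f
        te = ~tr
        sub = TrainingDesign(
            X=design.X[tr], y=design.y[tr], weights=design.weights[tr],
            imputation_state=design.imputation_state,
        )
        for j, spec in enumerate(specs):
            model = fit_base(spec.with_seed(seed + j), sub)
            if mode == "categorical":
                blocks[j][te] = predict_proba(model, design.X[te])
            else:
                blocks[j][te] = predict_real(model, design.X[te])[:, None]
    Z = np.hstack(blocks)
    return Z, blocks


def fit_superlearner(
    design: TrainingDesign,
    specs: list[BaseLearnerSpec],
    k: int = 5,
    seed: int = 0,
    mode: str = "categorical",
) -> StackedModel:
    """Fit the stacked ensemble.

    ``specs`` are the three base-learner specifications (GLM, GBM, DRF in
    the conventional order).  Deterministic under the seed; invariant to
    the storage order of the design rows.
    """
    if mode not in ("categorical", "continuous"):
        raise ValueError(f"unknown mode {mode!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    order = canonical_order(design.X, design.y)
    canon = TrainingDesign(
        X=design.X[order], y=design.y[order], weights=design.weights[order],
        imputation_state=design.imputation_state,
    )
    folds = modulo_folds(canon.n, k, seed, y=canon.y if mode == "categorical" else None)
    Z, _ = _oof_meta_features(canon, specs, folds, k, seed, mode)
    if mode == "categorical":
        meta: NonnegativeMultinomialGLM | NonnegativeLinearMeta = (
            NonnegativeMultinomialGLM.fit_cv(
                Z, canon.y, sample_weight=canon.weights, k=k, seed=seed + 101
            )
        )
    else:
        meta = NonnegativeLinearMeta.fit(
            Z, canon.y.astype(float), sample_weight=canon.weights
        )
    base_models = [fit_base(s.with_seed(seed + j), canon) for j, s in enumerate(specs)]
    return StackedModel(
        base_models=base_models, meta=meta, folds=k, seed=seed, mode=mode,
        preprocessing_state=design.imputation_state,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _prepare_matrix(model: StackedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Apply the stored preprocessing to a raw feature matrix."""
    filled, unusable = fill_mean_scores(matrix)
    if unusable.any():
        logger.warning(
            "%d prediction rows have no variant-level scores; imputed throughout",
            int(unusable.sum()),
        )
    if model.preprocessing_state is None:
        raise ValueError("model has no stored preprocessing state")
    complete, _ = impute_missing(filled, model.preprocessing_state)
    return complete.values


def predict_stack(
    model: StackedModel,
    X: np.ndarray | FeatureMatrix,
    chunk_size: int | None = None,
) -> tuple[np.ndarray, list[ClassLabel]]:
    """Ensemble probabilities and class labels.

    Accepts either a complete numeric matrix or a raw
    :class:`FeatureMatrix` (mean-fill and training-mean imputation applied
    first).  Argmax ties break toward the more pathogenic (lower) code.
    With ``chunk_size`` the rows are streamed in chunks with constant
    memory per chunk; the output is identical to a single pass.
    """
    if isinstance(X, FeatureMatrix):
        X = _prepare_matrix(model, X)
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty((0, len(CLASS_CODES))), []
    if model.mode != "categorical":
        raise ValueError("class prediction requires a categorical-mode model")
    n = X.shape[0]
    step = n if not chunk_size else max(1, int(chunk_size))
    probs = np.empty((n, len(CLASS_CODES)))
    for start in range(0, n, step):
        block = X[start:start + step]
        Z = _meta_features_cat(model.base_models, block)
        probs[start:start + step] = model.meta.predict_proba(Z)
    # argmax returns the first maximum; class order starts at the most
    # pathogenic code, so exact ties resolve toward pathogenic
    labels = [ClassLabel(int(_CODES[i])) for i in np.argmax(probs, axis=1)]
    return probs, labels


def predict_stack_real(
    model: StackedModel, X: np.ndarray | FeatureMatrix, chunk_size: int | None = None
) -> np.ndarray:
    """Continuous-mode ensemble prediction (real value per row)."""
    if isinstance(X, FeatureMatrix):
        X = _prepare_matrix(model, X)
    X = np.asarray(X, dtype=float)
    if model.mode != "continuous":
        raise ValueError("real prediction requires a continuous-mode model")
    if X.shape[0] == 0:
        return np.empty(0)
    n = X.shape[0]
    step = n if not chunk_size else max(1, int(chunk_size))
    out = np.empty(n)
    for start in range(0, n, step):
        Z = _meta_features_cont(model.base_models, X[start:start + step])
        out[start:start + step] = model.meta.predict(Z)
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def crossvalidate(
    design: TrainingDesign,
    specs: list[BaseLearnerSpec],
    k: int = 5,
    seed: int = 0,
    mode: str = "categorical",
) -> dict[str, MetricsReport]:
    """k-fold cross-validated metric blocks for GLM, GBM, DRF and Ensemble.

    Base-learner metrics are computed on their out-of-fold predictions.
    The ensemble is scored by a second-level k-fold over the out-of-fold
    meta-feature matrix: the meta-learner is refit with each fold held out
    and evaluated on it, so its metrics are held-out as well.
    """
    if mode not in ("categorical", "continuous"):
        raise ValueError(f"unknown mode {mode!r}")
    order = canonical_order(design.X, design.y)
    canon = TrainingDesign(
        X=design.X[order], y=design.y[order], weights=design.weights[order],
        imputation_state=design.imputation_state,
    )
    folds = modulo_folds(canon.n, k, seed, y=canon.y if mode == "categorical" else None)
    Z, blocks = _oof_meta_features(canon, specs, folds, k, seed, mode)

    reports: dict[str, MetricsReport] = {}
    for spec, block in zip(specs, blocks):
        if mode == "categorical":
            reports[spec.kind] = categorical_report(canon.y, block)
        else:
            reports[spec.kind] = continuous_report(canon.y.astype(float), block[:, 0])

    if mode == "categorical":
        ens_P = np.zeros_like(Z[:, : len(CLASS_CODES)])
        for f in range(k):
            tr = folds != f
            meta = NonnegativeMultinomialGLM.fit_cv(
                Z[tr], canon.y[tr], sample_weight=canon.weights[tr],
                k=k, seed=seed + 211 + f,
            )
            ens_P[~tr] = meta.predict_proba(Z[~tr])
        reports["Ensemble"] = categorical_report(canon.y, ens_P)
    else:
        ens_pred = np.zeros(canon.n)
        for f in range(k):
            tr = folds != f
            meta = NonnegativeLinearMeta.fit(
                Z[tr], canon.y[tr].astype(float), sample_weight=canon.weights[tr]
            )
            ens_pred[~tr] = meta.predict(Z[~tr])
        reports["Ensemble"] = continuous_report(canon.y.astype(float), ens_pred)
    return reports


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------


def save_bundle(model: StackedModel, directory: str | Path) -> None:
    """Serialize a stacked model to a versioned on-disk bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "bundle_version": BUNDLE_VERSION,
        "mode": model.mode,
        "folds": model.folds,
        "seed": model.seed,
        "base_kinds": model.kinds,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(model, directory / "model.joblib")


def load_bundle(directory: str | Path) -> StackedModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("bundle_version") != BUNDLE_VERSION:
        raise ValueError(
            f"unsupported bundle version {manifest.get('bundle_version')!r}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return joblib.load(directory / "model.joblib")
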