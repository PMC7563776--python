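"""Training-design construction: mean-score substitution, imputation,
class downsampling and class balancing.

The pipeline order mirrors how the training table is assembled: the
per-variant mean score is filled into position x31 first, missing cells are
then imputed with training-column means, the over-represented
uncertain-significance class is randomly downsampled (seven-fold by
default), and finally classes are balanced by per-row weights or by
replication.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_model import (
    CLASS_CODES,
    FeatureMatrix,
    INDISP_IDX,
    MEAN_IDX,
    MEANABLE_IDX,
    N_FEATURES,
    SCORE_IDS,
)

logger = logging.getLogger("cvep")


@dataclass
class ImputationState:
    """Per-column fill values learned on training rows only."""

    column_means: np.ndarray  # length 41

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float)
        if self.column_means.ndim != 1:
            raise ValueError("imputation state must be a vector of per-column means")


@dataclass
class TrainingDesign:
    """Complete design matrix ready for the learners.

    ``X`` has no missing cells; ``y`` holds ordinal class codes in
    {−2…+2}; ``weights`` (or row replication, depending on the balancing
    mode) equalizes effective per-class totals; ``imputation_state`` is
    retained so prediction-time inputs are filled with the training means.
    """

    X: np.ndarray
    y: np.ndarray
    weights: np.ndarray
    imputation_state: ImputationState
    imputed_mask: np.ndarray | None = None
    row_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing cells")
        bad = set(np.unique(self.y)) - set(CLASS_CODES)
        if bad:
            raise ValueError(f"labels outside the five class codes: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# Mean score (x31)
# ---------------------------------------------------------------------------


def compute_mean_score(scores: np.ndarray) -> float:
    """Per-variant mean over the available variant-level scores.

    The mean is taken over the non-missing entries of the 39 variant-level
    scores — positions x1…x30 and x32…x40; the mean slot itself (x31) and
    the gene-level indispensability (x41) never enter the average.  This
    fills the slot that held a mostly-missing score in the source database.

    Raises ``ValueError`` if all 39 inputs are missing (such a row is
    unusable for training).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (N_FEATURES,):
        raise ValueError(f"expected a {N_FEATURES}-vector")
    pool = scores[list(MEANABLE_IDX)]
    avail = ~np.isnan(pool)
    if not avail.any():
        raise ValueError("all 39 variant-level scores missing; row unusable")
    return float(pool[avail].mean())


def fill_mean_scores(matrix: FeatureMatrix) -> tuple[FeatureMatrix, np.ndarray]:
    """Fill column x31 of a copy of ``matrix`` with per-row mean scores.

    Returns the filled matrix and a boolean vector flagging rows whose 39
    variant-level scores were all missing (x31 left missing there).
    """
    out = matrix.copy()
    dense = matrix.dense()
    pool = dense[:, list(MEANABLE_IDX)]
    avail = ~np.isnan(pool)
    counts = avail.sum(axis=1)
    unusable = counts == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(pool, axis=1)
    ok = ~unusable
    out.values[ok, MEAN_IDX] = means[ok]
    out.mask[ok, MEAN_IDX] = False
    if unusable.any():
        logger.warning("%d rows have no variant-level scores; flagged unusable", unusable.sum())
    return out, unusable


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute_missing(
    matrix: FeatureMatrix,
    state: ImputationState | None = None,
) -> tuple[FeatureMatrix, ImputationState]:
    """Fill missing cells with per-column training means.

    When ``state`` is None the column means are learned from the available
    cells of ``matrix`` (training time); a column with no available cell is
    a hard error.  When ``state`` is given (prediction time) the stored
    training means are reused and the batch's own means are never
    consulted.  The original mask is preserved on the input matrix, so the
    "was imputed" indicator stays recoverable for diagnostics.
    """
    dense = matrix.dense()
    if state is None:
        empty = matrix.mask.all(axis=0)
        if empty.any():
            names = [SCORE_IDS[j] for j in np.flatnonzero(empty)]
            raise ValueError(f"column(s) entirely missing in training data: {names}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            state = ImputationState(np.nanmean(dense, axis=0))
    filled = np.where(np.isnan(dense), state.column_means[None, :], dense)
    out = FeatureMatrix(
        filled, np.zeros_like(matrix.mask), matrix.columns, list(matrix.row_ids)
    )
    return out, state


# ---------------------------------------------------------------------------
# Downsampling and balancing
# ---------------------------------------------------------------------------


def downsample_class(
    y: np.ndarray,
    target_class: int,
    factor: int,
    seed: int,
) -> np.ndarray:
    """Row indices keeping a uniform 1/``factor`` subset of one class.

    Retains ``floor(n_class / factor)`` rows of ``target_class`` chosen
    uniformly at random under ``seed`` (at least one, with a warning, if
    the factor exceeds the class size); all other classes are untouched.
    The returned indices are sorted, so relative row order is preserved.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    y = np.asarray(y, dtype=int)
    cls_idx = np.flatnonzero(y == target_class)
    keep_n = len(cls_idx) // factor
    if keep_n == 0 and len(cls_idx) > 0:
        logger.warning(
            "downsampling factor %d exceeds class size %d; retaining 1 row", factor, len(cls_idx)
        )
        keep_n = 1
    rng = np.random.default_rng(seed)
    kept = rng.choice(cls_idx, size=keep_n, replace=False) if len(cls_idx) else cls_idx
    others = np.flatnonzero(y != target_class)
    return np.sort(np.concatenate([others, kept]).astype(int))


@dataclass
class BalancingRecipe:
    """Per-row balancing: either weights or a replicated row index."""

    mode: str  # "weight" | "replicate"
    weights: np.ndarray | None = None
    indices: np.ndarray | None = None

    def effective_counts(self, y: np.ndarray) -> dict[int, float]:
        y = np.asarray(y, dtype=int)
        if self.mode == "weight":
            return {
                int(c): float(self.weights[y == c].sum()) for c in np.unique(y)
            }
        counts: dict[int, float] = {}
        yy = y[self.indices]
        for c in np.unique(yy):
            counts[int(c)] = float((yy == c).sum())
        return counts


def balance_classes(y: np.ndarray, mode: str = "weight", seed: int = 0) -> BalancingRecipe:
    """Equalize effective per-class totals.

    ``weight`` mode assigns each row the weight max_count / class_count;
    ``replicate`` mode oversamples minority classes with replacement up to
    the majority count.  Both give every class the same effective total.
    """
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balancing requires at least two classes")
    max_count = counts.max()
    if mode == "weight":
        per_class = {int(c): max_count / n for c, n in zip(classes, counts)}
        w = np.array([per_class[int(v)] for v in y])
        return BalancingRecipe(mode="weight", weights=w)
    if mode == "replicate":
        rng = np.random.default_rng(seed)
        parts = []
        for c, n in zip(classes, counts):
            idx = np.flatnonzero(y == c)
            parts.append(idx)
            extra = max_count - n
            if extra > 0:
                parts.append(rng.choice(idx, size=extra, replace=True))
        indices = np.sort(np.concatenate(parts))
        return BalancingRecipe(mode="replicate", indices=indices)
    raise ValueError(f"unknown balancing mode {mode!r}")


# ---------------------------------------------------------------------------
# End-to-end design construction
# ---------------------------------------------------------------------------


def build_training_design(
    matrix: FeatureMatrix,
    y: np.ndarray,
    downsample_factor: int = 7,
    downsample_target: int = 0,
    balance_mode: str = "weight",
    seed: int = 0,
) -> TrainingDesign:
    """Mean-fill, drop unusable rows, downsample, impute and balance.

    One master ``seed`` drives the downsampling draw and (in replicate
    mode) the oversampling draw, so the whole design is reproducible
    end-to-end.  The uncertain-significance class (code 0) is downsampled
    ``downsample_factor``-fold by default.
    """
    y = np.asarray(y, dtype=int)
    if matrix.n != len(y):
        raise ValueError("matrix and labels have different lengths")
    filled, unusable = fill_mean_scores(matrix)
    usable = np.flatnonzero(~unusable)
    sub = FeatureMatrix(
        filled.values[usable], filled.mask[usable], filled.columns,
        [filled.row_ids[i] for i in usable],
    )
    y_sub = y[usable]
    if downsample_factor > 1:
        keep = downsample_class(y_sub, downsample_target, downsample_factor, seed)
        sub = FeatureMatrix(
            sub.values[keep], sub.mask[keep], sub.columns, [sub.row_ids[i] for i in keep]
        )
        y_sub = y_sub[keep]
    imputed_mask = sub.mask.copy()
    complete, state = impute_missing(sub)
    recipe = balance_classes(y_sub, mode=balance_mode, seed=seed + 1)
    if recipe.mode == "replicate":
        idx = recipe.indices
        X = complete.values[idx]
        yy = y_sub[idx]
        w = np.ones(len(idx))
        ids = [complete.row_ids[i] for i in idx]
        imputed_mask = imputed_mask[idx]
    else:
        X, yy, w, ids = complete.values, y_sub, recipe.weights, list(complete.row_ids)
    return TrainingDesign(
        X=X, y=yy, weights=w, imputation_state=state,
        imputed_mask=imputed_mask, row_ids=ids,
    )
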