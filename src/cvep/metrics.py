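"""Scalar performance metrics and the confusion matrix.

All metrics operate on the five ordinal class codes −2…+2 (Pathogenic …
Benign) in that fixed order.  Each has a plain, brute-force-checkable
definition:

* ``logloss`` — mean multinomial logarithmic loss, −mean log p(true class).
* ``hit_ratio`` — HRw, the fraction of predictions within w−1 ordinal
  classes of the truth (HR1 = exact, HR2 allows the nearest class, HR5 is
  always 1).
* ``mean_per_class_error`` — unweighted mean over classes of
  1 − within-class accuracy.
* ``mcfadden_r2`` — likelihood-ratio index 1 − llf/ll0.
* ``continuous_metrics`` — mse/rmse/mae/mrd/Pearson for the real-valued
  prediction mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .io_model import CLASS_CODES

logger = logging.getLogger("cvep")

#: Probability floor applied before taking logs, to keep the loss finite.
LOGLOSS_EPS = 1e-15

_CODE_INDEX = {c: i for i, c in enumerate(CLASS_CODES)}


def _check_codes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    bad = set(np.unique(y)) - set(CLASS_CODES)
    if bad:
        raise ValueError(f"labels outside the five class codes: {sorted(bad)}")
    return y


def logloss(y: np.ndarray, P: np.ndarray, clip: bool = True) -> float:
    """Mean multinomial logarithmic loss.

    For each observation only the probability assigned to its true class
    enters the sum: loss = −mean_o log p(y_o).  A perfect predictor scores
    exactly 0 (with ``clip=False``) and the loss grows as predicted
    probability diverges from the actual label.  With ``clip=True``
    probabilities are floored at 1e-15 first, so degenerate zeros stay
    finite.
    """
    y = _check_codes(y)
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(CLASS_CODES):
        raise ValueError("P must be n x 5")
    if P.shape[0] != len(y):
        raise ValueError("P and y have different lengths")
    idx = np.array([_CODE_INDEX[c] for c in y])
    p_true = P[np.arange(len(y)), idx]
    if clip:
        p_true = np.clip(p_true, LOGLOSS_EPS, 1.0 - LOGLOSS_EPS)
    return float(-np.mean(np.log(p_true)))


def hit_ratio(y: np.ndarray, predicted: np.ndarray, width: int) -> float:
    """HRw: fraction of rows with |predicted − true| ≤ width−1 on the
    ordinal code scale.  width=1 is exact-class accuracy; width=2 accepts
    the adjacent class; width=5 is 1 by construction."""
    if not 1 <= width <= 5:
        raise ValueError("width must be in 1..5")
    y = _check_codes(y)
    predicted = _check_codes(predicted)
    if len(y) != len(predicted):
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(predicted - y) <= width - 1))


def hit_ratio_topk(y: np.ndarray, P: np.ndarray, k: int) -> float:
    """Alternative top-k reading of the hit ratio: fraction of rows whose
    true class is among the k highest-probability classes.  Provided for
    comparison; the ordinal adjacency reading (:func:`hit_ratio`) is the
    default throughout."""
    y = _check_codes(y)
    P = np.asarray(P, dtype=float)
    idx = np.array([_CODE_INDEX[c] for c in y])
    order = np.argsort(-P, axis=1, kind="stable")[:, :k]
    return float(np.mean([t in row for t, row in zip(idx, order)]))


def confusion_matrix(y: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """5×5 count matrix, rows = true class, columns = predicted class, in
    code order −2…+2."""
    y = _check_codes(y)
    predicted = _check_codes(predicted)
    if len(y) != len(predicted):
        raise ValueError("length mismatch")
    cm = np.zeros((5, 5), dtype=int)
    for t, p in zip(y, predicted):
        cm[_CODE_INDEX[t], _CODE_INDEX[p]] += 1
    return cm


def mean_per_class_error(confusion: np.ndarray) -> float:
    """Unweighted mean over the five true classes of (1 − class accuracy).

    Classes with zero support are excluded with a warning; an all-zero
    matrix is a hard error.
    """
    confusion = np.asarray(confusion)
    if confusion.shape != (5, 5):
        raise ValueError("confusion must be 5 x 5")
    support = confusion.sum(axis=1)
    if support.sum() == 0:
        raise ValueError("empty confusion matrix")
    present = support > 0
    if not present.all():
        logger.warning(
            "%d class(es) with zero support excluded from mean per-class error",
            int((~present).sum()),
        )
    acc = confusion[present, :].diagonal() if present.all() else np.array(
        [confusion[i, i] for i in np.flatnonzero(present)]
    )
    return float(np.mean(1.0 - acc / support[present]))


def mcfadden_r2(loglik_full: float, loglik_intercept: float) -> float:
    """McFadden's pseudo-R² (likelihood-ratio index): 1 − llf/ll0.

    The intercept-only log-likelihood plays the role of a total sum of
    squares and the full model's that of the residual sum; the ratio scaled
    to 0–1 measures improvement over the intercept model.  1 for a perfect
    fit (llf = 0), 0 for no improvement.
    """
    if loglik_intercept == 0:
        raise ValueError("degenerate single-class data: intercept log-likelihood is 0")
    if loglik_intercept > 0:
        raise ValueError("intercept log-likelihood must be negative")
    return float(1.0 - loglik_full / loglik_intercept)


def expected_code(P: np.ndarray) -> np.ndarray:
    """Probability-weighted expected class code per row."""
    P = np.asarray(P, dtype=float)
    return P @ np.asarray(CLASS_CODES, dtype=float)


def continuous_metrics(
    y_real: np.ndarray, yhat_real: np.ndarray
) -> dict[str, float | None]:
    """mse, rmse, mae, mrd and Pearson correlation for real-valued output.

    ``mrd`` is the mean Gaussian residual deviance (mean squared residual),
    consistent with the Gaussian-distribution fit of the continuous mode.
    Pearson is reported as None when either vector has zero variance.
    """
    y_real = np.asarray(y_real, dtype=float)
    yhat_real = np.asarray(yhat_real, dtype=float)
    if y_real.shape != yhat_real.shape or y_real.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    if len(y_real) < 2:
        raise ValueError("need at least two points")
    if not (np.isfinite(y_real).all() and np.isfinite(yhat_real).all()):
        raise ValueError("non-finite values")
    resid = yhat_real - y_real
    mse = float(np.mean(resid**2))
    out: dict[str, float | None] = {
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "mae": float(np.mean(np.abs(resid))),
        "mrd": mse,
    }
    if np.std(y_real) == 0 or np.std(yhat_real) == 0:
        logger.warning("zero variance; Pearson correlation undefined")
        out["pearson"] = None
    else:
        out["pearson"] = float(np.corrcoef(y_real, yhat_real)[0, 1])
    return out


@dataclass
class MetricsReport:
    """Bundle of the categorical-mode and continuous-mode metrics for one
    model (one column of the CV summary tables)."""

    logloss: float | None = None
    mse: float | None = None
    rmse: float | None = None
    mpce: float | None = None
    hr: tuple[float, ...] | None = None
    confusion: np.ndarray | None = None
    mcfadden_r2: float | None = None
    mae: float | None = None
    mrd: float | None = None
    pearson: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d: dict = {}
        for k in ("logloss", "mse", "rmse", "mpce", "mcfadden_r2", "mae", "mrd", "pearson"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        if self.hr is not None:
            for i, v in enumerate(self.hr, start=1):
                d[f"HR{i}"] = v
        if self.confusion is not None:
            d["confusion"] = np.asarray(self.confusion).tolist()
        d.update(self.extra)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def categorical_report(y: np.ndarray, P: np.ndarray) -> MetricsReport:
    """Full categorical metric block from labels and a probability matrix.

    The class prediction is the argmax with ties broken toward the more
    pathogenic (lower) code; mse/rmse are computed between the integer
    codes and the probability-weighted expected code.
    """
    y = _check_codes(y)
    P = np.asarray(P, dtype=float)
    codes = np.asarray(CLASS_CODES)
    pred = codes[np.argmax(P, axis=1)]  # first maximum = most pathogenic
    cm = confusion_matrix(y, pred)
    exp_code = expected_code(P)
    resid = exp_code - y
    mse = float(np.mean(resid**2))
    ll_full = -logloss(y, P) * len(y)
    freqs = np.array([(y == c).mean() for c in CLASS_CODES])
    present = freqs > 0
    ll0 = float(np.sum([np.sum(y == c) * np.log(f) for c, f in zip(CLASS_CODES, freqs) if f > 0]))
    r2 = mcfadden_r2(ll_full, ll0) if ll0 < 0 else None
    return MetricsReport(
        logloss=logloss(y, P),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mpce=mean_per_class_error(cm),
        hr=tuple(hit_ratio(y, pred, w) for w in range(1, 6)),
        confusion=cm,
        mcfadden_r2=r2,
    )


def continuous_report(y_real: np.ndarray, yhat_real: np.ndarray) -> MetricsReport:
    """Continuous-mode metric block (mse, rmse, mae, mrd, Pearson)."""
    m = continuous_metrics(y_real, yhat_real)
    return MetricsReport(
        mse=m["mse"], rmse=m["rmse"], mae=m["mae"], mrd=m["mrd"], pearson=m["pearson"]
    )
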