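"""Feature ranking, importance league tables and stratified summaries.

Everything here emits plot-ready pandas DataFrames (written as TSV by the
CLI): the single-feature pseudo-R² ranking of all 41 scores, per-learner
importance tables, class-proportion summaries stratified by gene
indispensability or by gene, per-AAF-bin score means, and the per-class
normalized histograms used for 1-D class-discrimination displays.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .io_model import (
    CLASS_CODES,
    CLASS_NAMES,
    FeatureMatrix,
    INDISP_IDX,
    N_FEATURES,
    SCORE_IDS,
    SCORE_NAMES,
    VariantRecord,
)
from .learners import TrainedBaseModel
from .metrics import logloss as _logloss
from .metrics import mcfadden_r2
from .preprocess import TrainingDesign

logger = logging.getLogger("cvep")

#: Indispensability strata: mutation-tolerant, intermediate and essential
#: genes.  The gap 0.7–0.95 is deliberately unassigned (configurable).
DEFAULT_INDISPENSABILITY_RANGES: tuple[tuple[float, float], ...] = (
    (0.0, 0.3),
    (0.3, 0.7),
    (0.95, 1.0),
)


# ---------------------------------------------------------------------------
# Single-feature ranking
# ---------------------------------------------------------------------------


def _single_feature_pseudo_r2(x: np.ndarray, y: np.ndarray, w: np.ndarray, seed: int) -> float:
    """McFadden pseudo-R² of a one-feature multinomial logistic fit."""
    if np.std(x) == 0:
        logger.warning("constant feature; pseudo-R2 set to 0")
        return 0.0
    # weak regularization approximates the maximum-likelihood fit
    est = LogisticRegression(C=1e4, max_iter=500, solver="lbfgs")
    est.fit(x[:, None], y, sample_weight=w)
    P = est.predict_proba(x[:, None])
    seen = [int(c) for c in est.classes_]
    full = np.zeros((len(y), len(CLASS_CODES)))
    for j, code in enumerate(CLASS_CODES):
        if code in seen:
            full[:, j] = P[:, seen.index(code)]
    wn = w / w.sum()
    idx = np.searchsorted(np.asarray(CLASS_CODES), y)
    p_true = np.clip(full[np.arange(len(y)), idx], 1e-15, 1.0)
    llf = float(np.sum(wn * np.log(p_true)))
    class_freq = np.array([wn[y == c].sum() for c in CLASS_CODES])
    ll0 = float(
        np.sum([wn[y == c].sum() * np.log(f) for c, f in zip(CLASS_CODES, class_freq) if f > 0])
    )
    return max(0.0, mcfadden_r2(llf, ll0))


def rank_features_single_glm(design: TrainingDesign, seed: int = 0) -> pd.DataFrame:
    """Rank all 41 features by single-feature GLM pseudo-R².

    Each score is fit alone in a multinomial logistic regression against
    the five-class target and scored by McFadden's pseudo-R²; the table is
    sorted descending with ranks 1…41.  Invariant to row order of the
    design (single-feature fits see one column only).
    """
    rows = []
    for j in range(N_FEATURES):
        r2 = _single_feature_pseudo_r2(design.X[:, j], design.y, design.weights, seed)
        rows.append({"feature": SCORE_IDS[j], "score_name": SCORE_NAMES[j], "pseudo_r2": r2})
    table = pd.DataFrame(rows).sort_values(
        "pseudo_r2", ascending=False, kind="stable"
    )
    table["rank"] = np.arange(1, N_FEATURES + 1)
    return table.reset_index(drop=True)


def importance_tables(base_models: Sequence[TrainedBaseModel]) -> dict[str, pd.DataFrame]:
    """Per-model descending importance lists keyed by learner kind."""
    out: dict[str, pd.DataFrame] = {}
    for model in base_models:
        order = np.argsort(-model.importance, kind="stable")
        out[model.spec.kind] = pd.DataFrame(
            {
                "feature": [SCORE_IDS[i] for i in order],
                "score_name": [SCORE_NAMES[i] for i in order],
                "importance": model.importance[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Stratified class proportions
# ---------------------------------------------------------------------------


def _proportion_row(codes: np.ndarray) -> dict[str, float]:
    n = len(codes)
    row: dict[str, float] = {"n": n}
    for code, name in zip(CLASS_CODES, CLASS_NAMES):
        row[name] = float((codes == code).mean()) if n else float("nan")
    return row


def stratify_by_indispensability(
    predicted_codes: np.ndarray,
    indispensability: np.ndarray,
    ranges: Sequence[tuple[float, float]] = DEFAULT_INDISPENSABILITY_RANGES,
) -> pd.DataFrame:
    """Per-range five-class proportion summary.

    Ranges are half-open [lo, hi) with the final range closed at the top;
    they must not overlap.  An empty stratum is emitted with n = 0 and
    missing proportions.
    """
    ranges = sorted(ranges)
    for (lo1, hi1), (lo2, _) in zip(ranges, ranges[1:]):
        if lo2 < hi1:
            raise ValueError("indispensability ranges overlap")
    predicted_codes = np.asarray(predicted_codes, dtype=int)
    indispensability = np.asarray(indispensability, dtype=float)
    top = max(hi for _, hi in ranges)
    rows = []
    for lo, hi in ranges:
        if hi == top:
            in_range = (indispensability >= lo) & (indispensability <= hi)
        else:
            in_range = (indispensability >= lo) & (indispensability < hi)
        row = {"stratum": f"{lo:g} <= I < {hi:g}", "lo": lo, "hi": hi}
        row.update(_proportion_row(predicted_codes[in_range]))
        rows.append(row)
    return pd.DataFrame(rows)


def gene_class_proportions(
    predicted_codes: np.ndarray, genes: Sequence[str]
) -> pd.DataFrame:
    """Per-gene five-class proportions (gene symbols case-normalized)."""
    predicted_codes = np.asarray(predicted_codes, dtype=int)
    genes_norm = np.asarray([str(g).upper() for g in genes])
    rows = []
    for gene in sorted(set(genes_norm)):
        sel = genes_norm == gene
        row = {"gene": gene}
        row.update(_proportion_row(predicted_codes[sel]))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AAF summaries
# ---------------------------------------------------------------------------

#: Six decadal AAF bins from common ([1, 0.1]) to ultra-rare ([1e-5, 1e-6]).
DECADAL_AAF_EDGES: tuple[float, ...] = (1.0, 1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6)


def score_means_by_aaf_bins(
    matrix: FeatureMatrix,
    aaf: np.ndarray,
    bin_edges: Sequence[float] = DECADAL_AAF_EDGES,
) -> pd.DataFrame:
    """Mean of each of the 40 variant-level scores per decadal AAF bin.

    The indispensability column (x41) is a gene-level quantity and is
    excluded.  Rows with AAF = 0 or missing are excluded (their count is
    reported in the ``n_excluded`` attribute); empty bins keep missing
    means.  Bins are [hi, lo) on the descending decade scale, the last one
    closed.
    """
    aaf = np.asarray(aaf, dtype=float)
    dense = matrix.dense()
    excluded = ~(np.isfinite(aaf) & (aaf > 0))
    rows = []
    edges = list(bin_edges)
    score_cols = [j for j in range(N_FEATURES) if j != INDISP_IDX]
    for b, (hi, lo) in enumerate(zip(edges, edges[1:])):
        last = b == len(edges) - 2
        sel = (~excluded) & (aaf <= hi) & ((aaf >= lo) if last else (aaf > lo))
        row: dict[str, float] = {"bin": f"[{hi:g}, {lo:g}]", "hi": hi, "lo": lo,
                                 "n": int(sel.sum())}
        for j in score_cols:
            vals = dense[sel, j]
            vals = vals[np.isfinite(vals)]
            row[SCORE_IDS[j]] = float(vals.mean()) if len(vals) else float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = int(excluded.sum())
    return out


def aaf_popmax_flag(records: Sequence[VariantRecord]) -> pd.Series:
    """Per-row rare-subpopulation indicator.

    True iff aaf_popmax − aaf > 0 (strictly) and aaf < 1e-4 — a variant
    both ultra-rare overall and over-represented in some sub-population,
    a useful extra signal for very rare pathogenic variants.  Missing
    (pd.NA) where either frequency field is absent.
    """
    vals = []
    for rec in records:
        if not (np.isfinite(rec.aaf) and np.isfinite(rec.aaf_popmax)):
            vals.append(pd.NA)
        else:
            vals.append(bool(rec.aaf_popmax - rec.aaf > 0 and rec.aaf < 1e-4))
    return pd.Series(vals, dtype="boolean")


# ---------------------------------------------------------------------------
# Class histograms
# ---------------------------------------------------------------------------


def class_histograms(
    values: np.ndarray,
    codes: np.ndarray,
    feature: str = "score",
    bins: int = 20,
) -> pd.DataFrame:
    """Per-class binned counts normalized by the grand total.

    For score features the range is [0, 1] in ``bins`` equal steps
    (default 20 × 0.05).  For ``feature="AAF"`` binning is on the log10
    scale with step 0.25 over [−6, 0] (24 bins).  Counts are normalized so
    the total over all classes and bins is 1.  Bins are half-open with the
    last bin closed.
    """
    values = np.asarray(values, dtype=float)
    codes = np.asarray(codes, dtype=int)
    finite = np.isfinite(values)
    if feature.upper() == "AAF":
        finite &= values > 0
        x = np.log10(values[finite])
        edges = np.arange(-6.0, 0.0 + 1e-9, 0.25)
    else:
        x = values[finite]
        edges = np.linspace(0.0, 1.0, bins + 1)
    sub_codes = codes[finite]
    total = len(x)
    rows = []
    for code, name in zip(CLASS_CODES, CLASS_NAMES):
        counts, _ = np.histogram(x[sub_codes == code], bins=edges)
        for b in range(len(edges) - 1):
            rows.append(
                {
                    "class": name,
                    "code": code,
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "normalized_count": counts[b] / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)
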