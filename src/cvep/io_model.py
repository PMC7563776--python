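"""Domain types and dbNSFP-style tab-separated I/O.

The package works on per-variant annotation tables in the dbNSFP layout:
one row per non-synonymous SNV carrying coordinates, a gene symbol, 41
rank-score features in [0, 1] (40 variant-level functional/conservation
scores, one of which is a per-variant mean, plus a gene-level
indispensability score), optional allele-frequency fields and an optional
ClinVar clinical-significance string.

Score columns are addressed by the canonical ids ``x1`` … ``x41``; the
conventional dbNSFP score names are kept alongside for display and for
header-driven reading of files that use them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cvep")

# ---------------------------------------------------------------------------
# Canonical feature layout
# ---------------------------------------------------------------------------

#: dbNSFP score identities in canonical column order.  Positions 1-30 are
#: functional-impact rank scores, 31 is the per-variant mean score, 32-40 are
#: cross-species conservation rank scores and 41 is the gene-level
#: indispensability (probability of essentiality).
SCORE_NAMES: tuple[str, ...] = (
    "SIFT_converted",
    "SIFT4G_converted",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT_converted",
    "MutationTaster_converted",
    "MutationAssessor",
    "FATHMM_converted",
    "PROVEAN_converted",
    "VEST4",
    "MetaSVM",
    "MetaLR",
    "M-CAP",
    "REVEL",
    "MutPred",
    "MVP",
    "MPC",
    "PrimateAI",
    "DEOGEN2",
    "CADD_raw",
    "DANN",
    "fathmm-MKL_coding",
    "fathmm-XF_coding",
    "Eigen-raw_coding",
    "Eigen-PC-raw_coding",
    "GenoCanyon_score",
    "integrated_fitCons",
    "GM12878_fitCons",
    "H1-hESC_fitCons",
    "HUVEC_fitCons",
    "Mean",
    "GERP++_RS",
    "phyloP100way_vertebrate",
    "phyloP30way_mammalian",
    "phyloP17way_primate",
    "phastCons100way_vertebrate",
    "phastCons30way_mammalian",
    "phastCons17way_primate",
    "SiPhy_29way_logOdds",
    "bStatistic",
    "Gene_indispensability",
)

N_FEATURES = 41
SCORE_IDS: tuple[str, ...] = tuple(f"x{i}" for i in range(1, N_FEATURES + 1))
MEAN_IDX = 30          # 0-based position of the mean score (x31)
INDISP_IDX = 40        # 0-based position of Gene_indispensability (x41)
#: 0-based positions of the 39 variant-level scores that enter the mean
#: (everything except x31 itself and x41).
MEANABLE_IDX: tuple[int, ...] = tuple(
    i for i in range(N_FEATURES) if i not in (MEAN_IDX, INDISP_IDX)
)

MISSING_TOKENS = (".", "", "NA")
MANDATORY_COLUMNS = ("chrom", "pos", "ref", "alt")
VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "M"])

# ---------------------------------------------------------------------------
# Class labels
# ---------------------------------------------------------------------------

CLASS_CODES: tuple[int, ...] = (-2, -1, 0, 1, 2)
CLASS_NAMES: tuple[str, ...] = (
    "Pathogenic",
    "Likely_pathogenic",
    "Uncertain_significance",
    "Likely_benign",
    "Benign",
)
CODE_TO_NAME: dict[int, str] = dict(zip(CLASS_CODES, CLASS_NAMES))
NAME_TO_CODE: dict[str, int] = dict(zip(CLASS_NAMES, CLASS_CODES))

#: Sentinel for significance strings outside the five training classes.
UNLABELLED = "unlabelled"

#: Default significance-string mapping (normalized form -> class code).
#: Compound "X/Likely_X" strings collapse onto the adjacent "Likely" class,
#: which is how the imbalance between the pure and "likely" classes was
#: reduced.  The table is config-extensible.
DEFAULT_CLINVAR_MAP: dict[str, int] = {
    "pathogenic": -2,
    "likely_pathogenic": -1,
    "pathogenic/likely_pathogenic": -1,
    "uncertain_significance": 0,
    "likely_benign": 1,
    "benign/likely_benign": 1,
    "benign": 2,
}


@dataclass(frozen=True)
class ClassLabel:
    """One of the five ordinal pathogenicity classes.

    The integer ``code`` runs from −2 (Pathogenic) to +2 (Benign); ``name``
    is the matching ClinVar-style class name.  Code and name are a bijection.
    """

    code: int

    def __post_init__(self) -> None:
        if self.code not in CODE_TO_NAME:
            raise ValueError(f"invalid class code {self.code!r}; expected one of {CLASS_CODES}")

    @property
    def name(self) -> str:
        return CODE_TO_NAME[self.code]

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        try:
            return cls(NAME_TO_CODE[name])
        except KeyError:
            raise ValueError(f"unknown class name {name!r}") from None


def parse_clinvar_label(
    raw: str | None,
    extra_map: Mapping[str, int] | None = None,
) -> ClassLabel | str:
    """Map a ClinVar clinical-significance string to a :class:`ClassLabel`.

    Matching is case-insensitive and tolerant of spaces vs underscores.
    The compound review strings ``Pathogenic/Likely_pathogenic`` and
    ``Benign/Likely_benign`` merge into the adjacent "Likely" class.
    Anything else — including conflicting-interpretation strings — returns
    the string ``"unlabelled"`` and is excluded from training.

    Parameters
    ----------
    raw:
        The significance string (may be ``None`` or empty).
    extra_map:
        Optional additional normalized-string -> code entries, e.g. from a
        YAML config, consulted after the built-in table.
    """
    if raw is None:
        return UNLABELLED
    key = str(raw).strip().lower().replace(" ", "_")
    if not key or key in {t.lower() for t in MISSING_TOKENS}:
        return UNLABELLED
    code = DEFAULT_CLINVAR_MAP.get(key)
    if code is None and extra_map:
        normalized_extra = {
            str(k).strip().lower().replace(" ", "_"): v for k, v in extra_map.items()
        }
        code = normalized_extra.get(key)
    if code is None:
        return UNLABELLED
    return ClassLabel(code)


# ---------------------------------------------------------------------------
# Records and matrices
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """A single nsSNV with its annotation vector.

    ``scores`` holds the 41 features in canonical order with ``nan`` marking
    missing values.  ``aaf`` / ``aaf_popmax`` are the overall and maximal
    sub-population alternative allele frequencies (``nan`` if unobserved).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    scores: np.ndarray
    aaf: float = float("nan")
    aaf_popmax: float = float("nan")
    clinvar_raw: str | None = None

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def n_available(self) -> int:
        return int(np.sum(~np.isnan(self.scores)))

    def label(self) -> ClassLabel | str:
        return parse_clinvar_label(self.clinvar_raw)


@dataclass
class FeatureMatrix:
    """n × 41 feature table with an explicit missingness mask.

    ``values[i, j]`` is meaningful only where ``mask[i, j]`` is False
    (``mask`` is True at missing cells).  Column order is fixed to the
    canonical dbNSFP order (:data:`SCORE_IDS`).
    """

    values: np.ndarray
    mask: np.ndarray
    columns: tuple[str, ...] = SCORE_IDS
    row_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError(
                f"expected {len(self.columns)} feature columns, got shape {self.values.shape}"
            )
        if not self.row_ids:
            self.row_ids = [str(i) for i in range(self.values.shape[0])]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def available_counts(self) -> np.ndarray:
        """Number of non-missing scores per row."""
        return (~self.mask).sum(axis=1)

    def dense(self) -> np.ndarray:
        """Values with missing cells as nan."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(), self.mask.copy(), self.columns, list(self.row_ids)
        )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _resolve_score_columns(
    header: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical ids x1…x41 to file column names.

    A file column satisfies id ``xk`` if it is literally ``xk``, the
    canonical score name for position k, or is mapped to either by
    ``column_map`` (file-column -> canonical name/id).
    """
    remap: dict[str, str] = {}
    if column_map:
        remap = {str(v): str(k) for k, v in column_map.items()}
    resolved: dict[str, str] = {}
    header_set = set(header)
    for idx, (sid, name) in enumerate(zip(SCORE_IDS, SCORE_NAMES)):
        for candidate in (remap.get(sid), remap.get(name), sid, name):
            if candidate is not None and candidate in header_set:
                resolved[sid] = candidate
                break
    return resolved


def read_feature_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[VariantRecord], FeatureMatrix]:
    """Read a dbNSFP-style TSV into records plus an aligned feature matrix.

    The file must be tab-separated with a header row.  ``chrom``, ``pos``,
    ``ref`` and ``alt`` are mandatory; score columns may be named by
    canonical id (``x1``…``x41``) or dbNSFP score name, optionally remapped
    through ``column_map`` (canonical -> file column).  ``.``, empty and
    ``NA`` cells are missing.

    Rows violating per-row invariants (score outside [0, 1], ref == alt,
    unparseable numerics) are rejected individually with a logged reason;
    ``aaf_popmax < aaf`` is logged as a warning but the row is retained.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        na_values=list(MISSING_TOKENS),
    )
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} missing from {path}")
    score_cols = _resolve_score_columns(df.columns, column_map)

    records: list[VariantRecord] = []
    value_rows: list[np.ndarray] = []
    n_rejected = 0
    for i, row in df.iterrows():
        reason = None
        chrom = str(row["chrom"]) if pd.notna(row["chrom"]) else ""
        ref = str(row["ref"]) if pd.notna(row["ref"]) else ""
        alt = str(row["alt"]) if pd.notna(row["alt"]) else ""
        try:
            pos = int(row["pos"])
        except (TypeError, ValueError):
            reason = f"unparseable pos {row['pos']!r}"
            pos = -1
        if reason is None and ref == alt:
            reason = f"ref == alt ({ref!r})"

        scores = np.full(N_FEATURES, np.nan)
        if reason is None:
            for j, sid in enumerate(SCORE_IDS):
                col = score_cols.get(sid)
                if col is None:
                    continue
                cell = row[col]
                if pd.isna(cell):
                    continue
                try:
                    val = float(cell)
                except ValueError:
                    reason = f"unparseable value {cell!r} in column {col}"
                    break
                if not 0.0 <= val <= 1.0:
                    reason = f"score {val} out of [0, 1] in column {col}"
                    break
                scores[j] = val

        if reason is not None:
            n_rejected += 1
            logger.info("rejecting row %d (%s:%s): %s", i, chrom, row["pos"], reason)
            continue

        def _opt_float(name: str) -> float:
            if name not in df.columns or pd.isna(row[name]):
                return float("nan")
            try:
                return float(row[name])
            except ValueError:
                return float("nan")

        aaf = _opt_float("aaf")
        popmax = _opt_float("aaf_popmax")
        if np.isfinite(aaf) and np.isfinite(popmax) and popmax < aaf:
            logger.warning(
                "row %d (%s:%s): aaf_popmax %.3g < aaf %.3g; retained", i, chrom, pos, popmax, aaf
            )
        clinvar = None
        if "clinvar" in df.columns and pd.notna(row["clinvar"]):
            clinvar = str(row["clinvar"])
        gene = str(row["gene"]) if "gene" in df.columns and pd.notna(row["gene"]) else ""
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                scores=scores, aaf=aaf, aaf_popmax=popmax, clinvar_raw=clinvar,
            )
        )
        value_rows.append(scores)

    if n_rejected:
        logger.info("rejected %d/%d rows from %s", n_rejected, len(df), path)
    values = np.vstack(value_rows) if value_rows else np.empty((0, N_FEATURES))
    mask = np.isnan(values)
    filled = np.where(mask, 0.0, values)
    matrix = FeatureMatrix(filled, mask, SCORE_IDS, [r.key for r in records])
    return records, matrix


def records_to_matrix(records: Iterable[VariantRecord]) -> FeatureMatrix:
    """Stack record score vectors into a :class:`FeatureMatrix`."""
    recs = list(records)
    values = (
        np.vstack([r.scores for r in recs]) if recs else np.empty((0, N_FEATURES))
    )
    mask = np.isnan(values)
    return FeatureMatrix(np.where(mask, 0.0, values), mask, SCORE_IDS, [r.key for r in recs])


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

#: Decimal precision used when writing probabilities and scores.
_FLOAT_FMT = "%.10g"


def write_predictions(
    records: Sequence[VariantRecord],
    predicted: Sequence[ClassLabel],
    probabilities: np.ndarray,
    path: str | Path,
) -> None:
    """Write a prediction TSV: variant key columns, class name/code and the
    five per-class probabilities (columns ``p_m2`` … ``p_p2`` in class-code
    order −2 … +2).

    Probability rows must sum to 1 within 1e-9.  Re-reading reproduces the
    written values at the printed precision, and a write–read–write cycle is
    byte-identical.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if not (len(records) == len(predicted) == probabilities.shape[0]):
        raise ValueError(
            f"length mismatch: {len(records)} records, {len(predicted)} labels, "
            f"{probabilities.shape[0]} probability rows"
        )
    if probabilities.size and probabilities.shape[1] != len(CLASS_CODES):
        raise ValueError("probabilities must have five columns")
    if probabilities.size and np.any(np.abs(probabilities.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("probability rows must sum to 1 within 1e-9")

    prob_cols = [f"p_{'m' if c < 0 else 'p' if c > 0 else ''}{abs(c)}" for c in CLASS_CODES]
    with open(path, "w") as fh:
        fh.write(
            "\t".join(
                ["chrom", "pos", "ref", "alt", "gene", "predicted_class", "predicted_code"]
                + prob_cols
            )
            + "\n"
        )
        for rec, lab, prow in zip(records, predicted, probabilities):
            cells = [
                rec.chrom, str(rec.pos), rec.ref, rec.alt, rec.gene,
                lab.name, str(lab.code),
            ] + [_FLOAT_FMT % p for p in prow]
            fh.write("\t".join(cells) + "\n")


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read back a prediction TSV written by :func:`write_predictions`."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_feature_table(
    records: Sequence[VariantRecord],
    path: str | Path,
    labels: Sequence[str | None] | None = None,
) -> None:
    """Write records as a dbNSFP-style TSV (missing cells as ``.``)."""
    with open(path, "w") as fh:
        header = ["chrom", "pos", "ref", "alt", "gene"] + list(SCORE_IDS) + [
            "aaf", "aaf_popmax", "clinvar",
        ]
        fh.write("\t".join(header) + "\n")
        for i, rec in enumerate(records):
            cells = [rec.chrom, str(rec.pos), rec.ref, rec.alt, rec.gene]
            for v in rec.scores:
                cells.append("." if np.isnan(v) else _FLOAT_FMT % v)
            cells.append("." if np.isnan(rec.aaf) else _FLOAT_FMT % rec.aaf)
            cells.append("." if np.isnan(rec.aaf_popmax) else _FLOAT_FMT % rec.aaf_popmax)
            if labels is not None:
                cells.append(labels[i] if labels[i] else ".")
            else:
                cells.append(rec.clinvar_raw if rec.clinvar_raw else ".")
            fh.write("\t".join(cells) + "\n")
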