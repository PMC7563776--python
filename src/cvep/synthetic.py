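"""Synthetic dbNSFP/gnomAD/ClinVar-like datasets.

No real download is needed to exercise the pipeline: this module draws
annotation tables with the statistical structure the method exploits —
class-conditionally shifted, mutually correlated rank scores in [0, 1];
per-row missingness with 23–40 of the 40 variant-level scores available;
gene indispensability enriched with pathogenicity (benign variants
concentrate in mutation-tolerant, low-indispensability genes); and a steep
allele-frequency spectrum with 85% ultra-rare mass, anti-correlated with
pathogenicity.

The generative model: each variant gets a latent pathogenicity
u = (2 − code)/4 ∈ {0, ¼, ½, ¾, 1} (Benign → 0, Pathogenic → 1) plus
Gaussian class noise; every variant-level score is a clipped mixture of u
(weight = that feature's separation) and correlated beta noise (a shared
per-row latent factor plus independent noise), so class-conditional score
means increase with pathogenicity, matching the 0 = benign / 1 =
pathogenic rank-score convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_model import (
    CLASS_CODES,
    CODE_TO_NAME,
    FeatureMatrix,
    INDISP_IDX,
    MEAN_IDX,
    MEANABLE_IDX,
    N_FEATURES,
    VariantRecord,
    records_to_matrix,
    write_feature_table,
)

#: Training-class frequencies used as default priors, proportional to the
#: five ClinVar class sizes the model was trained on
#: (35,698 / 21,510 / 18,716 / 21,931 / 35,659 for codes −2…+2).
_CLASS_COUNTS = np.array([35698.0, 21510.0, 18716.0, 21931.0, 35659.0])
DEFAULT_CLASS_PRIORS: tuple[float, ...] = tuple(_CLASS_COUNTS / _CLASS_COUNTS.sum())

_BASES = np.array(["A", "C", "G", "T"])
_CHROMS = [str(i) for i in range(1, 23)] + ["X", "Y", "M"]


def default_separation() -> np.ndarray:
    """Per-feature signal strengths: functional scores slightly stronger
    than conservation scores, mirroring their relative single-feature
    discrimination; the mean (x31) and indispensability (x41) slots are
    unused by the score sampler."""
    sep = np.empty(N_FEATURES)
    sep[:30] = 0.65
    sep[31:40] = 0.55
    sep[MEAN_IDX] = 0.0
    sep[INDISP_IDX] = 0.0
    return sep


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n: int = 1000
    class_priors: tuple[float, ...] = DEFAULT_CLASS_PRIORS
    separation: np.ndarray = field(default_factory=default_separation)
    correlation: float = 0.3
    class_noise: float = 0.05
    missingness: tuple[int, int] = (23, 40)
    indispensability_enrichment: float = 6.0
    aaf_ultrarare_mass: float = 0.85
    aaf_anticorrelation: bool = True
    genes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        priors = np.asarray(self.class_priors, dtype=float)
        if priors.shape != (5,) or abs(priors.sum() - 1.0) > 1e-9 or (priors < 0).any():
            raise ValueError("class_priors must be a 5-vector of non-negative values summing to 1")
        sep = np.asarray(self.separation, dtype=float)
        if np.isscalar(self.separation) or sep.ndim == 0:
            sep = np.full(N_FEATURES, float(sep))
        if sep.shape != (N_FEATURES,):
            raise ValueError(f"separation must be scalar or a {N_FEATURES}-vector")
        if ((sep < 0) | (sep > 1)).any():
            raise ValueError("separation strengths must lie in [0, 1]")
        self.separation = sep
        lo, hi = self.missingness
        if not (1 <= lo <= hi <= 40):
            raise ValueError("missingness range must satisfy 1 <= lo <= hi <= 40")
        if not 0.0 <= self.aaf_ultrarare_mass <= 1.0:
            raise ValueError("aaf_ultrarare_mass must be in [0, 1]")
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [0, 1]")


def _sample_aaf(
    rng: np.random.Generator, u_noisy: np.ndarray, mass: float, anticorrelate: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Steep log-scale AAF spectrum via quantile mapping.

    A rarity propensity (pathogenicity plus noise when anti-correlation is
    on, pure noise otherwise) is rank-mapped onto a piecewise target for
    e = −log10 AAF: the top ``mass`` fraction falls in e ∈ (4, 6]
    (AAF < 1e-4, ultra-rare), the rest in e ∈ (0.05, 4].  The monotone map
    preserves the anti-correlation while pinning the ultra-rare fraction.
    """
    n = len(u_noisy)
    propensity = (
        2.0 * u_noisy + rng.normal(0, 0.6, n) if anticorrelate else rng.normal(0, 1, n)
    )
    ranks = np.empty(n, dtype=float)
    ranks[np.argsort(propensity, kind="stable")] = np.arange(n)
    q = (ranks + 0.5) / n
    e = np.where(
        q < 1.0 - mass,
        0.05 + q / max(1.0 - mass, 1e-12) * (4.0 - 0.05),
        4.0 + (q - (1.0 - mass)) / max(mass, 1e-12) * 2.0,
    )
    aaf = 10.0 ** (-e)
    popmax = np.minimum(1.0, aaf * (1.0 + np.abs(rng.normal(0, 0.6, n))))
    return aaf, popmax


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[VariantRecord], FeatureMatrix, np.ndarray]:
    """Draw a full synthetic annotation table.

    Returns records (with ClinVar-style label strings attached), the
    aligned feature matrix with its missingness mask, and the class codes.
    Fully deterministic under ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    priors = np.asarray(cfg.class_priors)
    if (priors == 0).any():
        zero_classes = [CLASS_CODES[i] for i in np.flatnonzero(priors == 0)]
        raise ValueError(
            f"zero prior for class(es) {zero_classes}: balancing downstream would fail"
        )
    codes = rng.choice(np.asarray(CLASS_CODES), size=n, p=priors)
    u = (2.0 - codes) / 4.0
    u_noisy = np.clip(u + rng.normal(0, cfg.class_noise, n), 0.0, 1.0)

    # correlated beta noise: shared per-row latent factor + independent part
    z = rng.beta(2, 2, size=n)
    scores = np.full((n, N_FEATURES), np.nan)
    for j in MEANABLE_IDX:
        e = rng.beta(2, 2, size=n)
        noise = cfg.correlation * z + (1.0 - cfg.correlation) * e
        sep = cfg.separation[j]
        scores[:, j] = np.clip(sep * u_noisy + (1.0 - sep) * noise, 0.0, 1.0)

    # missingness: available counts over the 40 variant-level scores
    # (x31 counts as available once computed downstream), so the number
    # masked among the other 39 is 40 - n_available
    lo, hi = cfg.missingness
    n_avail = rng.integers(lo, hi + 1, size=n)
    meanable = np.asarray(MEANABLE_IDX)
    for i in range(n):
        n_missing = 40 - int(n_avail[i])
        if n_missing > 0:
            drop = rng.choice(meanable, size=n_missing, replace=False)
            scores[i, drop] = np.nan

    # gene indispensability with class-linked enrichment: pathogenic
    # variants preferentially land in essential (high-I) genes, benign in
    # mutation-tolerant (low-I) genes
    n_genes = max(cfg.genes, 2)
    gene_names = [f"GENE{g + 1:04d}" for g in range(n_genes)]
    half = n_genes // 2
    gene_I = np.concatenate([rng.beta(1.2, 8, half), rng.beta(8, 1.2, n_genes - half)])
    log_odds = np.log(cfg.indispensability_enrichment) * 2.0 * (u - 0.5)
    p_high = 1.0 / (1.0 + np.exp(-log_odds))
    is_high = rng.random(n) < p_high
    gene_idx = np.where(
        is_high,
        rng.integers(half, n_genes, size=n),
        rng.integers(0, half, size=n),
    )
    scores[:, INDISP_IDX] = gene_I[gene_idx]

    aaf, popmax = _sample_aaf(rng, u_noisy, cfg.aaf_ultrarare_mass, cfg.aaf_anticorrelation)

    chroms = rng.choice(_CHROMS, size=n)
    positions = rng.integers(1, 250_000_000, size=n)
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4

    records = []
    for i in range(n):
        records.append(
            VariantRecord(
                chrom=str(chroms[i]),
                pos=int(positions[i]),
                ref=str(_BASES[ref_i[i]]),
                alt=str(_BASES[alt_i[i]]),
                gene=gene_names[gene_idx[i]],
                scores=scores[i].copy(),
                aaf=float(aaf[i]),
                aaf_popmax=float(popmax[i]),
                clinvar_raw=CODE_TO_NAME[int(codes[i])],
            )
        )
    matrix = records_to_matrix(records)
    return records, matrix, codes.astype(int)


def generate_to_tsv(config: SyntheticConfig, path: str | Path) -> None:
    """Generate and write a fixture TSV (bitwise reproducible per seed)."""
    records, _, _ = generate_dataset(config)
    write_feature_table(records, path)


# ---------------------------------------------------------------------------
# Worked fixture
# ---------------------------------------------------------------------------

#: Constant score level per class in the worked fixture (codes −2…+2).
_WORKED_LEVELS = {-2: 0.9, -1: 0.7, 0: 0.5, 1: 0.3, 2: 0.1}
_WORKED_AAF = {-2: 1e-5, -1: 5e-5, 0: 1e-3, 1: 5e-3, 2: 1e-1}
_WORKED_INDISP = {-2: 0.9, -1: 0.8, 0: 0.5, 1: 0.2, 2: 0.1}


def generate_worked_fixture() -> tuple[list[VariantRecord], FeatureMatrix, np.ndarray]:
    """A frozen 30-row table with hand-checkable values.

    Six rows per class.  Within a class, every available variant-level
    score of row r equals level + 0.01·r (level 0.9 for Pathogenic down to
    0.1 for Benign), so each row's mean score equals its constant by
    inspection.  Row 0 of the Uncertain class has exactly 17 of its 39
    variant-level scores missing — 23 of the 40 variant-level slots
    available, the documented minimum.  Version: v1; any change to these
    values is a breaking change for recorded oracles.
    """
    records: list[VariantRecord] = []
    codes: list[int] = []
    for code in CLASS_CODES:
        level = _WORKED_LEVELS[code]
        for r in range(6):
            scores = np.full(N_FEATURES, np.nan)
            value = round(level + 0.01 * r, 10)
            for j in MEANABLE_IDX:
                scores[j] = value
            if code == 0 and r == 0:
                # drop the last 17 meanable columns -> 23 of 40 available
                for j in MEANABLE_IDX[-17:]:
                    scores[j] = np.nan
            scores[INDISP_IDX] = _WORKED_INDISP[code]
            aaf = _WORKED_AAF[code]
            records.append(
                VariantRecord(
                    chrom=str((len(records) % 22) + 1),
                    pos=1000 + 10 * len(records),
                    ref="A",
                    alt="G" if r % 2 == 0 else "T",
                    gene=f"GENE{code + 3:04d}",
                    scores=scores,
                    aaf=aaf,
                    aaf_popmax=aaf * 2.0,
                    clinvar_raw=CODE_TO_NAME[code],
                )
            )
            codes.append(code)
    matrix = records_to_matrix(records)
    return records, matrix, np.asarray(codes, dtype=int)
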