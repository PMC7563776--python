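"""Feature ranking, importance tables and stratified summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cvep.analysis import (
    aaf_popmax_flag,
    class_histograms,
    gene_class_proportions,
    importance_tables,
    rank_features_single_glm,
    score_means_by_aaf_bins,
    stratify_by_indispensability,
)
from cvep.io_model import CLASS_CODES, CLASS_NAMES, FeatureMatrix, N_FEATURES, VariantRecord
from cvep.learners import BaseLearnerSpec, fit_base
from cvep.preprocess import build_training_design
from cvep.synthetic import SyntheticConfig, generate_dataset

from conftest import FAST_HP
from test_learners import make_design

CODES = np.asarray(CLASS_CODES)


def design_with_features(feature_builder, n=400, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.choice(CODES, size=n)
    X = rng.uniform(0, 1, (n, N_FEATURES))
    feature_builder(X, y, rng)
    return make_design(np.clip(X, 0, 1), y)


class TestRankFeatures:
    def test_planted_perfect_predictor_ranks_first(self):
        def build(X, y, rng):
            X[:, 3] = (2.0 - y) / 4.0  # deterministic monotone recoding

        table = rank_features_single_glm(design_with_features(build))
        assert table.iloc[0]["feature"] == "x4"
        assert table.iloc[0]["pseudo_r2"] > 0.9
        assert sorted(table["rank"]) == list(range(1, N_FEATURES + 1))

    def test_pure_noise_scores_near_zero(self):
        table = rank_features_single_glm(design_with_features(lambda X, y, r: None, n=800))
        assert table["pseudo_r2"].max() < 0.05

    def test_constant_feature_scores_zero_with_warning(self, caplog):
        def build(X, y, rng):
            X[:, 10] = 0.5

        with caplog.at_level("WARNING", logger="cvep"):
            table = rank_features_single_glm(design_with_features(build))
        assert table.set_index("feature").loc["x11", "pseudo_r2"] == 0.0

    def test_signal_strength_ordering_recovered(self):
        # s1 > s2 must give the stronger feature the better rank in a
        # majority of seeds
        hits = 0
        for seed in range(10):
            def build(X, y, rng, seed=seed):
                u = (2.0 - y) / 4.0
                X[:, 0] = 0.8 * u + 0.2 * rng.uniform(0, 1, len(y))
                X[:, 1] = 0.3 * u + 0.7 * rng.uniform(0, 1, len(y))

            table = rank_features_single_glm(
                design_with_features(build, n=300, seed=seed)
            ).set_index("feature")
            if table.loc["x1", "rank"] < table.loc["x2", "rank"]:
                hits += 1
        assert hits >= 9

    def test_invariant_to_row_order(self):
        design = design_with_features(lambda X, y, r: None, n=150)
        t1 = rank_features_single_glm(design)
        perm = np.random.default_rng(0).permutation(design.n)
        shuffled = make_design(design.X[perm], design.y[perm])
        t2 = rank_features_single_glm(shuffled)
        pd.testing.assert_frame_equal(t1, t2)


class TestImportanceTables:
    def test_planted_signal_tops_tree_models(self):
        def build(X, y, rng):
            X[:, 7] = (2.0 - y) / 4.0 + rng.normal(0, 0.05, len(y))

        design = design_with_features(build, n=500)
        models = [
            fit_base(BaseLearnerSpec(k, FAST_HP[k]), design) for k in ("GLM", "GBM", "DRF")
        ]
        tables = importance_tables(models)
        assert set(tables) == {"GLM", "GBM", "DRF"}
        for kind in ("GBM", "DRF"):
            assert tables[kind].iloc[0]["feature"] == "x8"
            assert (tables[kind]["importance"].diff().dropna() <= 0).all()

    def test_mean_column_tops_glm_on_noisy_copies(self):
        # every variant-level score is the same weak signal plus heavy
        # independent noise; their average (x31) cancels the noise, so the
        # linear model leans on the mean column hardest
        _, matrix, codes = generate_dataset(
            SyntheticConfig(n=1500, seed=5, separation=np.full(N_FEATURES, 0.35),
                            correlation=0.0)
        )
        design = build_training_design(matrix, codes, seed=5)
        model = fit_base(BaseLearnerSpec("GLM"), design)
        tables = importance_tables([model])
        assert tables["GLM"].iloc[0]["feature"] == "x31"

    def test_all_noise_importance_stays_flat(self):
        # null calibration: without signal no feature should dominate
        top_counts = 0
        for seed in range(10):
            design = design_with_features(lambda X, y, r: None, n=300, seed=seed)
            model = fit_base(BaseLearnerSpec("DRF", FAST_HP["DRF"], seed=seed), design)
            med = np.median(model.importance)
            if model.importance.max() > 3 * med:
                top_counts += 1
        assert top_counts <= 2


class TestStratifiedSummaries:
    def test_single_class_stratum_is_a_unit_vector(self):
        codes = np.full(20, 2)
        I = np.full(20, 0.1)
        table = stratify_by_indispensability(codes, I)
        row = table.iloc[0]
        assert row["Benign"] == 1.0 and row["Pathogenic"] == 0.0
        assert row["n"] == 20

    def test_proportions_sum_to_one_per_stratum(self, rng):
        codes = rng.choice(CODES, size=300)
        I = rng.uniform(0, 1, 300)
        table = stratify_by_indispensability(codes, I)
        sums = table[list(CLASS_NAMES)].sum(axis=1)
        filled = table["n"] > 0
        np.testing.assert_allclose(sums[filled], 1.0, atol=1e-9)

    def test_benign_enrichment_direction_low_vs_high_indispensability(self):
        _, matrix, codes = generate_dataset(SyntheticConfig(n=3000, seed=2))
        from cvep.io_model import INDISP_IDX

        I = matrix.dense()[:, INDISP_IDX]
        table = stratify_by_indispensability(codes, I).set_index("lo")
        benign_low = table.loc[0.0, "Benign"] + table.loc[0.0, "Likely_benign"]
        benign_high = table.loc[0.95, "Benign"] + table.loc[0.95, "Likely_benign"]
        assert benign_low > benign_high

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            stratify_by_indispensability(
                np.array([0]), np.array([0.5]), ranges=[(0, 0.5), (0.4, 1.0)]
            )

    def test_empty_stratum_emitted_with_missing_proportions(self):
        table = stratify_by_indispensability(
            np.array([0]), np.array([0.1]), ranges=[(0.0, 0.3), (0.95, 1.0)]
        )
        empty = table[table["lo"] == 0.95].iloc[0]
        assert empty["n"] == 0 and np.isnan(empty["Benign"])

    def test_gene_proportions_single_gene(self):
        table = gene_class_proportions(np.array([2, 2, -2]), ["brca1", "BRCA1", "Brca1"])
        assert len(table) == 1
        assert table.iloc[0]["gene"] == "BRCA1"
        assert table.iloc[0]["Benign"] == pytest.approx(2 / 3)

    def test_gene_pathogenic_skew_ordering(self, rng):
        codes = np.concatenate([
            rng.choice(CODES, 200, p=[0.6, 0.2, 0.1, 0.05, 0.05]),  # pathogenic-skewed
            rng.choice(CODES, 200, p=[0.05, 0.05, 0.1, 0.2, 0.6]),  # benign-skewed
        ])
        genes = ["HBB"] * 200 + ["TTN"] * 200
        table = gene_class_proportions(codes, genes).set_index("gene")
        assert table.loc["HBB", "Pathogenic"] > table.loc["TTN", "Pathogenic"]
        sums = table[list(CLASS_NAMES)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestAafSummaries:
    def test_constant_score_means_constant_per_bin(self, rng):
        values = np.full((200, N_FEATURES), 0.5)
        matrix = FeatureMatrix(values, np.zeros_like(values, dtype=bool))
        aaf = 10 ** rng.uniform(-6, 0, 200)
        table = score_means_by_aaf_bins(matrix, aaf)
        filled = table[table["n"] > 0]
        for col in ("x1", "x31", "x40"):
            np.testing.assert_allclose(filled[col], 0.5)
        assert "x41" not in table.columns

    def test_rare_bins_have_higher_means_with_anticorrelation(self):
        _, matrix, _ = generate_dataset(SyntheticConfig(n=4000, seed=9))
        records, matrix, _ = generate_dataset(SyntheticConfig(n=4000, seed=9))
        aaf = np.array([r.aaf for r in records])
        table = score_means_by_aaf_bins(matrix, aaf)
        means = table[table["n"] > 20]["x1"].to_numpy()
        # bins run common -> ultra-rare top to bottom; means must rise
        assert means[-1] > means[0]
        assert np.all(np.diff(means) > -0.05)  # near-monotone trend

    def test_zero_aaf_rows_excluded_with_count(self):
        values = np.full((3, N_FEATURES), 0.5)
        matrix = FeatureMatrix(values, np.zeros_like(values, dtype=bool))
        table = score_means_by_aaf_bins(matrix, np.array([0.0, 1e-3, np.nan]))
        assert table.attrs["n_excluded"] == 2
        assert table["n"].sum() == 1

    def test_empty_bin_reports_missing_mean(self):
        values = np.full((2, N_FEATURES), 0.5)
        matrix = FeatureMatrix(values, np.zeros_like(values, dtype=bool))
        table = score_means_by_aaf_bins(matrix, np.array([0.5, 0.5]))
        empty = table[table["n"] == 0]
        assert len(empty) >= 1 and empty["x1"].isna().all()


class TestAafPopmaxFlag:
    def _record(self, aaf, popmax):
        return VariantRecord(
            chrom="1", pos=1, ref="A", alt="G", gene="X",
            scores=np.full(N_FEATURES, 0.5), aaf=aaf, aaf_popmax=popmax,
        )

    def test_rare_subpopulation_signal(self):
        flags = aaf_popmax_flag([self._record(5e-5, 2e-4)])
        assert flags.iloc[0] == True  # noqa: E712

    def test_common_variant_not_flagged(self):
        # popmax above aaf but the variant is too common (aaf >= 1e-4)
        flags = aaf_popmax_flag([self._record(5e-3, 1e-2)])
        assert flags.iloc[0] == False  # noqa: E712

    def test_equal_frequencies_fail_strict_inequality(self):
        flags = aaf_popmax_flag([self._record(5e-5, 5e-5)])
        assert flags.iloc[0] == False  # noqa: E712

    def test_missing_fields_give_missing_flag(self):
        flags = aaf_popmax_flag([self._record(np.nan, 1e-3)])
        assert flags.isna().iloc[0]


class TestClassHistograms:
    def test_single_class_single_bin_normalizes_to_one(self):
        values = np.full(10, 0.52)
        codes = np.zeros(10, dtype=int)
        table = class_histograms(values, codes)
        assert table["normalized_count"].sum() == pytest.approx(1.0)
        assert table["normalized_count"].max() == pytest.approx(1.0)

    def test_grand_total_normalization(self, rng):
        values = rng.uniform(0, 1, 500)
        codes = rng.choice(CODES, 500)
        table = class_histograms(values, codes)
        assert table["normalized_count"].sum() == pytest.approx(1.0)
        assert len(table) == 5 * 20

    def test_modal_bins_ordered_by_class_pathogenicity(self):
        _, matrix, codes = generate_dataset(
            SyntheticConfig(n=4000, seed=1, separation=np.full(N_FEATURES, 0.9),
                            class_noise=0.02)
        )
        table = class_histograms(matrix.dense()[:, 0], codes)
        modes = {}
        for code in CLASS_CODES:
            sub = table[table["code"] == code]
            modes[code] = sub.loc[sub["normalized_count"].idxmax(), "bin_lo"]
        # pathogenic classes peak in higher score bins than benign ones
        assert modes[-2] > modes[0] > modes[2]

    def test_aaf_histogram_uses_log_bins(self, rng):
        aaf = 10 ** rng.uniform(-6, 0, 300)
        codes = rng.choice(CODES, 300)
        table = class_histograms(aaf, codes, feature="AAF")
        assert len(table) == 5 * 24
        assert table["bin_lo"].min() == pytest.approx(-6.0)
        assert table["normalized_count"].sum() == pytest.approx(1.0)
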