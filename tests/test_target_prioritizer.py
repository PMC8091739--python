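import numpy as np
import pandas as pd
import pytest

from pin2target.embedding import LatentFeatureMatrix
from pin2target.target_prioritizer import (
    SMALL_GRID,
    GridConfig,
    LabeledDataset,
    build_datasets,
    fit_ensemble,
    fit_one_dataset,
    score_genes,
    select_putative,
    smote_oversample,
    write_scores,
)

TINY_GRID = GridConfig(
    learning_rate=(0.1,), max_depth=(2,), n_estimators=30,
    gamma=(0.0,), reg_lambda=(0.0,), reg_alpha=(0.0,),
)


def _features(n_genes, d, seed=0, shift_positives=None, n_positives=0):
    """Random feature matrix; optionally shifts the first n_positives rows
    to make the classes separable."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n_genes, d))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    positives = set(genes[:n_positives])
    if shift_positives is not None:
        values[:n_positives, 0] += shift_positives
    return LatentFeatureMatrix(values, genes, []), positives


class TestGridConfig:
    def test_paper_grid_values(self):
        g = GridConfig()
        assert g.learning_rate == (0.01, 0.1, 0.5)
        assert g.max_depth == (1, 2, 3, 5, 10)
        assert g.n_estimators == 100
        assert g.gamma == (0.0, 0.3)
        assert g.reg_lambda == (0.0, 0.1, 1.0)
        assert g.reg_alpha == (0.0, 0.1, 1.0)
        assert g.cv_folds == 5

    def test_effective_points_deduplicate_reg_lambda(self):
        # 3*5*2*3*3 = 270 raw combinations; reg_lambda has no backend
        # equivalent so the effective grid collapses to 90
        points = list(GridConfig().iter_points())
        assert len(points) == 90
        assert len({tuple(sorted(p.items())) for p in points}) == 90

    def test_iteration_order_learning_rate_outermost(self):
        points = list(GridConfig().iter_points())
        assert points[0]["learning_rate"] == 0.01
        assert points[-1]["learning_rate"] == 0.5

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            GridConfig(cv_folds=1)


class TestBuildDatasets:
    def test_construction_contract(self):
        latent, positives = _features(40, 4, n_positives=10)
        datasets = build_datasets(latent, positives, n_datasets=3, n_negatives=30)
        assert len(datasets) == 3
        for ds in datasets:
            assert len(ds.labels) == 40
            assert ds.labels.sum() == 10
            assert {g for g, y in zip(ds.genes, ds.labels) if y == 1} == positives
            assert not ds.synthetic.any()

    def test_negative_exhaustion_identical_datasets(self):
        latent, positives = _features(20, 3, n_positives=5)
        datasets = build_datasets(latent, positives, n_datasets=2, n_negatives=15)
        assert datasets[0].genes == datasets[1].genes

    def test_too_many_negatives_rejected(self):
        latent, positives = _features(20, 3, n_positives=5)
        with pytest.raises(ValueError):
            build_datasets(latent, positives, n_datasets=1, n_negatives=16)

    def test_negatives_sampled_without_replacement(self):
        latent, positives = _features(50, 3, n_positives=5)
        (ds,) = build_datasets(latent, positives, n_datasets=1, n_negatives=40)
        negs = [g for g, y in zip(ds.genes, ds.labels) if y == 0]
        assert len(negs) == len(set(negs)) == 40

    def test_independent_across_datasets(self):
        latent, positives = _features(200, 3, n_positives=5)
        d1, d2 = build_datasets(latent, positives, n_datasets=2, n_negatives=50)
        assert d1.genes != d2.genes


class TestSmote:
    def test_collinearity_two_points(self):
        minority = np.array([[0.0, 0.0], [2.0, 2.0]])
        synth = smote_oversample(minority, k=1, n_synthetic=50, seed=0)
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert (synth >= 0).all() and (synth <= 2).all()

    def test_identical_rows_degenerate(self):
        minority = np.tile([1.5, -2.0, 3.0], (5, 1))
        synth = smote_oversample(minority, k=2, n_synthetic=10, seed=1)
        assert np.allclose(synth, minority[0])

    def test_bounding_box_31_rows_d100(self):
        rng = np.random.default_rng(7)
        minority = rng.normal(size=(31, 100))
        synth = smote_oversample(minority, k=2, n_synthetic=469, seed=7)
        assert synth.shape == (469, 100)
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            smote_oversample(np.array([[1.0, 2.0]]), k=1, n_synthetic=5)

    def test_determinism(self):
        minority = np.random.default_rng(3).normal(size=(10, 4))
        a = smote_oversample(minority, k=2, n_synthetic=20, seed=9)
        b = smote_oversample(minority, k=2, n_synthetic=20, seed=9)
        assert np.array_equal(a, b)

    def test_k_capped_at_minority_minus_one(self):
        minority = np.random.default_rng(4).normal(size=(3, 2))
        synth = smote_oversample(minority, k=10, n_synthetic=5, seed=0)
        assert synth.shape == (5, 2)


def _dataset(latent, positives, n_negatives, seed=0):
    (ds,) = build_datasets(latent, positives, n_datasets=1,
                           n_negatives=n_negatives, seed=seed)
    return ds


class TestFitOneDataset:
    def test_separable_auc_one(self):
        latent, positives = _features(80, 4, shift_positives=10.0, n_positives=15)
        fit = fit_one_dataset(_dataset(latent, positives, 60), TINY_GRID, seed=0)
        assert fit.cv_auc == pytest.approx(1.0)

    def test_null_auc_near_half(self):
        aucs = []
        for seed in range(10):
            latent, positives = _features(70, 4, seed=seed, n_positives=15)
            fit = fit_one_dataset(_dataset(latent, positives, 50, seed), TINY_GRID,
                                  seed=seed)
            aucs.append(fit.cv_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_leakage_audit_all_zero(self):
        latent, positives = _features(60, 4, n_positives=12)
        fit = fit_one_dataset(_dataset(latent, positives, 48), SMALL_GRID, seed=1)
        assert fit.leakage_audit == [0] * 5

    def test_single_class_rejected(self):
        latent, _ = _features(20, 3)
        ds = LabeledDataset(0, latent.values, np.zeros(20, dtype=int),
                            latent.genes, np.zeros(20, dtype=bool))
        with pytest.raises(ValueError):
            fit_one_dataset(ds, TINY_GRID)

    def test_best_params_from_grid(self):
        latent, positives = _features(60, 4, shift_positives=5.0, n_positives=12)
        fit = fit_one_dataset(_dataset(latent, positives, 40), SMALL_GRID, seed=2)
        assert fit.best_params["learning_rate"] == 0.1
        assert fit.best_params["max_depth"] in (2, 3)


class TestFitEnsemble:
    def test_separable_mean_auc_one(self):
        latent, positives = _features(80, 4, shift_positives=10.0, n_positives=15)
        datasets = build_datasets(latent, positives, n_datasets=3, n_negatives=60)
        ens = fit_ensemble(datasets, TINY_GRID, seed=0)
        assert ens.mean_cv_auc == pytest.approx(1.0)
        assert ens.n_models == 3

    def test_determinism_of_choices(self):
        latent, positives = _features(60, 4, n_positives=12, seed=5)
        datasets = build_datasets(latent, positives, n_datasets=2, n_negatives=40)
        e1 = fit_ensemble(datasets, SMALL_GRID, seed=4)
        e2 = fit_ensemble(datasets, SMALL_GRID, seed=4)
        assert [f.best_params for f in e1.fits] == [f.best_params for f in e2.fits]
        assert [f.cv_auc for f in e1.fits] == [f.cv_auc for f in e2.fits]

    def test_empty_dataset_list_rejected(self):
        with pytest.raises(ValueError):
            fit_ensemble([], TINY_GRID)

    def test_planted_signal_recovery(self, planted_pin):
        # adjacency rows as features: cohesion signal should be learnable
        graph, positives, adj, _ = planted_pin
        latent = LatentFeatureMatrix(adj.entries.astype(float), adj.node_order, [])
        aucs = []
        for seed in range(3):
            datasets = build_datasets(latent, positives, n_datasets=2,
                                      n_negatives=150, seed=seed)
            aucs.append(fit_ensemble(datasets, TINY_GRID, seed=seed).mean_cv_auc)
        assert np.mean(aucs) > 0.75

    def test_cv_report_shape(self):
        latent, positives = _features(60, 4, n_positives=12)
        datasets = build_datasets(latent, positives, n_datasets=2, n_negatives=40)
        report = fit_ensemble(datasets, TINY_GRID, seed=0).cv_report()
        assert list(report["dataset"]) == [0, 1]
        assert "cv_auc" in report.columns


class TestScoreGenes:
    def test_positives_excluded_and_sorted(self):
        latent, positives = _features(50, 4, shift_positives=8.0, n_positives=10)
        datasets = build_datasets(latent, positives, n_datasets=2, n_negatives=40)
        ens = fit_ensemble(datasets, TINY_GRID, seed=0)
        scores = score_genes(ens, latent, positives)
        assert len(scores) == 40
        assert positives.isdisjoint(scores.index)
        assert (scores.to_numpy()[:-1] >= scores.to_numpy()[1:]).all()
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_single_model_mean_is_probability(self):
        latent, positives = _features(40, 3, shift_positives=6.0, n_positives=8)
        datasets = build_datasets(latent, positives, n_datasets=1, n_negatives=32)
        ens = fit_ensemble(datasets, TINY_GRID, seed=0)
        scores = score_genes(ens, latent, positives)
        gene = scores.index[0]
        row = latent.values[latent.genes.index(gene)][None, :]
        expected = ens.fits[0].model.predict_proba(row)[0, 1]
        assert scores[gene] == pytest.approx(expected)

    def test_held_out_positives_rank_high(self, planted_pin):
        graph, positives, adj, _ = planted_pin
        latent = LatentFeatureMatrix(adj.entries.astype(float), adj.node_order, [])
        ranks = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            pos_list = sorted(positives)
            train_pos = set(rng.choice(pos_list, size=18, replace=False))
            held_out = positives - train_pos
            datasets = build_datasets(latent, train_pos, n_datasets=2,
                                      n_negatives=150, seed=seed)
            ens = fit_ensemble(datasets, TINY_GRID, seed=seed)
            scores = score_genes(ens, latent, train_pos)
            rank = pd.Series(range(1, len(scores) + 1), index=scores.index)
            ranks.append(rank[sorted(held_out)].median() / len(scores))
        assert np.median(ranks) < 0.25

    def test_write_scores_format(self, tmp_path):
        scores = pd.Series([0.9, 0.1], index=["a", "b"], name="mean_probability")
        out = tmp_path / "scores.tsv"
        write_scores(scores.rename_axis("gene"), out)
        frame = pd.read_csv(out, sep="\t")
        assert list(frame.columns) == ["gene", "mean_probability"]


class TestSelectPutative:
    def test_strict_threshold(self):
        scores = pd.Series({"a": 0.76, "b": 0.75, "c": 0.2})
        putative = select_putative(scores, threshold=0.75)
        assert putative.as_set() == {"a"}

    def test_all_below_threshold_empty(self):
        scores = pd.Series({"a": 0.5, "b": 0.2})
        assert len(select_putative(scores, 0.75)) == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.random(100),
                           index=[f"g{i}" for i in range(100)])
        sizes = [len(select_putative(scores, t)) for t in (0.1, 0.5, 0.75, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            select_putative(pd.Series({"a": 1.2}))

    def test_null_putative_near_empty(self):
        # random features: almost nothing should clear 0.75
        latent, positives = _features(80, 4, seed=9, n_positives=15)
        datasets = build_datasets(latent, positives, n_datasets=2, n_negatives=60)
        ens = fit_ensemble(datasets, TINY_GRID, seed=9)
        scores = score_genes(ens, latent, positives)
        assert len(select_putative(scores, 0.75)) <= 5
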