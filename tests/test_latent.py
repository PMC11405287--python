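import numpy as np
import pytest
from scipy.stats import poisson

from scatlas.features import FeaturePanel, rank_markers_wilcoxon, select_feature_genes
from scatlas.latent import (
    HyperparamGrid,
    LatentClassifier,
    LatentModelConfig,
    fit_latent_model,
    hyperparameter_search,
    logistic_transfer,
    nb_log_likelihood,
)
from scatlas.synth import SynthConfig, default_tree, simulate_atlas

FAST = dict(latent_dim=10, hidden_dim=32, max_epochs=25)


@pytest.fixture(scope="module")
def four_type_atlas():
    """Disjoint 20-gene markers at 8-fold, 200 cells/type."""
    cfg = SynthConfig(tree=default_tree(4, 1), n_cells_per_subtype=200,
                      n_genes=500, markers_per_type=20, seed=0)
    return simulate_atlas(cfg)


@pytest.fixture(scope="module")
def trained(four_type_atlas):
    ds, _ = four_type_atlas
    mt = rank_markers_wilcoxon(ds, ds.level1)
    panel = select_feature_genes(mt, 50)
    model = LatentClassifier(LatentModelConfig(seed=0)).fit(ds, ds.level1, panel)
    return ds, panel, model


class TestNBLikelihood:
    def test_theta_limit_recovers_poisson(self):
        # 1-gene toy: huge inverse dispersion -> Poisson log pmf
        x = np.arange(0, 30, dtype=float)
        mean = 6.5
        nb = nb_log_likelihood(x, mean, 1e8)
        np.testing.assert_allclose(nb, poisson.logpmf(x, mean), atol=1e-5)

    def test_matches_scipy_nbinom(self):
        from scipy.stats import nbinom

        x = np.array([0.0, 1, 4, 9])
        mean, theta = 3.0, 2.0
        # scipy parameterization: n=theta, p=theta/(theta+mean)
        np.testing.assert_allclose(
            nb_log_likelihood(x, mean, theta),
            nbinom.logpmf(x, theta, theta / (theta + mean)),
            rtol=1e-10,
        )


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        model = LatentClassifier(
            LatentModelConfig(latent_dim=3, n_layers=2, hidden_dim=6, seed=0)
        )
        model.panel = FeaturePanel([f"g{i}" for i in range(12)])
        model.labels_vocab = ["A", "B"]
        model.batch_vocab = ["s0", "s1"]
        model.params = model._init_params(12, 12, 2, rng)
        X = rng.poisson(4.0, size=(6, 12)).astype(float)
        lib = X.sum(1)
        bat = np.zeros((6, 2))
        bat[np.arange(6), rng.integers(0, 2, 6)] = 1
        y = np.zeros((6, 2))
        y[np.arange(6), rng.integers(0, 2, 6)] = 1
        labeled = np.array([True, True, True, False, True, True])
        eps = rng.standard_normal((6, 3))
        _, grads, _ = model._loss_and_grads(X, lib, bat, y, labeled, eps, 5.0)
        for name, g in grads.items():
            p = model.params[name]
            for _ in range(4):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                h, orig = 1e-5, p[idx]
                p[idx] = orig + h
                lp, _, _ = model._loss_and_grads(X, lib, bat, y, labeled, eps, 5.0)
                p[idx] = orig - h
                lm, _, _ = model._loss_and_grads(X, lib, bat, y, labeled, eps, 5.0)
                p[idx] = orig
                num = (lp - lm) / (2 * h)
                assert num == pytest.approx(g[idx], rel=1e-3, abs=1e-6), name


class TestFit:
    def test_heldout_accuracy_on_separable_atlas(self, trained):
        ds, _, model = trained
        val_idx = model.validation_indices
        pred, _ = model.classify(ds.subset_cells(val_idx))
        truth = ds.level1[val_idx].astype(str)
        assert (pred == truth).mean() >= 0.95

    def test_single_class_labels_rejected(self, four_type_atlas):
        ds, _ = four_type_atlas
        panel = FeaturePanel(list(ds.gene_ids[:30]))
        with pytest.raises(ValueError, match="two label classes"):
            fit_latent_model(ds, ["A"] * ds.n_cells, panel)

    def test_phase1_elbo_nondecreasing(self, trained):
        _, _, model = trained
        elbo = np.asarray(model.history["elbo_unsup"])
        assert len(elbo) == model.config.unsup_epochs
        # allow 1% relative slack for minibatch noise
        assert (np.diff(elbo) >= -0.01 * np.abs(elbo[:-1])).all()

    def test_early_stop_restores_best_state(self, trained):
        ds, _, model = trained
        acc = np.asarray(model.history["val_accuracy"])
        best_epoch = int(acc.argmax())
        # halted within patience epochs of the best epoch
        assert len(acc) - 1 - best_epoch <= model.config.early_stop_patience
        # restored parameters reproduce the best recorded accuracy
        val_idx = model.validation_indices
        pred, _ = model.classify(ds.subset_cells(val_idx))
        recomputed = (pred == ds.level1[val_idx].astype(str)).mean()
        assert recomputed == pytest.approx(model.best_val_accuracy, abs=1e-12)

    def test_seeded_reproducibility_bitwise(self, four_type_atlas):
        ds, _ = four_type_atlas
        panel = FeaturePanel(list(ds.gene_ids[:60]))
        cfg = LatentModelConfig(seed=11, **FAST)
        a = fit_latent_model(ds, ds.level1, panel, cfg)
        b = fit_latent_model(ds, ds.level1, panel, cfg)
        la, _ = a.classify(ds)
        lb, _ = b.classify(ds)
        assert (la == lb).all()
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])


class TestEncodeClassify:
    def test_identical_cells_identical_embeddings(self, trained):
        from .conftest import make_dataset

        ds, _, model = trained
        row = ds.counts[0].toarray()
        dup = make_dataset(np.vstack([row, row, row]), gene_ids=ds.gene_ids)
        z = model.encode(dup)
        assert z.shape == (3, model.config.latent_dim)
        np.testing.assert_array_equal(z[0], z[1])
        np.testing.assert_array_equal(z[1], z[2])

    def test_between_type_separation_exceeds_within(self, trained):
        ds, _, model = trained
        z = model.encode(ds)
        labels = ds.level1.astype(str)
        types = sorted(set(labels))[:2]
        za, zb = z[labels == types[0]], z[labels == types[1]]
        centroid_dist = np.linalg.norm(za.mean(0) - zb.mean(0))
        within = np.linalg.norm(za - za.mean(0), axis=1).mean()
        assert centroid_dist > within

    def test_probabilities_sum_to_one(self, trained):
        ds, _, model = trained
        _, probs = model.classify(ds.subset_cells(np.arange(50)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_classification_invariant_to_cell_order(self, trained):
        ds, _, model = trained
        rng = np.random.default_rng(4)
        perm = rng.permutation(ds.n_cells)
        labels, _ = model.classify(ds)
        labels_perm, _ = model.classify(ds.subset_cells(perm))
        assert (labels[perm] == labels_perm).all()

    def test_missing_panel_genes_zero_filled(self, trained):
        ds, panel, model = trained
        keep = [g for g in ds.gene_ids if g not in set(panel.genes[:5])]
        z = model.encode(ds.subset_genes(keep))
        assert z.shape == (ds.n_cells, model.config.latent_dim)

    def test_save_load_roundtrip(self, trained, tmp_path):
        ds, _, model = trained
        model.save(tmp_path / "m")
        back = LatentClassifier.load(tmp_path / "m")
        la, pa = model.classify(ds)
        lb, pb = back.classify(ds)
        assert (la == lb).all()
        np.testing.assert_array_equal(pa, pb)


class TestHyperparameterSearch:
    def test_singleton_grid_equals_direct_fit(self, four_type_atlas):
        ds, _ = four_type_atlas
        panel = FeaturePanel(list(ds.gene_ids[:60]))
        base = LatentModelConfig(seed=2, **FAST)
        grid = HyperparamGrid(latent_dims=(10,), n_layers=(2,), seeds=(2,))
        best = hyperparameter_search(ds, ds.level1, panel, grid, base)
        direct = fit_latent_model(ds, ds.level1, panel, base)
        assert best.best_val_accuracy == direct.best_val_accuracy
        for k in best.params:
            np.testing.assert_array_equal(best.params[k], direct.params[k])

    def test_returns_maximal_validation_accuracy(self, four_type_atlas):
        ds, _ = four_type_atlas
        panel = FeaturePanel(list(ds.gene_ids[:60]))
        base = LatentModelConfig(seed=2, hidden_dim=32, max_epochs=12)
        grid = HyperparamGrid(latent_dims=(2, 10), n_layers=(1,), seeds=(2,))
        best = hyperparameter_search(ds, ds.level1, panel, grid, base)
        for D in (2, 10):
            cfg = LatentModelConfig(seed=2, hidden_dim=32, max_epochs=12,
                                    latent_dim=D, n_layers=1)
            other = fit_latent_model(ds, ds.level1, panel, cfg)
            assert best.best_val_accuracy >= other.best_val_accuracy

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            HyperparamGrid(latent_dims=())


class TestLogisticTransfer:
    def test_memorizes_separable_reference(self):
        rng = np.random.default_rng(0)
        z = np.vstack([rng.normal(-3, 0.3, (40, 2)), rng.normal(3, 0.3, (40, 2))])
        labels = np.array(["A"] * 40 + ["B"] * 40)
        pred, probs = logistic_transfer(z, labels, z)
        assert (pred == labels).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_two_gaussians_high_accuracy(self):
        rng = np.random.default_rng(0)
        ref = np.vstack([rng.normal(-5, 1, (500, 2)), rng.normal(5, 1, (500, 2))])
        ref_labels = np.array(["neg"] * 500 + ["pos"] * 500)
        query = np.vstack([rng.normal(-5, 1, (500, 2)), rng.normal(5, 1, (500, 2))])
        truth = np.array(["neg"] * 500 + ["pos"] * 500)
        pred, _ = logistic_transfer(ref, ref_labels, query)
        assert (pred == truth).mean() >= 0.99

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            logistic_transfer(np.zeros((4, 3)), ["a", "a", "b", "b"], np.zeros((2, 2)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two reference classes"):
            logistic_transfer(np.zeros((4, 2)), ["a"] * 4, np.zeros((2, 2)))
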