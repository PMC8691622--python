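"""L1 logistic edge/surface decoder: printed conventions, training, curves."""

import numpy as np
import pytest

from gammasf import decoder as dec
from gammasf import synthetic as syn


def toy_dataset(n=200, d=3.0, n_sites=1, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    y = np.concatenate([np.ones(half), np.zeros(half)])
    X = rng.standard_normal((n, 3 * n_sites))
    X[: half, 0] += d
    return dec.DecodeDataset(X=X, y=y)


class TestPredict:
    def test_zero_model_boundary(self):
        model = dec.DecoderModel(W=np.zeros(3), w0=0.0, lam=0.0)
        X = np.ones((4, 3))
        assert np.all(dec.predict(model, X) == 0.5)
        assert np.all(dec.classify(model, X) == 1.0)  # p >= 0.5 -> edge

    def test_printed_sign_convention(self):
        # X.W + w0 = -ln 3  ->  p = 1/(1 + e^{-ln 3}) = 0.75
        model = dec.DecoderModel(W=np.array([1.0, 0.0, 0.0]), w0=0.0, lam=0.0)
        p = dec.predict(model, np.array([[-np.log(3.0), 0.0, 0.0]]))
        assert p[0] == pytest.approx(0.75)

    def test_saturation_toward_surface(self):
        model = dec.DecoderModel(W=np.array([1.0, 0.0, 0.0]), w0=0.0, lam=0.0)
        p = dec.predict(model, np.array([[1e6, 0.0, 0.0]]))
        assert p[0] < 1e-10  # huge positive score -> surface

    def test_dimension_mismatch(self):
        model = dec.DecoderModel(W=np.zeros(3), w0=0.0, lam=0.0)
        with pytest.raises(ValueError):
            dec.predict(model, np.ones((2, 6)))

    def test_equivalent_to_conventional_logistic_with_flipped_weights(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(3)
        X = rng.standard_normal((50, 3))
        model = dec.DecoderModel(W=w, w0=0.3, lam=0.0)
        conventional = 1.0 / (1.0 + np.exp(-(X @ (-w) + (-0.3))))
        np.testing.assert_allclose(dec.predict(model, X), conventional, atol=1e-12)


class TestLoss:
    def test_chance_closed_form(self):
        model = dec.DecoderModel(W=np.zeros(3), w0=0.0, lam=1.0)
        X = np.random.default_rng(0).standard_normal((40, 3))
        y = np.tile([0.0, 1.0], 20)
        assert dec.loss(model, X, y) == pytest.approx(np.log(2.0))

    def test_penalty_linearity(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 3))
        y = np.tile([0.0, 1.0], 20)
        model = dec.DecoderModel(W=np.array([1.0, -2.0, 0.5]), w0=0.1, lam=0.0)
        base = dec.loss(model, X, y, lam=0.0)
        l1 = dec.loss(model, X, y, lam=1.0) - base
        l2 = dec.loss(model, X, y, lam=2.0) - base
        assert l2 == pytest.approx(2 * l1)
        assert l1 == pytest.approx(3.5 / (2 * 40))

    def test_confident_correct_predictions(self):
        model = dec.DecoderModel(W=np.array([-50.0, 0.0, 0.0]), w0=0.0, lam=0.0)
        X = np.zeros((10, 3))
        X[:5, 0] = 1.0  # edge trials get very negative score -> p ~ 1
        X[5:, 0] = -1.0
        y = np.array([1.0] * 5 + [0.0] * 5)
        assert dec.loss(model, X, y) < 1e-8


class TestTrain:
    def test_separable_accuracy(self):
        model = dec.train(toy_dataset(n=400, d=6.0), lam=0.01, seed=0)
        assert model.test_accuracy >= 0.95

    def test_heavy_shrinkage_limit(self):
        model = dec.train(toy_dataset(n=400, d=0.3), lam=1e5, seed=0, standardize=False)
        assert np.all(np.abs(model.W) < 1e-3)

    def test_solution_no_worse_than_zero_model(self):
        ds = toy_dataset(n=300, d=1.0)
        model = dec.train(ds, lam=0.5, seed=1)
        zero = dec.DecoderModel(
            W=np.zeros(3), w0=0.0, lam=0.5,
            feature_mean=model.feature_mean, feature_sd=model.feature_sd,
        )
        idx = model.split["train"]
        assert dec.loss(model, ds.X[idx], ds.y[idx]) <= dec.loss(zero, ds.X[idx], ds.y[idx]) + 1e-8

    def test_shrinkage_monotone_in_lambda(self):
        ds = toy_dataset(n=300, d=1.5, n_sites=2, seed=3)
        norms = []
        for lam in np.geomspace(0.001, 40.0, 8):
            model = dec.train(ds, lam=lam, seed=0)
            norms.append(np.sum(np.abs(model.W)))
        assert all(a >= b - 1e-6 for a, b in zip(norms, norms[1:]))

    def test_grid_selection_records_lambda(self):
        ds = toy_dataset(n=300, d=2.0)
        model = dec.train(ds, seed=0)
        assert model.lam in dec.DEFAULT_LAMBDA_GRID
        assert model.val_mse is not None

    def test_brute_force_grid_equivalence(self):
        # 2-feature toy: padded to one 3-feature site with an empty column
        rng = np.random.default_rng(5)
        X = np.zeros((40, 3))
        y = np.tile([1.0, 0.0], 20)
        X[:, 0] = rng.standard_normal(40) - (2 * y - 1) * 1.0
        X[:, 1] = rng.standard_normal(40)
        ds = dec.DecodeDataset(X=X, y=y)
        lam = 0.5
        model = dec.train(ds, lam=lam, seed=0, standardize=False, split=(0.6, 0.15, 0.25))
        idx = model.split["train"]
        Xs, ys = X[idx], y[idx]

        def objective(u, v, b, w_dead=0.0):
            m = len(ys)
            s = np.clip(Xs @ np.array([u, v, w_dead]) + b, -30, 30)
            p = np.clip(1.0 / (1.0 + np.exp(s)), 1e-12, 1 - 1e-12)
            nll = -np.mean(ys * np.log(p) + (1 - ys) * np.log(1 - p))
            return nll + lam / (2 * m) * (abs(u) + abs(v) + abs(w_dead))

        # nested zooming grid over (u, v, b); the dead third column's weight
        # is 0 at any optimum (it is all-zero data but penalized)
        best = (0.0, 0.0, 0.0)
        span = 4.0
        for _ in range(6):
            us = np.linspace(best[0] - span, best[0] + span, 21)
            vs = np.linspace(best[1] - span, best[1] + span, 21)
            bs = np.linspace(best[2] - span, best[2] + span, 21)
            vals = np.array([[[objective(u, v, b) for b in bs] for v in vs] for u in us])
            i, j, kk = np.unravel_index(np.argmin(vals), vals.shape)
            best = (us[i], vs[j], bs[kk])
            span /= 4.0
        grid_obj = objective(*best)
        ours = objective(model.W[0], model.W[1], model.w0, model.W[2])
        assert abs(ours - grid_obj) < 1e-3

    def test_split_requirements(self):
        with pytest.raises(ValueError):
            dec.train(toy_dataset(n=30), lam=0.1)


class TestAccuracyCurves:
    def test_no_signal_flat_at_chance(self, gt3):
        gt = syn.GroundTruth(
            model_params=gt3.model_params,
            edge_surface_effects={
                "gamma_diff": {"LG": 0.0, "MG": 0.0, "HG": 0.0},
                "gamma_sd": 1.0, "mua_diff": 0.0, "mua_sd": 5.0, "mua_base_rate": 20.0,
            },
        )
        ga, _ = syn.simulate_edge_surface(gt, n_sites=4, n_trials=1000, seed=0)
        curve = dec.accuracy_vs_nsites(ga, counts=[1, 4], repeats=4, lam=0.1, seed=0)
        for mean, _ in curve.values():
            assert mean == pytest.approx(0.5, abs=0.07)

    def test_deterministic(self, gt3):
        ga, _ = syn.simulate_edge_surface(gt3, n_sites=4, n_trials=400, seed=1)
        a = dec.accuracy_vs_nsites(ga, counts=[1, 2], repeats=3, seed=5)
        b = dec.accuracy_vs_nsites(ga, counts=[1, 2], repeats=3, seed=5)
        assert a == b

    def test_count_exceeding_pool(self, gt3):
        ga, _ = syn.simulate_edge_surface(gt3, n_sites=2, n_trials=200, seed=1)
        with pytest.raises(ValueError):
            dec.accuracy_vs_nsites(ga, counts=[3], repeats=2)


class TestDatasetValidation:
    def test_contracts(self):
        with pytest.raises(ValueError):
            dec.DecodeDataset(X=np.ones((4, 4)), y=np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError):
            dec.DecodeDataset(X=np.ones((4, 3)), y=np.array([0, 1, 2, 1]))
        with pytest.raises(ValueError):
            dec.DecodeDataset(X=np.full((4, 3), np.nan), y=np.array([0, 1, 0, 1]))
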