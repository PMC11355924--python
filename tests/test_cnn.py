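"""Normalization, splitting, architecture, training and evaluation of the
numpy CNN regressor."""

import numpy as np
import pytest
from scipy import stats

from osteocurv.cnn import (ArchitectureError, CNNConfig, TABLE_CONFIGS,
                           TargetNormalizer, build_model, evaluate,
                           minmax_normalize, split_dataset, train)


class TestMinMaxNormalize:
    def test_simple_values(self):
        out, norm = minmax_normalize(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])
        assert norm.transform(np.array([[2.0]]))[0, 0] == 0.0

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(100, 3)) * 50
        out, norm = minmax_normalize(vals)
        np.testing.assert_allclose(norm.inverse(out), vals, atol=1e-12)

    def test_constant_target_raises_with_name(self):
        vals = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="tbth"):
            minmax_normalize(vals, names=("bvtv", "tbth"))

    def test_no_leakage_from_test_split(self):
        train_vals = np.array([[0.0], [1.0]])
        _, norm = minmax_normalize(train_vals)
        # wildly out-of-range test values do not affect the statistics
        out = norm.transform(np.array([[10.0]]))
        assert out[0, 0] == 10.0
        assert norm.minima[0] == 0.0 and norm.maxima[0] == 1.0


class TestSplitDataset:
    def test_80_20_disjoint_exhaustive(self):
        tr, te = split_dataset(10, 0.8, seed=0)
        assert len(tr) == 8 and len(te) == 2
        assert set(tr) | set(te) == set(range(10))
        assert not set(tr) & set(te)

    def test_same_seed_identical(self):
        assert all(np.array_equal(a, b) for a, b in
                   zip(split_dataset(50, 0.8, 3), split_dataset(50, 0.8, 3)))

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.5])
    def test_invalid_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            split_dataset(10, frac, 0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(4, 0.8, 0)


class TestBuildModel:
    def test_histomorphometric_variant_structure(self):
        cfg = TABLE_CONFIGS["histomorphometric"]
        assert cfg.conv_filters == (8, 16, 32)
        assert cfg.kernel_size == 3 and cfg.pool_size == 2
        assert cfg.hidden_widths == (128, 64) and cfg.n_outputs == 6
        assert cfg.dropout_rate == 0.3 and cfg.n_epochs == 200
        assert cfg.learning_rate == 1e-4
        model = build_model(cfg, (64, 64))
        from osteocurv.cnn import _Conv2D, _Dense
        convs = [l for l in model.layers if isinstance(l, _Conv2D)]
        assert [c.W.shape[0] for c in convs] == [8, 16, 32]
        denses = [l for l in model.layers if isinstance(l, _Dense)]
        assert [d.W.shape[1] for d in denses] == [128, 64, 6]

    def test_stiffness_variant(self):
        cfg = TABLE_CONFIGS["stiffness"]
        assert cfg.conv_filters == (16, 32, 64)
        assert cfg.n_outputs == 9 and cfg.dropout_rate == 0.5
        assert cfg.n_epochs == 250
        model = build_model(cfg, (64, 64))
        assert model.forward(np.zeros((2, 4, 64, 64))).shape == (2, 9)

    def test_pool_stack_exceeding_input_raises(self):
        with pytest.raises(ArchitectureError):
            build_model(CNNConfig(conv_filters=(4, 4, 4, 4, 4)), (16, 16))

    def test_seeded_init_is_reproducible(self):
        a = build_model(CNNConfig(seed=7), (32, 32))
        b = build_model(CNNConfig(seed=7), (32, 32))
        for pa, pb in zip(a.parameters, b.parameters):
            np.testing.assert_array_equal(pa, pb)


def _toy_problem(n=60, res=16, seed=0):
    """Images whose center brightness encodes the target: easy to learn."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 1, size=(n, 2))
    X = rng.normal(0, 0.05, size=(n, 4, res, res))
    X[:, 0, 4:12, 4:12] += t[:, 0, None, None]
    X[:, 1, 4:12, 4:12] += t[:, 1, None, None]
    return X, t


class TestTrain:
    def test_loss_decreases_on_learnable_problem(self):
        X, t = _toy_problem()
        cfg = CNNConfig(conv_filters=(4, 8), hidden_widths=(16,),
                        n_outputs=2, dropout_rate=0.0, n_epochs=25,
                        learning_rate=1e-3, seed=1)
        model = build_model(cfg, X.shape[2:])
        hist = train(model, X, t, cfg)
        assert hist[-1] < hist[0]
        # smoothed early vs late trend
        assert np.mean(hist[-5:]) < np.mean(hist[:5])

    def test_zero_epochs_returns_initial_model(self):
        X, t = _toy_problem(n=10)
        cfg = CNNConfig(conv_filters=(4,), hidden_widths=(8,), n_outputs=2,
                        n_epochs=0, seed=0)
        model = build_model(cfg, X.shape[2:])
        before = [p.copy() for p in model.parameters]
        hist = train(model, X, t, cfg)
        assert hist == []
        for p0, p1 in zip(before, model.parameters):
            np.testing.assert_array_equal(p0, p1)

    def test_zero_learning_rate_keeps_loss_constant(self):
        X, t = _toy_problem(n=12)
        cfg = CNNConfig(conv_filters=(4,), hidden_widths=(8,), n_outputs=2,
                        n_epochs=4, learning_rate=0.0, dropout_rate=0.0,
                        batch_size=12, seed=0, augment=False)
        model = build_model(cfg, X.shape[2:])
        hist = train(model, X, t, cfg)
        assert np.ptp(hist) == 0.0

    def test_fully_deterministic(self):
        X, t = _toy_problem(n=20)
        cfg = CNNConfig(conv_filters=(4,), hidden_widths=(8,), n_outputs=2,
                        n_epochs=3, dropout_rate=0.2, seed=5)
        h1 = train(build_model(cfg, X.shape[2:]), X, t, cfg)
        h2 = train(build_model(cfg, X.shape[2:]), X, t, cfg)
        assert h1 == h2


class _StubModel:
    """Duck-typed regressor returning canned normalized predictions."""

    def __init__(self, outputs):
        self._out = np.asarray(outputs, dtype=float)

    def forward(self, x, train=False):
        return self._out


class TestEvaluate:
    def _normalizer(self, lo=0.0, hi=1.0, k=1):
        n = TargetNormalizer()
        n.minima = np.full(k, lo)
        n.maxima = np.full(k, hi)
        n.names = None
        return n

    def test_perfect_predictions_score_one(self):
        y = np.linspace(0, 1, 8)[:, None]
        rep = evaluate(_StubModel(y), np.zeros((8, 1, 4, 4)), y,
                       self._normalizer())
        assert rep.r2[0] == pytest.approx(1.0)
        assert rep.p_value[0] < 1e-6

    def test_hand_computed_four_points(self):
        pred = np.array([[1.0], [2.0], [3.0], [4.0]])
        true = np.array([[1.0], [2.0], [2.0], [3.0]])
        r_expected, _ = stats.pearsonr(pred.ravel(), true.ravel())
        rep = evaluate(_StubModel(pred), np.zeros((4, 1, 2, 2)), true,
                       self._normalizer())
        assert rep.r2[0] == pytest.approx(r_expected ** 2)

    def test_uncorrelated_noise_scores_near_zero(self):
        rng = np.random.default_rng(1)
        pred = rng.normal(size=(1000, 1))
        true = rng.normal(size=(1000, 1))
        rep = evaluate(_StubModel(pred), np.zeros((1000, 1, 2, 2)), true,
                       self._normalizer())
        assert rep.r2[0] < 0.02

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_StubModel([[1.0]]), np.zeros((1, 1, 2, 2)),
                     np.array([[1.0]]), self._normalizer())

    def test_predictions_denormalized_to_native_units(self):
        pred_norm = np.array([[0.0], [0.5], [1.0]])
        true = np.array([[10.0], [20.0], [30.0]])
        rep = evaluate(_StubModel(pred_norm), np.zeros((3, 1, 2, 2)), true,
                       self._normalizer(10.0, 30.0))
        np.testing.assert_allclose(rep.predicted.ravel(), [10.0, 20.0, 30.0])
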