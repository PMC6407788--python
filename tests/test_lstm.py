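import numpy as np
import pytest

from placedecode.lstm import (GradientTensor, LSTMRegressor, RegressorSpec,
                              SequenceRegressor, TrainConfig, build_regressor,
                              loss_input_gradients, predict_positions,
                              train_regressor)


class _ArrayDataset:
    """Minimal duck-typed dataset over in-memory arrays."""

    def __init__(self, x, y, unit_ids=None):
        self.x = np.asarray(x)
        self.y = np.asarray(y)
        self.unit_ids = unit_ids or [str(i) for i in range(self.x.shape[2])]
        self.seq_len = self.x.shape[1]

    n_samples = property(lambda self: len(self.x))
    dims = property(lambda self: self.y.shape[1])
    inputs = property(lambda self: self.x)
    targets = property(lambda self: self.y)

    def take(self, idx):
        return self.x[idx], self.y[idx]


def _toy_data(rng, n=48, t=12, units=6, dims=2):
    x = rng.poisson(2.0, size=(n, t, units)).astype(float)
    y = rng.uniform(0, 100, size=(n, dims))
    return _ArrayDataset(x, y)


class TestConstruction:
    def test_parameter_count_closed_form(self):
        # 4(h(h+n)+h) per layer + h*out + out
        assert RegressorSpec(63).n_params == 3_279_874
        spec = RegressorSpec(10, recurrent_layers=1, hidden_per_layer=7,
                             output_dim=1)
        assert spec.n_params == 4 * (7 * 17 + 7) + 7 + 1
        m = build_regressor(spec, seed=0)
        assert m.n_params == spec.n_params

    def test_seed_determinism(self, rng):
        spec = RegressorSpec(6, hidden_per_layer=12)
        x = rng.poisson(2, (4, 9, 6)).astype(float)
        a = build_regressor(spec, seed=3).predict(x)
        b = build_regressor(spec, seed=3).predict(x)
        np.testing.assert_array_equal(a, b)
        c = build_regressor(spec, seed=4).predict(x)
        assert not np.array_equal(a, c)

    def test_output_dim_one(self, rng):
        m = build_regressor(RegressorSpec(5, hidden_per_layer=8, output_dim=1))
        y = m.predict(rng.poisson(1, (3, 6, 5)).astype(float))
        assert y.shape == (3, 1)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            RegressorSpec(0)


class TestPredict:
    def test_zeroed_readout_predicts_bias(self, rng):
        m = build_regressor(RegressorSpec(4, hidden_per_layer=6), seed=0)
        m.Wy[:] = 0
        m.by[:] = [7.0, -3.0]
        y = m.predict(rng.poisson(2, (5, 8, 4)).astype(float))
        np.testing.assert_allclose(y, np.tile([7.0, -3.0], (5, 1)), atol=1e-6)

    def test_repeat_call_bitwise_identical(self, rng):
        m = build_regressor(RegressorSpec(4, hidden_per_layer=6), seed=1)
        x = rng.poisson(2, (5, 8, 4)).astype(float)
        np.testing.assert_array_equal(m.predict(x), m.predict(x))

    def test_shape_mismatch_errors(self, rng):
        m = build_regressor(RegressorSpec(4, hidden_per_layer=6), seed=1)
        with pytest.raises(ValueError):
            m.predict(rng.poisson(2, (5, 8, 3)).astype(float))


class TestTraining:
    def test_loss_history_length_and_reproducibility(self, rng):
        data = _toy_data(rng)
        cfg = TrainConfig(epochs=3, rng_seed=7, batch_size=16)
        m1, h1 = train_regressor(
            build_regressor(RegressorSpec(6, hidden_per_layer=8), seed=5),
            data, cfg)
        m2, h2 = train_regressor(
            build_regressor(RegressorSpec(6, hidden_per_layer=8), seed=5),
            data, cfg)
        assert len(h1) == 3
        assert h1 == h2  # bitwise-reproducible training

    def test_constant_target_converges_to_it(self, rng):
        data = _toy_data(rng, n=32)
        data.y = np.full((32, 2), 42.0)
        m = build_regressor(RegressorSpec(6, hidden_per_layer=8), seed=0)
        hist = m.train(data, TrainConfig(epochs=5, rng_seed=0))
        pred = m.predict(data.x)
        np.testing.assert_allclose(pred, 42.0, atol=1.0)
        assert hist[-1] < 1.0

    def test_empty_data_errors(self, rng):
        data = _toy_data(rng, n=0)
        m = build_regressor(RegressorSpec(6, hidden_per_layer=8))
        with pytest.raises(ValueError):
            m.train(data, TrainConfig(epochs=1))

    def test_smoke_profile_beats_predict_mean_baseline(self, small_session):
        """Scaled-down profile learns position structure from counts."""
        from placedecode import (blocked_folds, build_sequences,
                                 count_in_windows, validate_session)
        _, spikes, traj, _ = small_session
        span = validate_session(spikes, traj).usable_span
        wc = count_in_windows(spikes, 1.4, 0.2, span)
        ds = build_sequences(wc, traj, 25)
        folds = blocked_folds(ds.n_samples, 5, 25)
        f = folds[0]
        # 500 training samples spread evenly over the training time
        pick = f.train_idx[np.linspace(0, len(f.train_idx) - 1, 500).astype(int)]
        x, y = ds.take(pick)
        data = _ArrayDataset(x, y)
        m = build_regressor(RegressorSpec(x.shape[2], hidden_per_layer=64),
                            seed=2)
        hist = m.train(data, TrainConfig(epochs=10, rng_seed=2))
        baseline_mse = float(((y - y.mean(0)) ** 2).sum(1).mean())
        assert hist[-1] < baseline_mse
        vx, vy = ds.take(f.val_idx)
        err = np.linalg.norm(m.predict(vx) - vy, axis=1)
        base = np.linalg.norm(vy - y.mean(0), axis=1)
        assert np.median(err) < np.median(base)


class TestInputGradients:
    def test_zeroed_readout_gives_zero_gradients(self, rng):
        m = build_regressor(RegressorSpec(4, hidden_per_layer=6), seed=0)
        m.Wy[:] = 0
        data = _toy_data(rng, n=6, t=5, units=4)
        g = loss_input_gradients(m, data)
        np.testing.assert_array_equal(g.abs_grad, 0.0)

    def test_shape_and_finiteness(self, rng):
        m = build_regressor(RegressorSpec(4, hidden_per_layer=6), seed=1)
        data = _toy_data(rng, n=6, t=5, units=4)
        g = loss_input_gradients(m, data)
        assert g.abs_grad.shape == (6, 5, 4)
        assert np.all(np.isfinite(g.abs_grad))
        assert np.all(g.abs_grad >= 0)

    def test_finite_difference_oracle(self, rng):
        """BPTT input gradients match central differences (float64)."""
        spec = RegressorSpec(5, hidden_per_layer=8)
        m = build_regressor(spec, seed=0, dtype=np.float64)
        x = rng.poisson(2, size=(3, 7, 5)).astype(float)
        y = rng.uniform(0, 100, size=(3, 2))
        g = m.input_gradients(x, y).abs_grad
        eps = 1e-3
        for _ in range(20):
            s, t, n = (int(rng.integers(3)), int(rng.integers(7)),
                       int(rng.integers(5)))
            xp, xm = x.copy(), x.copy()
            xp[s, t, n] += eps
            xm[s, t, n] -= eps
            lp = np.sum((m.predict(xp)[s] - y[s]) ** 2)
            lm = np.sum((m.predict(xm)[s] - y[s]) ** 2)
            fd = abs((lp - lm) / (2 * eps))
            assert abs(fd - g[s, t, n]) <= 1e-3 * max(fd, g[s, t, n], 1e-8)

    def test_gradient_tensor_rejects_nan(self):
        with pytest.raises(ValueError):
            GradientTensor(np.array([[[np.nan]]]))


def test_sequence_regressor_results_surface(rng):
    data = _toy_data(rng, n=32, t=8, units=5)
    res = SequenceRegressor(data).fit(
        TrainConfig(epochs=2, rng_seed=0), seed=0)
    assert len(res.loss_history) == 2
    assert res.predict(data.x).shape == (32, 2)
    assert "parameters" in res.summary()
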