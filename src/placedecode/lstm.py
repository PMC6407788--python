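"""Many-to-one LSTM sequence regressor, implemented in NumPy.

The decoder maps a sequence of spike-count vectors (seq_len x units) to a
single position estimate read out at the final timestep: an input layer the
size of the recorded population, two LSTM layers, and a linear output layer
(one node per coordinate).  Training minimises the mean squared error of
the coordinates with RMSprop at a constant learning rate, no early
stopping.

Loss gradients with respect to the *inputs* — the quantity behind gradient
sensitivity analysis — are obtained by backpropagation through time with
the per-sample loss, exactly as gradients with respect to weights are.

Everything is plain NumPy: runs are bit-reproducible given the seed, and
float64 mode supports finite-difference verification of the gradients.

Gate layout per layer l (input size n, hidden size h):
    z = x_t @ Wx + h_{t-1} @ Wh + b,      z split into (i, f, g, o)
    c_t = sigmoid(f) * c_{t-1} + sigmoid(i) * tanh(g)
    h_t = sigmoid(o) * tanh(c_t)
giving 4 (h (h + n) + h) parameters per layer plus the h*out + out readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import SequenceDataset

__all__ = [
    "RegressorSpec",
    "TrainConfig",
    "GradientTensor",
    "LSTMRegressor",
    "build_regressor",
    "train_regressor",
    "predict_positions",
    "loss_input_gradients",
    "SequenceRegressor",
    "SequenceRegressorResults",
]


@dataclass
class RegressorSpec:
    input_units: int
    recurrent_layers: int = 2
    hidden_per_layer: int = 512
    output_dim: int = 2  # 1 for the linearised track

    def __post_init__(self) -> None:
        if min(self.input_units, self.recurrent_layers,
               self.hidden_per_layer, self.output_dim) < 1:
            raise ValueError("all sizes must be >= 1")

    @property
    def n_params(self) -> int:
        h = self.hidden_per_layer
        total, n_in = 0, self.input_units
        for _ in range(self.recurrent_layers):
            total += 4 * (h * (h + n_in) + h)
            n_in = h
        return total + h * self.output_dim + self.output_dim


@dataclass
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 0.001  # constant
    batch_size: int = 64
    optimizer: str = "rmsprop"
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-7
    rng_seed: int = 0
    standardize_inputs: bool = False
    center_targets: bool = True  # fit residuals around the training-mean position

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "rmsprop":
            raise ValueError("only the rmsprop optimizer is supported")


@dataclass
class GradientTensor:
    """|dLoss_s / d input_{s,t,n}|: samples x seq_len x units magnitudes."""

    abs_grad: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.abs_grad)):
            raise ValueError("gradients contain non-finite values")
        if np.any(self.abs_grad < 0):
            raise ValueError("magnitudes must be non-negative")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _orthogonal(rng: np.random.Generator, n: int, dtype) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diag(r))).astype(dtype)


class LSTMRegressor:
    """Stacked-LSTM many-to-one regressor with hand-rolled BPTT."""

    def __init__(self, spec: RegressorSpec, seed: int = 0,
                 dtype=np.float32):
        self.spec = spec
        self.seed = seed
        self.dtype = np.dtype(dtype)
        self.input_mean: np.ndarray | None = None
        self.input_scale: np.ndarray | None = None
        # additive output offset (training-mean target when centring is on);
        # the network itself regresses residuals around it
        self.target_offset = np.zeros(spec.output_dim, dtype=np.dtype(dtype))
        rng = np.random.default_rng(seed)
        h = spec.hidden_per_layer
        self.Wx, self.Wh, self.b = [], [], []
        n_in = spec.input_units
        for _ in range(spec.recurrent_layers):
            lim = np.sqrt(6.0 / (n_in + 4 * h))
            self.Wx.append(rng.uniform(-lim, lim, size=(n_in, 4 * h))
                           .astype(self.dtype))
            wh = np.concatenate(
                [_orthogonal(rng, h, self.dtype) for _ in range(4)], axis=1)
            self.Wh.append(wh)
            bias = np.zeros(4 * h, dtype=self.dtype)
            bias[h:2 * h] = 1.0  # forget-gate bias
            self.b.append(bias)
            n_in = h
        lim = np.sqrt(6.0 / (h + spec.output_dim))
        self.Wy = rng.uniform(-lim, lim, size=(h, spec.output_dim)) \
            .astype(self.dtype)
        self.by = np.zeros(spec.output_dim, dtype=self.dtype)
        self._ms = None  # RMSprop second-moment caches

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out = []
        for l in range(self.spec.recurrent_layers):
            out += [self.Wx[l], self.Wh[l], self.b[l]]
        out += [self.Wy, self.by]
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward -------------------------------------------------

    def _prep(self, inputs: np.ndarray) -> np.ndarray:
        x = np.asarray(inputs, dtype=self.dtype)
        if x.ndim != 3 or x.shape[2] != self.spec.input_units:
            raise ValueError(
                f"inputs must be samples x seq_len x {self.spec.input_units}, "
                f"got {x.shape}")
        if self.input_mean is not None:
            x = (x - self.input_mean) / self.input_scale
        return x

    def _forward(self, x: np.ndarray, keep: bool):
        """Run the stack; returns (y, cache).  x: (B, T, n)."""
        B, T, _ = x.shape
        h_dim = self.spec.hidden_per_layer
        cache = [] if keep else None
        layer_in = x
        for l in range(self.spec.recurrent_layers):
            h = np.zeros((B, h_dim), dtype=self.dtype)
            c = np.zeros((B, h_dim), dtype=self.dtype)
            hs = np.empty((T, B, h_dim), dtype=self.dtype)
            st = {"i": np.empty((T, B, h_dim), self.dtype),
                  "f": np.empty((T, B, h_dim), self.dtype),
                  "g": np.empty((T, B, h_dim), self.dtype),
                  "o": np.empty((T, B, h_dim), self.dtype),
                  "tc": np.empty((T, B, h_dim), self.dtype),
                  "c_prev": np.empty((T, B, h_dim), self.dtype),
                  "h_prev": np.empty((T, B, h_dim), self.dtype)} if keep else None
            Wx, Wh, bb = self.Wx[l], self.Wh[l], self.b[l]
            pre = layer_in @ Wx  # (B, T, 4h), one big GEMM
            for t in range(T):
                z = pre[:, t, :] + h @ Wh + bb
                i = _sigmoid(z[:, :h_dim])
                f = _sigmoid(z[:, h_dim:2 * h_dim])
                g = np.tanh(z[:, 2 * h_dim:3 * h_dim])
                o = _sigmoid(z[:, 3 * h_dim:])
                if keep:
                    st["c_prev"][t] = c
                    st["h_prev"][t] = h
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                hs[t] = h
                if keep:
                    st["i"][t], st["f"][t], st["g"][t] = i, f, g
                    st["o"][t], st["tc"][t] = o, tc
            if keep:
                cache.append({"x": layer_in, "st": st})
            layer_in = hs.transpose(1, 0, 2)  # (B, T, h)
        h_last = layer_in[:, -1, :]
        y = h_last @ self.Wy + self.by
        if keep:
            return y, (cache, h_last)
        return y, None

    def _backward(self, dY: np.ndarray, fwd_cache, want_param_grads: bool,
                  want_input_grads: bool):
        """BPTT.  dY: (B, out) gradient on the network output."""
        cache, h_last = fwd_cache
        B = dY.shape[0]
        h_dim = self.spec.hidden_per_layer
        grads = {} if want_param_grads else None
        if want_param_grads:
            grads["Wy"] = h_last.T @ dY
            grads["by"] = dY.sum(axis=0)
        dh_out_last = dY @ self.Wy.T  # external grad on top layer final h
        dx_next = None  # per-timestep grads flowing to the layer below
        for l in reversed(range(self.spec.recurrent_layers)):
            x, st = cache[l]["x"], cache[l]["st"]
            T = x.shape[1]
            Wx, Wh = self.Wx[l], self.Wh[l]
            dWx = np.zeros_like(Wx) if want_param_grads else None
            dWh = np.zeros_like(Wh) if want_param_grads else None
            db = np.zeros(4 * h_dim, dtype=self.dtype) if want_param_grads else None
            need_dx = want_input_grads or l > 0
            dz_all = np.empty((T, B, 4 * h_dim), dtype=self.dtype) \
                if (need_dx or want_param_grads) else None
            dh = np.zeros((B, h_dim), dtype=self.dtype)
            dc = np.zeros((B, h_dim), dtype=self.dtype)
            for t in reversed(range(T)):
                dh_t = dh.copy()
                if l == self.spec.recurrent_layers - 1:
                    if t == T - 1:
                        dh_t += dh_out_last
                else:
                    dh_t += dx_next[t]
                i, f, g, o = st["i"][t], st["f"][t], st["g"][t], st["o"][t]
                tc, c_prev = st["tc"][t], st["c_prev"][t]
                dct = dh_t * o * (1.0 - tc * tc) + dc
                dz = np.concatenate([
                    dct * g * i * (1.0 - i),
                    dct * c_prev * f * (1.0 - f),
                    dct * i * (1.0 - g * g),
                    dh_t * tc * o * (1.0 - o),
                ], axis=1)
                if dz_all is not None:
                    dz_all[t] = dz
                if want_param_grads:
                    dWh += st["h_prev"][t].T @ dz
                    db += dz.sum(axis=0)
                dh = dz @ Wh.T
                dc = dct * f
            if want_param_grads:
                # batched: sum_t x_t^T dz_t
                xt = x.reshape(B * T, -1)
                dWx += xt.T @ dz_all.transpose(1, 0, 2).reshape(B * T, -1)
                grads[f"Wx{l}"], grads[f"Wh{l}"], grads[f"b{l}"] = dWx, dWh, db
            if need_dx:
                dx_next = dz_all @ Wx.T  # (T, B, n_in)
            else:
                dx_next = None
        input_grads = None
        if want_input_grads:
            input_grads = dx_next.transpose(1, 0, 2)  # (B, T, n)
            if self.input_scale is not None:
                input_grads = input_grads / self.input_scale
        return grads, input_grads

    # -- public ops ---------------------------------------------------------

    def predict(self, inputs: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Coordinates per sample; deterministic given fixed weights, no
        clamping to the arena."""
        x = self._prep(inputs)
        outs = []
        for s in range(0, len(x), batch_size):
            y, _ = self._forward(x[s:s + batch_size], keep=False)
            outs.append(y)
        y = np.concatenate(outs, axis=0) + self.target_offset
        if not np.all(np.isfinite(y)):
            raise FloatingPointError("non-finite predictions")
        return y

    def train(self, data: SequenceDataset, cfg: TrainConfig,
              loss_callback=None) -> list[float]:
        """RMSprop / MSE training for exactly ``cfg.epochs`` epochs.

        The loss is the mean over samples of the summed squared coordinate
        error; the per-epoch training loss history is returned.  No
        validation-based stopping.
        """
        if data.n_samples == 0:
            raise ValueError("empty training data")
        if data.dims != self.spec.output_dim:
            raise ValueError("target dims do not match output_dim")
        if cfg.standardize_inputs and self.input_mean is None:
            flat = data.inputs.reshape(-1, data.inputs.shape[2])
            self.input_mean = flat.mean(axis=0).astype(self.dtype)
            self.input_scale = np.maximum(flat.std(axis=0), 1e-6) \
                .astype(self.dtype)
        if cfg.center_targets and not self.target_offset.any():
            self.target_offset = np.asarray(data.targets, dtype=self.dtype) \
                .mean(axis=0)
        params = self.parameters()
        if self._ms is None:
            self._ms = [np.zeros_like(p) for p in params]
        rng = np.random.default_rng(cfg.rng_seed)
        n = data.n_samples
        history: list[float] = []
        order_names = []
        for l in range(self.spec.recurrent_layers):
            order_names += [f"Wx{l}", f"Wh{l}", f"b{l}"]
        order_names += ["Wy", "by"]
        for epoch in range(cfg.epochs):
            perm = rng.permutation(n)
            total, seen = 0.0, 0
            for s in range(0, n, cfg.batch_size):
                idx = perm[s:s + cfg.batch_size]
                xb, yb = data.take(idx)
                xb = self._prep(xb)
                yb = np.asarray(yb, dtype=self.dtype) - self.target_offset
                y, cache = self._forward(xb, keep=True)
                err = y - yb
                batch_loss = float(np.sum(err * err))
                if not np.isfinite(batch_loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}; "
                        "reduce the learning rate")
                total += batch_loss
                seen += len(idx)
                dY = (2.0 / len(idx)) * err
                grads, _ = self._backward(dY.astype(self.dtype), cache,
                                          want_param_grads=True,
                                          want_input_grads=False)
                for p, ms, name in zip(params, self._ms, order_names):
                    g = grads[name]
                    ms *= cfg.rmsprop_rho
                    ms += (1.0 - cfg.rmsprop_rho) * g * g
                    p -= cfg.learning_rate * g / (np.sqrt(ms) + cfg.rmsprop_eps)
            epoch_loss = total / seen
            history.append(epoch_loss)
            if loss_callback is not None:
                loss_callback(epoch, epoch_loss)
        return history

    def input_gradients(self, data: SequenceDataset | np.ndarray,
                        targets: np.ndarray | None = None,
                        batch_size: int = 128) -> GradientTensor:
        """|d per-sample loss / d input| over all samples (BPTT).

        The per-sample loss is that sample's summed squared coordinate
        error; magnitudes only, per the sensitivity-analysis convention.
        """
        if hasattr(data, "n_samples"):  # any SequenceDataset-like container
            take = data.take
            n = data.n_samples
        else:
            x_all = np.asarray(data)
            y_all = np.asarray(targets)
            take = lambda idx: (x_all[idx], y_all[idx])
            n = len(x_all)
        out = []
        for s in range(0, n, batch_size):
            idx = np.arange(s, min(s + batch_size, n))
            xb, yb = take(idx)
            xb = self._prep(xb)
            yb = np.asarray(yb, dtype=self.dtype) - self.target_offset
            y, cache = self._forward(xb, keep=True)
            dY = 2.0 * (y - yb)  # per-sample loss gradient
            _, gin = self._backward(dY.astype(self.dtype), cache,
                                    want_param_grads=False,
                                    want_input_grads=True)
            out.append(np.abs(gin))
        return GradientTensor(np.concatenate(out, axis=0))


# -- spec-level functional surface ------------------------------------------


def build_regressor(spec: RegressorSpec, seed: int = 0,
                    dtype=np.float32) -> LSTMRegressor:
    """Deterministically initialised (untrained) regressor."""
    return LSTMRegressor(spec, seed=seed, dtype=dtype)


def train_regressor(model: LSTMRegressor, data: SequenceDataset,
                    cfg: TrainConfig) -> tuple[LSTMRegressor, list[float]]:
    history = model.train(data, cfg)
    return model, history


def predict_positions(model: LSTMRegressor, inputs: np.ndarray) -> np.ndarray:
    return model.predict(inputs)


def loss_input_gradients(model: LSTMRegressor,
                         data: SequenceDataset) -> GradientTensor:
    return model.input_gradients(data)


# -- model / results presentation -------------------------------------------


class SequenceRegressor:
    """Many-to-one sequence regression as a fit/results pair."""

    def __init__(self, data: SequenceDataset, spec: RegressorSpec | None = None):
        self.data = data
        self.spec = spec or RegressorSpec(
            input_units=len(data.unit_ids), output_dim=data.dims)

    def fit(self, train_config: TrainConfig | None = None,
            seed: int = 0, dtype=np.float32) -> "SequenceRegressorResults":
        cfg = train_config or TrainConfig(rng_seed=seed)
        model = build_regressor(self.spec, seed=seed, dtype=dtype)
        history = model.train(self.data, cfg)
        return SequenceRegressorResults(self, model, history, cfg)


class SequenceRegressorResults:
    def __init__(self, parent: SequenceRegressor, model: LSTMRegressor,
                 loss_history: list[float], train_config: TrainConfig):
        self.model = model
        self.parent = parent
        self.loss_history = loss_history
        self.train_config = train_config

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        return self.model.predict(inputs)

    def input_gradients(self, data: SequenceDataset) -> GradientTensor:
        return self.model.input_gradients(data)

    def summary(self) -> str:
        s = self.model.spec
        lines = [
            "Many-to-one LSTM position regressor",
            "=" * 43,
            f"inputs: {s.input_units} units x seq_len   layers: "
            f"{s.recurrent_layers} x {s.hidden_per_layer} LSTM   "
            f"outputs: {s.output_dim}",
            f"parameters: {s.n_params:,}",
            f"epochs: {self.train_config.epochs}   lr: "
            f"{self.train_config.learning_rate}   batch: "
            f"{self.train_config.batch_size} (RMSprop, MSE)",
            f"training loss: {self.loss_history[0]:.2f} -> "
            f"{self.loss_history[-1]:.2f} (cm^2, summed over coordinates)",
        ]
        return "\n".join(lines)
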