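"""The default synthetic benchmark: one fixed set of study conditions that
exercises the whole pipeline end to end.

Conditions: a 1 m x 1 m open field, 40 place units + 3 interneuron-like
units, a 1200 s session at 50 Hz tracking with gamma-modulated Poisson
spiking; 1400 ms count windows at a 200 ms stride; 10-fold blocked CV for
the deterministic Bayesian decoders; and a desk-scale recurrent decoder
profile (2 x 128 LSTM, 20 epochs, single blocked fold, training set thinned
to every 2nd sample) for the stochastic one.  The same driver backs the
test suite and the reproduction script so all reported numbers come from
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import baseline_errors, blocked_folds, run_cv, CVResult
from .features import build_sequences, count_in_windows
from .io import ArenaSpec, RunConfig, validate_session
from .lstm import LSTMRegressor, RegressorSpec, TrainConfig
from .synthetic import SimConfig, simulate_session

__all__ = ["BenchmarkRNNResult", "benchmark_session", "run_flat_cv",
           "train_benchmark_rnn"]

RNN_HIDDEN = 128
RNN_EPOCHS = 20
RNN_TRAIN_SUBSAMPLE = 2


def benchmark_session(seed: int = 1):
    """Simulate the benchmark session. Returns (spikes, traj, tuning, cfg)."""
    sim = SimConfig(rng_seed=seed)
    spikes, traj, tuning = simulate_session(sim, ArenaSpec())
    cfg = RunConfig(window_len_ms=1400.0, rng_seed=seed)
    return spikes, traj, tuning, cfg


def run_flat_cv(spikes, traj, cfg) -> tuple[CVResult, float, float]:
    """Full 10-fold blocked CV with the flat Bayesian decoder; returns the
    result plus the predict-arena-centre baseline (mean, median) on the same
    retained samples."""
    res = run_cv("flat", spikes, traj, cfg)
    truth = res.samples[["true_x", "true_y"]].to_numpy()
    _, base_mean, base_median = baseline_errors(truth, "center", traj.arena)
    return res, base_mean, base_median


@dataclass
class BenchmarkRNNResult:
    model: LSTMRegressor
    val_inputs: np.ndarray
    val_targets: np.ndarray
    errors_cm: np.ndarray
    mean_error_cm: float
    median_error_cm: float
    baseline_mean_cm: float      # predict-training-mean baseline
    baseline_median_cm: float
    loss_history: list
    val_dataset: object = None   # SequenceDataset view of the validation fold


class _Subset:
    def __init__(self, ds, idx):
        self._ds, self._idx = ds, np.asarray(idx)
        self.unit_ids, self.seq_len = ds.unit_ids, ds.seq_len

    n_samples = property(lambda self: len(self._idx))
    dims = property(lambda self: self._ds.dims)
    inputs = property(lambda self: self._ds.take(self._idx)[0])
    targets = property(lambda self: self._ds.targets[self._idx])

    def take(self, idx):
        return self._ds.take(self._idx[idx])


def train_benchmark_rnn(spikes, traj, cfg, seed: int = 1,
                        hidden: int = RNN_HIDDEN, epochs: int = RNN_EPOCHS,
                        train_subsample: int = RNN_TRAIN_SUBSAMPLE,
                        fold: int = 0) -> BenchmarkRNNResult:
    """Train the desk-scale recurrent decoder on one blocked fold and
    evaluate it on that fold's retained validation samples."""
    report = validate_session(spikes, traj)
    wc = count_in_windows(spikes, cfg.window_len_s, cfg.stride_s,
                          report.usable_span)
    ds = build_sequences(wc, traj, cfg.seq_len)
    folds = blocked_folds(ds.n_samples, cfg.n_folds, cfg.seq_len)
    fs = folds[fold]
    train_idx = fs.train_idx[::train_subsample]
    spec = RegressorSpec(input_units=len(ds.unit_ids),
                         hidden_per_layer=hidden, output_dim=ds.dims)
    model = LSTMRegressor(spec, seed=seed)
    history = model.train(_Subset(ds, train_idx),
                          TrainConfig(epochs=epochs, rng_seed=seed))
    # proper SequenceDataset restricted to the retained validation samples,
    # so knockout/gradient analyses can consume it directly
    from .features import SequenceDataset
    val = SequenceDataset(ds.counts_wn, ds.targets[fs.val_idx],
                          ds.sample_to_window[fs.val_idx], ds.seq_len,
                          list(ds.unit_ids), ds.window_centers)
    val_x, val_y = val.inputs, val.targets
    pred = model.predict(val_x)
    err = np.linalg.norm(pred - val_y, axis=1)
    train_mean = ds.targets[train_idx].mean(axis=0)
    base = np.linalg.norm(val_y - train_mean, axis=1)
    return BenchmarkRNNResult(
        model=model, val_inputs=val_x, val_targets=val_y, errors_cm=err,
        mean_error_cm=float(err.mean()),
        median_error_cm=float(np.median(err)),
        baseline_mean_cm=float(base.mean()),
        baseline_median_cm=float(np.median(base)),
        loss_history=history, val_dataset=val)
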