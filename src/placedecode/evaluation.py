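"""Blocked cross-validation, error metrics, and error-covariate analyses.

Consecutive windowed-count samples overlap heavily in time, so random CV
splits leak: a validation sample would almost always share spike-count
vectors with a training sample.  Folds here are contiguous blocks of the
recording (fold 1 = first tenth, ...), and any validation sample whose
window span shares a window index with a training sample's span is
discarded.  The span-overlap predicate is authoritative; for 100-window
sequences it discards 99 samples at each train/validation border.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .bayes import BayesianPositionDecoder, MemoryParams
from .features import (WindowedCounts, build_sequences, count_in_windows,
                       downsample_units)
from .io import ArenaSpec, RunConfig, SpikeData, Trajectory, validate_session
from .lstm import LSTMRegressor, RegressorSpec, TrainConfig

logger = logging.getLogger("placedecode")

__all__ = [
    "FoldSplit",
    "CVResult",
    "blocked_folds",
    "run_cv",
    "window_scan",
    "compute_errors",
    "error_histogram",
    "linearize_z",
    "covariate_analysis",
    "downsampling_experiment",
    "baseline_errors",
]


# ---------------------------------------------------------------------------
# fold construction


@dataclass
class FoldSplit:
    """Disjoint train / retained-validation / discarded sample index sets."""

    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    discarded_idx: np.ndarray


def blocked_folds(n_samples: int, k: int = 10,
                  seq_len: int = 100) -> list[FoldSplit]:
    """Contiguous equal blocks (remainder to the last fold).

    Sample ``i`` spans window indices ``[i, i + seq_len - 1]``; a validation
    sample is discarded iff its span overlaps any training sample's span,
    i.e. iff it lies within ``seq_len - 1`` of the validation block's
    borders.  A fold whose retained set is empty triggers a warning, not an
    error.
    """
    if n_samples < k:
        raise ValueError("need at least one sample per fold")
    base = n_samples // k
    folds = []
    for f in range(k):
        a = f * base
        b = (f + 1) * base if f < k - 1 else n_samples
        val = np.arange(a, b)
        train = np.concatenate([np.arange(0, a), np.arange(b, n_samples)])
        keep = np.ones(len(val), dtype=bool)
        if a > 0:
            keep &= val >= a + seq_len - 1
        if b < n_samples:
            keep &= val <= b - seq_len
        if not keep.any():
            logger.warning("blocked_folds: fold %d retains zero samples "
                           "(block %d, seq_len %d)", f, b - a, seq_len)
        folds.append(FoldSplit(f, train, val[keep], val[~keep]))
    return folds


# ---------------------------------------------------------------------------
# error metrics


def compute_errors(pred: np.ndarray, truth: np.ndarray, mode: str = "2d",
                   bin_cm: float = 2.0):
    """Per-sample errors plus MED and median.

    Modes: ``2d`` Euclidean on continuous coordinates; ``1d`` absolute
    arc-length difference; ``bin2d`` Euclidean after snapping the true
    position to the nearest bin centre (decoded positions are already bin
    centres).  Returns ``(ErrorTable DataFrame, MED, median)``.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if len(pred) != len(truth):
        raise ValueError("pred and truth length mismatch")
    if mode == "1d":
        p = pred.reshape(-1)
        t = truth.reshape(-1)
        err = np.abs(p - t)
        df = pd.DataFrame({"true_s": t, "pred_s": p, "error_cm": err})
    elif mode in ("2d", "bin2d"):
        p = pred.reshape(-1, 2)
        t = truth.reshape(-1, 2)
        if mode == "bin2d":
            t = (np.floor(t / bin_cm) + 0.5) * bin_cm
        dx = p[:, 0] - t[:, 0]
        dy = p[:, 1] - t[:, 1]
        err = np.hypot(dx, dy)
        df = pd.DataFrame({
            "true_x": t[:, 0], "true_y": t[:, 1],
            "pred_x": p[:, 0], "pred_y": p[:, 1],
            "x_error": np.abs(dx), "y_error": np.abs(dy),
            "error_cm": err,
        })
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(df)
    med = float(err.sum() / n) if n else float("nan")
    return df, med, float(np.median(err)) if n else float("nan")


def error_histogram(errors: np.ndarray, bin_cm: float = 2.0,
                    cap_cm: float = 50.0):
    """Counts in [0,2), [2,4), ... plus one overflow bin for errors > cap.

    Returns ``(edges, counts)`` where ``len(counts) == len(edges)`` and the
    final count is the overflow bin.
    """
    e = np.asarray(errors, dtype=float)
    if np.any(e < 0):
        raise ValueError("errors must be non-negative")
    edges = np.arange(0.0, cap_cm + bin_cm / 2, bin_cm)
    counts = np.histogram(e[e < cap_cm], bins=edges)[0]
    return edges, np.append(counts, int((e >= cap_cm).sum()))


def baseline_errors(truth: np.ndarray, mode: str = "center",
                    arena: ArenaSpec | None = None,
                    train_truth: np.ndarray | None = None):
    """Chance-level reference: predict the arena centre, or the training-set
    mean position, for every sample.  Returns (errors, MED, median)."""
    truth = np.asarray(truth, dtype=float)
    if mode == "center":
        if arena is None:
            raise ValueError("center baseline needs the arena")
        if arena.dims == 2:
            ref = np.array([arena.width_cm / 2, arena.height_cm / 2])
        else:
            ref = np.array([arena.total_length_cm / 2])
    elif mode == "mean":
        src = train_truth if train_truth is not None else truth
        ref = np.asarray(src, dtype=float).reshape(len(src), -1).mean(axis=0)
    else:
        raise ValueError(f"unknown baseline {mode!r}")
    t = truth.reshape(len(truth), -1)
    err = np.linalg.norm(t - ref, axis=1)
    return err, float(err.mean()), float(np.median(err))


# ---------------------------------------------------------------------------
# Z-track linearisation


def linearize_z(points2d: np.ndarray, track: ArenaSpec) -> np.ndarray:
    """Project 2D points onto the idealised Z polyline; returns cumulative
    arc length (cm) of the nearest on-track point, in [0, total length]."""
    if track.kind != "ztrack":
        raise ValueError("linearize_z needs a ztrack arena")
    corners = np.asarray(track.corners, dtype=float)
    seg_len = np.asarray(track.segment_lengths_cm, dtype=float)
    if np.any(seg_len <= 0):
        raise ValueError("degenerate track segment")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    p = np.atleast_2d(np.asarray(points2d, dtype=float))
    best_d2 = np.full(len(p), np.inf)
    best_s = np.zeros(len(p))
    for i in range(len(corners) - 1):
        a, b = corners[i], corners[i + 1]
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = np.sum((p - proj) ** 2, axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        # arc length scaled to the configured segment length
        best_s[better] = cum[i] + t[better] * seg_len[i]
    return best_s if np.asarray(points2d).ndim == 2 else float(best_s[0])


# ---------------------------------------------------------------------------
# cross-validated decoding


@dataclass
class CVResult:
    """Per-fold and per-sample cross-validation errors.

    For stochastic decoders run ``n_repeats`` times, each sample's error is
    the average of its errors over the realizations (not the error of the
    averaged prediction); fold and aggregate statistics are computed from
    those per-sample averaged errors.
    """

    decoder: str
    samples: pd.DataFrame          # per retained validation sample
    fold_summary: pd.DataFrame     # fold, n_val, mean_cm, median_cm
    realization_errors: np.ndarray | None = None  # (samples, repeats)

    @property
    def mean_error_cm(self) -> float:
        return float(self.samples["error_cm"].mean())

    @property
    def median_error_cm(self) -> float:
        return float(self.samples["error_cm"].median())


def _bayes_fold_decode(spikes, traj, cfg, wc, fold, method, mode):
    t0 = wc.window_centers[0] - wc.window_len_s / 2
    stride = wc.stride_s
    # validation block in window indices, before discards
    block = np.concatenate([fold.val_idx, fold.discarded_idx])
    lo_w, hi_w = int(block.min()), int(block.max())
    val_t0 = t0 + lo_w * stride
    val_t1 = t0 + hi_w * stride + wc.window_len_s
    span0, span1 = spikes.session_span
    train_intervals = []
    if val_t0 > span0:
        train_intervals.append((span0, val_t0))
    if val_t1 < span1:
        train_intervals.append((val_t1, span1))
    model = BayesianPositionDecoder(spikes, traj, cfg)
    res = model.fit(train_intervals=train_intervals or None)
    sub = WindowedCounts(wc.counts[:, lo_w:hi_w + 1],
                         wc.window_centers[lo_w:hi_w + 1],
                         wc.window_len_s, stride, list(wc.unit_ids))
    if method == "flat":
        path = res.decode(sub, "flat", return_posterior=False)
    else:
        path = res.decode(sub, "memory")
    keep = fold.val_idx - lo_w
    return path.positions[keep], res


def run_cv(decoder: str, spikes: SpikeData, traj: Trajectory,
           cfg: RunConfig | None = None, *,
           error_mode: str | None = None,
           rnn_spec: RegressorSpec | None = None,
           rnn_train: TrainConfig | None = None,
           n_repeats: int | None = None,
           train_subsample: int = 1,
           folds_to_run=None) -> CVResult:
    """Blocked cross-validated decoding errors for one decoder.

    The Bayesian decoders (``flat``, ``memory``) are deterministic and run
    once; per fold the ratemaps/prior are refit on the training time.  The
    recurrent decoder (``rnn``) runs ``n_repeats`` realizations per fold
    with distinct seeds; per-sample errors are averaged across
    realizations.  ``train_subsample`` thins the RNN training set (every
    n-th sample) for desk-scale runs; ``folds_to_run`` restricts to a
    subset of folds.
    """
    cfg = cfg or RunConfig()
    if decoder not in ("flat", "memory", "rnn"):
        raise ValueError(f"unknown decoder {decoder!r}")
    report = validate_session(spikes, traj)
    span = report.usable_span
    wc = count_in_windows(spikes, cfg.window_len_s, cfg.stride_s, span)
    dims = traj.arena.dims
    if error_mode is None:
        error_mode = "2d" if dims == 2 else "1d"

    if decoder in ("flat", "memory"):
        m_eff = int(math.ceil(cfg.window_len_s / cfg.stride_s))
        folds = blocked_folds(wc.n_windows, cfg.n_folds, m_eff)
        truth_all = traj.interp(wc.window_centers)
        rows, fold_rows = [], []
        for fold in folds:
            if folds_to_run is not None and fold.fold not in folds_to_run:
                continue
            if len(fold.val_idx) == 0:
                continue
            pred, _ = _bayes_fold_decode(spikes, traj, cfg, wc, fold, decoder,
                                         error_mode)
            truth = np.asarray(truth_all).reshape(wc.n_windows, -1)[fold.val_idx]
            df, med, mdn = compute_errors(pred, truth, error_mode, cfg.bin_cm)
            df.insert(0, "window_center_s", wc.window_centers[fold.val_idx])
            df.insert(0, "sample_idx", fold.val_idx)
            df.insert(0, "fold", fold.fold)
            rows.append(df)
            fold_rows.append({"fold": fold.fold, "n_val": len(df),
                              "mean_cm": med, "median_cm": mdn})
        samples = pd.concat(rows, ignore_index=True)
        samples["summed_count"] = wc.counts.sum(axis=0)[samples["sample_idx"]]
        samples["speed_cm_s"] = traj.speeds_cm_s()[
            np.searchsorted(traj.timestamps, samples["window_center_s"])
            .clip(0, len(traj) - 1)]
        return CVResult(decoder, samples, pd.DataFrame(fold_rows))

    # --- recurrent decoder -------------------------------------------------
    ds = build_sequences(wc, traj, cfg.seq_len)
    folds = blocked_folds(ds.n_samples, cfg.n_folds, cfg.seq_len)
    reps = n_repeats if n_repeats is not None else cfg.n_repeats
    spec = rnn_spec or RegressorSpec(input_units=len(ds.unit_ids),
                                     output_dim=ds.dims)
    tc = rnn_train or TrainConfig()
    rows, fold_rows = [], []
    all_real = []
    for fold in folds:
        if folds_to_run is not None and fold.fold not in folds_to_run:
            continue
        if len(fold.val_idx) == 0:
            continue
        train_idx = fold.train_idx[::train_subsample]
        val_x, val_y = ds.take(fold.val_idx)
        per_rep = np.empty((len(fold.val_idx), reps))
        preds_last = None
        for r in range(reps):
            seed = cfg.rng_seed * 10007 + fold.fold * 101 + r
            model = LSTMRegressor(spec, seed=seed % (2**31))
            sub = _SubsetDataset(ds, train_idx)
            model.train(sub, TrainConfig(
                epochs=tc.epochs, learning_rate=tc.learning_rate,
                batch_size=tc.batch_size, rng_seed=seed % (2**31),
                standardize_inputs=tc.standardize_inputs))
            pred = model.predict(val_x)
            preds_last = pred
            if ds.dims == 1:
                per_rep[:, r] = np.abs(pred[:, 0] - val_y[:, 0])
            else:
                per_rep[:, r] = np.linalg.norm(pred - val_y, axis=1)
        err = per_rep.mean(axis=1)
        df, _, _ = compute_errors(preds_last, val_y, error_mode, cfg.bin_cm)
        df["error_cm"] = err  # averaged over realizations
        t_centers = ds.target_times()[fold.val_idx]
        df.insert(0, "window_center_s", t_centers)
        df.insert(0, "sample_idx", fold.val_idx)
        df.insert(0, "fold", fold.fold)
        rows.append(df)
        all_real.append(per_rep)
        fold_rows.append({"fold": fold.fold, "n_val": len(df),
                          "mean_cm": float(err.mean()),
                          "median_cm": float(np.median(err))})
    samples = pd.concat(rows, ignore_index=True)
    last_w = ds.sample_to_window[samples["sample_idx"].to_numpy()]
    samples["summed_count"] = wc.counts.sum(axis=0)[last_w]
    samples["speed_cm_s"] = traj.speeds_cm_s()[
        np.searchsorted(traj.timestamps, samples["window_center_s"])
        .clip(0, len(traj) - 1)]
    return CVResult("rnn", samples, pd.DataFrame(fold_rows),
                    np.concatenate(all_real, axis=0))


class _SubsetDataset:
    """Sample-index view of a SequenceDataset (duck-typed for training)."""

    def __init__(self, ds, idx):
        self._ds = ds
        self._idx = np.asarray(idx)
        self.unit_ids = ds.unit_ids
        self.seq_len = ds.seq_len

    @property
    def n_samples(self):
        return len(self._idx)

    @property
    def dims(self):
        return self._ds.dims

    @property
    def inputs(self):
        return self._ds.take(self._idx)[0]

    @property
    def targets(self):
        return self._ds.targets[self._idx]

    def take(self, idx):
        return self._ds.take(self._idx[idx])


def window_scan(spikes: SpikeData, traj: Trajectory, window_lens_ms,
                decoder: str = "flat", cfg: RunConfig | None = None,
                **cv_kw) -> pd.DataFrame:
    """Error-vs-window-length scan (one blocked CV per length)."""
    cfg = cfg or RunConfig()
    rows = []
    for w in window_lens_ms:
        res = run_cv(decoder, spikes, traj, cfg.replace(window_len_ms=float(w)),
                     **cv_kw)
        rows.append({"window_ms": float(w),
                     "mean_cm": res.mean_error_cm,
                     "median_cm": res.median_error_cm})
    return pd.DataFrame(rows)


def downsampling_experiment(spikes: SpikeData, traj: Trajectory,
                            sizes=range(5, 56, 5), n_sets: int = 10,
                            decoder: str = "flat",
                            cfg: RunConfig | None = None, seed: int = 0,
                            **cv_kw) -> pd.DataFrame:
    """Decoding error vs population size: ``n_sets`` random unit subsets per
    size, full blocked CV per subset; reports mean-of-means and
    mean-of-medians.  Sizes above the population are skipped."""
    cfg = cfg or RunConfig()
    n = spikes.n_units
    rows = []
    for size in sizes:
        if size > n:
            logger.warning("downsampling: size %d > %d units, skipped", size, n)
            continue
        means, medians = [], []
        for s in range(n_sets):
            sub = downsample_units(spikes, size, seed * 1000 + size * 10 + s)
            res = run_cv(decoder, sub, traj, cfg, **cv_kw)
            means.append(res.mean_error_cm)
            medians.append(res.median_error_cm)
        rows.append({"n_units": size, "mean_of_means_cm": float(np.mean(means)),
                     "mean_of_medians_cm": float(np.mean(medians)),
                     "n_sets": len(means)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate analysis


def covariate_analysis(errtable: pd.DataFrame, train_positions: np.ndarray,
                       arena: ArenaSpec, radius_cm: float = 10.0,
                       wall_band_cm: float = 25.0,
                       speed_splits=(0.5, 10.5)) -> dict:
    """Error-covariate report for a 2D session.

    Emits Spearman rank correlations of the per-sample error with (i) the
    number of training positions within ``radius_cm`` of the predicted
    point, (ii) the summed population spike count in the sample's window,
    and (iii) per-coordinate error vs distance to the perpendicular wall
    within ``wall_band_cm``; plus mean/median errors for speed classes
    split at ``speed_splits`` cm/s with Welch t-tests.
    """
    if arena.dims != 2:
        raise ValueError("covariate analysis is defined for 2D sessions")
    need = {"pred_x", "pred_y", "error_cm"}
    if not need.issubset(errtable.columns):
        raise ValueError(f"error table must have columns {sorted(need)}")
    err = errtable["error_cm"].to_numpy()
    out: dict = {}

    def _spear(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        if np.all(a == a[0]) or np.all(b == b[0]):
            return {"rho": float("nan"), "p": float("nan"), "n": len(a),
                    "note": "undefined under constant input"}
        rho, p = stats.spearmanr(a, b)
        return {"rho": float(rho), "p": float(p), "n": len(a)}

    tree = cKDTree(np.asarray(train_positions, float).reshape(-1, 2))
    pred = errtable[["pred_x", "pred_y"]].to_numpy()
    density = np.array([len(ix) for ix in
                        tree.query_ball_point(pred, r=radius_cm)])
    out["error_vs_train_density"] = _spear(err, density)

    if "summed_count" in errtable:
        out["error_vs_summed_count"] = _spear(
            err, errtable["summed_count"].to_numpy())

    for coord, size in (("x", arena.width_cm), ("y", arena.height_cm)):
        col = f"{coord}_error"
        if col not in errtable or f"true_{coord}" not in errtable:
            continue
        true_c = errtable[f"true_{coord}"].to_numpy()
        wall_d = np.minimum(true_c, size - true_c)
        m = wall_d <= wall_band_cm
        if m.sum() >= 3:
            out[f"{coord}_error_vs_wall_distance"] = _spear(
                errtable[col].to_numpy()[m], wall_d[m])

    if "speed_cm_s" in errtable:
        sp = errtable["speed_cm_s"].to_numpy()
        lo, hi = speed_splits
        classes = {
            f"speed<= {lo}": sp <= lo,
            f"{lo}<speed<={hi}": (sp > lo) & (sp <= hi),
            f"speed>{hi}": sp > hi,
        }
        cls_rows = []
        for name, m in classes.items():
            if m.sum() < 3:
                cls_rows.append({"class": name, "n": int(m.sum()),
                                 "note": "skipped (<3 samples)"})
                continue
            cls_rows.append({"class": name, "n": int(m.sum()),
                             "mean_cm": float(err[m].mean()),
                             "median_cm": float(np.median(err[m]))})
        out["speed_classes"] = pd.DataFrame(cls_rows)
        still, moving = classes[f"speed<= {lo}"], sp > lo
        if still.sum() >= 3 and moving.sum() >= 3:
            t, p = stats.ttest_ind(err[still], err[moving], equal_var=False)
            out["still_vs_moving_ttest"] = {"t": float(t), "p": float(p)}
        mid, fast = classes[f"{lo}<speed<={hi}"], sp > hi
        if mid.sum() >= 3 and fast.sum() >= 3:
            t, p = stats.ttest_ind(err[mid], err[fast], equal_var=False)
            out["mid_vs_fast_ttest"] = {"t": float(t), "p": float(p)}
    return out
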