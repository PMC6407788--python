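"""Windowed spike-count features and fixed-length input sequences.

Spike counts are taken in sliding windows of length ``window_len_s`` spaced
``stride_s`` apart (half-open intervals ``[start, start + L)``), so
consecutive windows overlap by ``1 - stride/window_len`` — 0% for 200 ms
windows at a 200 ms stride, 50% at 400 ms, 80% at 1000 ms.  A sequence
sample is ``seq_len`` consecutive count vectors whose regression target is
the position interpolated at the centre of the last window; with the default
100 windows at 200 ms stride a sample spans ~20 s of activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import SpikeData, Trajectory

logger = logging.getLogger("placedecode")

__all__ = [
    "WindowedCounts",
    "SequenceDataset",
    "count_in_windows",
    "build_sequences",
    "knockout_unit",
    "downsample_units",
]


@dataclass
class WindowedCounts:
    """units x windows integer spike counts on an arithmetic window grid."""

    counts: np.ndarray            # (units, windows) int
    window_centers: np.ndarray    # (windows,) s
    window_len_s: float
    stride_s: float
    unit_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be units x windows")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        if self.counts.shape[1] != self.window_centers.size:
            raise ValueError("one centre per window required")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_windows(self) -> int:
        return self.counts.shape[1]

    @property
    def overlap_fraction(self) -> float:
        """Overlap of consecutive windows, 1 - stride/window_len."""
        return max(1.0 - self.stride_s / self.window_len_s, 0.0)


@dataclass
class SequenceDataset:
    """samples x seq_len x units count sequences with position targets.

    Sample ``s`` covers window columns ``[s, s + seq_len - 1]`` of the
    underlying count matrix; its target is the position at the centre of its
    last window.  ``inputs`` is a zero-copy sliding view into that matrix.
    """

    counts_wn: np.ndarray          # (windows, units) base matrix
    targets: np.ndarray            # (samples, dims)
    sample_to_window: np.ndarray   # (samples,) index of each sample's last window
    seq_len: int
    unit_ids: list[str]
    window_centers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def _view(self) -> np.ndarray:
        """(W - seq_len + 1, seq_len, units) zero-copy sliding view, one row
        per possible first-window index."""
        view = np.lib.stride_tricks.sliding_window_view(
            self.counts_wn, self.seq_len, axis=0)  # (rows, units, seq_len)
        return view.transpose(0, 2, 1)

    @property
    def inputs(self) -> np.ndarray:
        """(samples, seq_len, units); zero-copy when no sample was dropped."""
        view = self._view()
        first = self.sample_to_window - self.seq_len + 1
        if len(first) == view.shape[0] and first[0] == 0:
            return view
        return view[first]

    @property
    def n_samples(self) -> int:
        return len(self.sample_to_window)

    @property
    def dims(self) -> int:
        return self.targets.shape[1]

    def target_times(self) -> np.ndarray:
        return self.window_centers[self.sample_to_window]

    def take(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Materialised (inputs, targets) for the given sample indices."""
        first = self.sample_to_window[idx] - self.seq_len + 1
        return self._view()[first], self.targets[idx]


def count_in_windows(spikes: SpikeData, window_len_s: float, stride_s: float,
                     span: tuple[float, float] | None = None) -> WindowedCounts:
    """Count spikes per unit in sliding half-open windows.

    Window ``w`` covers ``[start + w*stride, start + w*stride + L)``; a spike
    exactly at a window start is counted, one at the end is not.  Windows
    running past the span end are dropped.
    """
    if not (window_len_s >= stride_s > 0):
        raise ValueError("need window_len_s >= stride_s > 0")
    t0, t1 = span if span is not None else spikes.session_span
    if t1 <= t0:
        raise ValueError("empty span")
    n_win = int(np.floor((t1 - t0 - window_len_s) / stride_s + 1e-9)) + 1
    if n_win < 1:
        raise ValueError("span shorter than one window")
    starts = t0 + np.arange(n_win) * stride_s
    counts = np.zeros((spikes.n_units, n_win), dtype=np.int64)
    for i, times in enumerate(spikes.spike_times):
        counts[i] = (np.searchsorted(times, starts + window_len_s, "left")
                     - np.searchsorted(times, starts, "left"))
    return WindowedCounts(counts, starts + window_len_s / 2.0,
                          window_len_s, stride_s, list(spikes.unit_ids))


def build_sequences(wc: WindowedCounts, traj: Trajectory,
                    seq_len: int) -> SequenceDataset:
    """One sample per last-window index in ``[seq_len-1, W-1]``; targets are
    positions interpolated at window centres.  Samples whose target time
    falls outside the trajectory span are dropped (count logged)."""
    if seq_len < 1 or seq_len > wc.n_windows:
        raise ValueError("need 1 <= seq_len <= number of windows")
    last = np.arange(seq_len - 1, wc.n_windows)
    t = wc.window_centers[last]
    lo, hi = traj.span
    ok = (t >= lo) & (t <= hi)
    if not ok.all():
        logger.info("build_sequences: dropped %d samples outside tracking",
                    int((~ok).sum()))
    last = last[ok]
    pos = traj.interp(wc.window_centers[last])
    targets = pos.reshape(len(last), -1)
    if not np.all(np.isfinite(targets)):
        raise ValueError("non-finite targets")
    return SequenceDataset(
        counts_wn=np.ascontiguousarray(wc.counts.T),
        targets=targets,
        sample_to_window=last,
        seq_len=seq_len,
        unit_ids=list(wc.unit_ids),
        window_centers=wc.window_centers,
    )


def knockout_unit(data, unit: str):
    """Copy of ``data`` with one unit's counts zeroed (input untouched).

    Works on :class:`WindowedCounts` and :class:`SequenceDataset`; this is
    the evaluation-time silencing used by knockout sensitivity analysis.
    """
    if unit not in data.unit_ids:
        raise KeyError(f"unknown unit {unit!r}")
    j = data.unit_ids.index(unit)
    if isinstance(data, WindowedCounts):
        counts = data.counts.copy()
        counts[j] = 0
        return WindowedCounts(counts, data.window_centers.copy(),
                              data.window_len_s, data.stride_s,
                              list(data.unit_ids))
    if isinstance(data, SequenceDataset):
        base = data.counts_wn.copy()
        base[:, j] = 0
        return SequenceDataset(base, data.targets, data.sample_to_window,
                               data.seq_len, list(data.unit_ids),
                               data.window_centers)
    raise TypeError(f"unsupported type {type(data).__name__}")


def downsample_units(spikes: SpikeData, k: int, seed: int) -> SpikeData:
    """Uniform random subset of ``k`` units without replacement.

    ``k == n`` returns the population unchanged (original order); the subset
    is deterministic per seed.
    """
    n = spikes.n_units
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return spikes.subset(spikes.unit_ids)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return spikes.subset([spikes.unit_ids[i] for i in idx])
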