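"""Domain types and delimited-table I/O for place-cell decoding sessions.

A session consists of per-unit spike times (seconds) and a tracked position
trace (nominally 50 Hz; 2D x,y in cm for an open-field box, or 1D arc-length
in cm for a linearised track).  Everything downstream — windowed counts,
ratemaps, decoders — consumes these two containers.

Units: time is seconds everywhere in memory (config fields may carry an
``_ms`` suffix); position is cm with the origin at the arena corner, x
rightward, y upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("placedecode")

__all__ = [
    "ArenaSpec",
    "SpikeData",
    "Trajectory",
    "RunConfig",
    "SessionReport",
    "read_spikes",
    "write_spikes",
    "read_positions",
    "write_positions",
    "validate_session",
]


# ---------------------------------------------------------------------------
# arena geometry


@dataclass(frozen=True)
class ArenaSpec:
    """Arena geometry: a 2D box or a Z-shaped elevated track.

    The default box is the 1 m x 1 m open field.  The default Z-track has
    two parallel 190 cm arms joined by a 220 cm diagonal (total 600 cm);
    positions on it are expressed as arc length along the idealised
    polyline.
    """

    kind: str = "box2d"  # "box2d" | "ztrack"
    width_cm: float = 100.0
    height_cm: float = 100.0
    segment_lengths_cm: tuple[float, ...] = (190.0, 220.0, 190.0)
    corners: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("box2d", "ztrack"):
            raise ValueError(f"unknown arena kind {self.kind!r}")
        if self.kind == "box2d":
            if self.width_cm <= 0 or self.height_cm <= 0:
                raise ValueError("box dimensions must be positive")
        else:
            if any(s <= 0 for s in self.segment_lengths_cm):
                raise ValueError("track segment lengths must be positive")
            if self.corners is None:
                object.__setattr__(self, "corners", self._default_z_corners())

    def _default_z_corners(self) -> tuple[tuple[float, float], ...]:
        # Z laid out in a bounding box: top arm left->right, diagonal down
        # to the lower-left, bottom arm left->right.
        a1, diag, a3 = self.segment_lengths_cm
        h = float(np.sqrt(max(diag**2 - a1**2, 1.0)))
        return ((0.0, h), (a1, h), (0.0, 0.0), (a3, 0.0))

    @property
    def dims(self) -> int:
        return 2 if self.kind == "box2d" else 1

    @property
    def total_length_cm(self) -> float:
        """Arc length of the full track (ztrack only)."""
        return float(sum(self.segment_lengths_cm))

    def contains(self, positions: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Boolean mask of positions inside the arena (with slack ``tol`` cm)."""
        p = np.atleast_2d(positions)
        if self.kind == "box2d":
            return (
                (p[:, 0] >= -tol)
                & (p[:, 0] <= self.width_cm + tol)
                & (p[:, 1] >= -tol)
                & (p[:, 1] <= self.height_cm + tol)
            )
        s = positions.reshape(-1)
        return (s >= -tol) & (s <= self.total_length_cm + tol)

    def clamp(self, positions: np.ndarray) -> np.ndarray:
        if self.kind == "box2d":
            lo = np.array([0.0, 0.0])
            hi = np.array([self.width_cm, self.height_cm])
            return np.clip(positions, lo, hi)
        return np.clip(positions, 0.0, self.total_length_cm)


# ---------------------------------------------------------------------------
# spike trains and trajectories


@dataclass
class SpikeData:
    """Sorted spike times per unit over a recording session."""

    unit_ids: list[str]
    spike_times: list[np.ndarray]
    session_span: tuple[float, float]

    def __post_init__(self) -> None:
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("unit_ids must be unique")
        if len(self.unit_ids) != len(self.spike_times):
            raise ValueError("one spike-time array per unit required")
        self.spike_times = [np.asarray(t, dtype=float) for t in self.spike_times]
        for uid, t in zip(self.unit_ids, self.spike_times):
            if t.size and np.any(np.diff(t) < 0):
                raise ValueError(f"spike times of unit {uid!r} are not sorted")
        t0, t1 = self.session_span
        if t1 < t0:
            raise ValueError("session_span end precedes start")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times))

    def mean_rates_hz(self) -> np.ndarray:
        dur = self.session_span[1] - self.session_span[0]
        if dur <= 0:
            return np.zeros(self.n_units)
        return np.array([t.size / dur for t in self.spike_times])

    def restrict(self, t_start: float, t_end: float) -> "SpikeData":
        """Spikes within [t_start, t_end); span set to the restriction."""
        times = [t[(t >= t_start) & (t < t_end)] for t in self.spike_times]
        return SpikeData(list(self.unit_ids), times, (t_start, t_end))

    def subset(self, unit_ids: Sequence[str]) -> "SpikeData":
        idx = {u: i for i, u in enumerate(self.unit_ids)}
        missing = [u for u in unit_ids if u not in idx]
        if missing:
            raise KeyError(f"unknown units: {missing}")
        return SpikeData(
            list(unit_ids),
            [self.spike_times[idx[u]] for u in unit_ids],
            self.session_span,
        )


@dataclass
class Trajectory:
    """Timestamped tracked positions (50 Hz nominal)."""

    timestamps: np.ndarray
    positions: np.ndarray  # (n, 2) cm for box2d, (n,) or (n, 1) arc-length cm for ztrack
    arena: ArenaSpec

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.arena.dims == 1:
            self.positions = self.positions.reshape(-1)
        else:
            self.positions = self.positions.reshape(-1, 2)
        if len(self.timestamps) != len(self.positions):
            raise ValueError("timestamps and positions length mismatch")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.timestamps[0]), float(self.timestamps[-1])

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Positions linearly interpolated at times ``t`` (must lie in span)."""
        t = np.asarray(t, dtype=float)
        if self.arena.dims == 1:
            return np.interp(t, self.timestamps, self.positions)
        x = np.interp(t, self.timestamps, self.positions[:, 0])
        y = np.interp(t, self.timestamps, self.positions[:, 1])
        return np.column_stack([x, y])

    def restrict(self, t_start: float, t_end: float) -> "Trajectory":
        m = (self.timestamps >= t_start) & (self.timestamps <= t_end)
        return Trajectory(self.timestamps[m], self.positions[m], self.arena)

    def speeds_cm_s(self, half_width_s: float = 0.1) -> np.ndarray:
        """Instantaneous speed from displacement over ±half_width_s."""
        t = self.timestamps
        lo = self.interp(np.maximum(t - half_width_s, t[0]))
        hi = self.interp(np.minimum(t + half_width_s, t[-1]))
        dt = np.minimum(t + half_width_s, t[-1]) - np.maximum(t - half_width_s, t[0])
        dt = np.maximum(dt, 1e-9)
        if self.arena.dims == 1:
            d = np.abs(hi - lo)
        else:
            d = np.linalg.norm(hi - lo, axis=1)
        return d / dt


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Knobs shared by the decoding pipeline.

    Window lengths are scanned 200..4000 ms in 200 ms steps in the full
    protocol; ``window_len_ms`` holds the single length a run uses.
    """

    window_len_ms: float = 1400.0
    stride_ms: float = 200.0
    seq_len: int = 100
    bin_cm: float = 2.0
    smooth_sigma_bins: float = 1.5
    n_folds: int = 10
    n_repeats: int = 10
    memory_history: int = 15
    memory_scale: float = 1.0  # 1 for box2d, 5 for ztrack
    rate_floor_hz: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len_ms < self.stride_ms:
            raise ValueError("window_len_ms must be >= stride_ms")
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")

    @property
    def window_len_s(self) -> float:
        return self.window_len_ms / 1000.0

    @property
    def stride_s(self) -> float:
        return self.stride_ms / 1000.0

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# readers / writers


def read_spikes(path, *, session_span: tuple[float, float] | None = None,
                strict: bool = False) -> SpikeData:
    """Read a ``unit_id,time_s`` table into :class:`SpikeData`.

    Per-unit times are sorted; the session span defaults to (min, max) over
    all spikes.  Non-numeric times raise with the offending row number.
    """
    df = pd.read_csv(path)
    required = {"unit_id", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"spike table must have columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = times.isna() & df["time_s"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric time_s at data row {row}: "
                         f"{df['time_s'].iloc[row]!r}")
    if df.empty:
        if strict:
            raise ValueError("empty spike table")
        return SpikeData([], [], session_span or (0.0, 0.0))
    unit_ids = sorted(df["unit_id"].astype(str).unique())
    grouped = {u: np.sort(times[df["unit_id"].astype(str) == u].to_numpy())
               for u in unit_ids}
    span = session_span or (float(times.min()), float(times.max()))
    return SpikeData(unit_ids, [grouped[u] for u in unit_ids], span)


def write_spikes(spikes: SpikeData, path) -> None:
    rows = [
        {"unit_id": u, "time_s": t}
        for u, times in zip(spikes.unit_ids, spikes.spike_times)
        for t in times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


def read_positions(path, arena: ArenaSpec, *, clamp_tol_cm: float = 5.0,
                   strict: bool = False) -> Trajectory:
    """Read a position table into a :class:`Trajectory`.

    Columns are ``time_s,x_cm,y_cm`` (box) or ``time_s,s_cm`` (track).
    Duplicate timestamps are dropped (count logged); time decreases are
    rejected.  Positions outside the arena are clamped with a warning, or
    rejected in strict mode.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("position table must have a time_s column")
    if arena.dims == 2:
        cols = ["x_cm", "y_cm"]
    else:
        cols = ["s_cm"]
    if not set(cols).issubset(df.columns):
        raise ValueError(f"position table must have columns {cols}")
    t = pd.to_numeric(df["time_s"], errors="raise").to_numpy(dtype=float)
    pos = df[cols].to_numpy(dtype=float)

    keep = np.ones(len(t), dtype=bool)
    if len(t) > 1:
        dup = np.diff(t) == 0
        keep[1:][dup] = False
        if dup.any():
            logger.info("read_positions: dropped %d duplicate timestamps",
                        int(dup.sum()))
    t, pos = t[keep], pos[keep]
    if len(t) > 1 and np.any(np.diff(t) < 0):
        raise ValueError("timestamps decrease; trajectory is not time-ordered")

    inside = arena.contains(pos, tol=0.0)
    if not inside.all():
        worst = pos[~inside]
        beyond = ~arena.contains(worst, tol=clamp_tol_cm)
        if strict or beyond.any():
            raise ValueError(
                f"{int((~inside).sum())} positions outside the arena "
                f"(max excursion beyond tolerance: {beyond.any()})")
        logger.warning("read_positions: clamped %d out-of-arena positions",
                       int((~inside).sum()))
        pos = arena.clamp(pos)
    return Trajectory(t, pos if arena.dims == 2 else pos[:, 0], arena)


def write_positions(traj: Trajectory, path) -> None:
    if traj.arena.dims == 2:
        df = pd.DataFrame({"time_s": traj.timestamps,
                           "x_cm": traj.positions[:, 0],
                           "y_cm": traj.positions[:, 1]})
    else:
        df = pd.DataFrame({"time_s": traj.timestamps, "s_cm": traj.positions})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# session validation


@dataclass
class SessionReport:
    usable_span: tuple[float, float]
    n_units: int
    mean_rates_hz: np.ndarray
    silent_units: list[str]
    frac_spikes_outside_tracking: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        t0, t1 = self.usable_span
        lines = [
            f"usable span          : [{t0:.2f}, {t1:.2f}] s ({t1 - t0:.1f} s)",
            f"units                : {self.n_units}"
            + (f" ({len(self.silent_units)} silent)" if self.silent_units else ""),
            f"mean rate            : {np.nanmean(self.mean_rates_hz):.2f} Hz",
            f"spikes outside track : {100 * self.frac_spikes_outside_tracking:.2f}%",
        ]
        return "\n".join(lines)


def validate_session(spikes: SpikeData, traj: Trajectory) -> SessionReport:
    """Check spike/tracking alignment; the usable span is the exact
    intersection of the two time ranges.  Zero overlap is an error; silent
    units are flagged but retained."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    s0, s1 = spikes.session_span
    p0, p1 = traj.span
    lo, hi = max(s0, p0), min(s1, p1)
    if hi <= lo:
        raise ValueError(
            f"no temporal overlap between spikes [{s0}, {s1}] and tracking "
            f"[{p0}, {p1}]")
    total = spikes.total_spikes
    inside = sum(int(((t >= p0) & (t <= p1)).sum()) for t in spikes.spike_times)
    dur = hi - lo
    rates = np.array([
        ((t >= lo) & (t <= hi)).sum() / dur for t in spikes.spike_times
    ])
    silent = [u for u, r in zip(spikes.unit_ids, rates) if r == 0]
    for u in silent:
        logger.info("validate_session: unit %r is silent in the usable span", u)
    return SessionReport(
        usable_span=(lo, hi),
        n_units=spikes.n_units,
        mean_rates_hz=rates,
        silent_units=silent,
        frac_spikes_outside_tracking=0.0 if total == 0 else 1 - inside / total,
    )
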