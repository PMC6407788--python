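"""Synthetic place-cell sessions: trajectory + tuning + spikes.

The simulator produces sessions with the statistical structure the decoders
assume: Gaussian place fields tiling the arena, inhomogeneous-Poisson
spiking (optionally gamma-modulated to make counts super-Poisson, since real
place-cell variability exceeds a Poisson process), a few high-rate weakly
tuned interneuron-like units, 50 Hz tracking, and either open-field foraging
(Ornstein-Uhlenbeck velocity with wall reflection and stationary pauses) or
Z-track lap running with dwell pauses at corners and ends.

Every output is a pure function of (config, seed): the master seed spawns
deterministic child seeds per component.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .io import ArenaSpec, SpikeData, Trajectory

__all__ = [
    "SimConfig",
    "TuningSet",
    "simulate_trajectory_2d",
    "simulate_trajectory_z",
    "make_tuning_set",
    "generate_spikes",
    "simulate_session",
]


@dataclass
class SimConfig:
    """Defaults mirror the default synthetic benchmark: 40 place units plus
    3 interneurons over a 20-minute session (recorded sessions in this
    setting run ~18-45 min with 26-72 units)."""

    n_place_units: int = 40
    n_interneurons: int = 3
    duration_s: float = 1200.0
    sample_rate_hz: float = 50.0
    mean_speed_cm_s: float = 12.0
    pause_prob: float = 0.05       # per-second probability of initiating a pause
    mean_pause_s: float = 2.0
    overdispersion_k: float = 3.0  # gamma shape; np.inf = pure Poisson
    rng_seed: int = 0

    # tuning-curve draws
    field_sigma_range_cm: tuple[float, float] = (5.0, 10.0)
    peak_rate_range_hz: tuple[float, float] = (5.0, 20.0)
    baseline_rate_range_hz: tuple[float, float] = (0.05, 0.5)
    interneuron_rate_factor: float = 4.0  # x the top place-unit peak

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not self.overdispersion_k > 0:
            raise ValueError("overdispersion_k must be > 0 (inf for Poisson)")


@dataclass
class TuningSet:
    """Ground-truth tuning parameters per unit."""

    unit_ids: list[str]
    field_center: np.ndarray       # (n, dims) cm
    field_sigma_cm: np.ndarray     # (n,)
    peak_rate_hz: np.ndarray       # (n,)
    baseline_rate_hz: np.ndarray   # (n,)
    unit_class: list[str]          # "place" | "interneuron"

    def __post_init__(self) -> None:
        if np.any(self.baseline_rate_hz < 0):
            raise ValueError("baseline rates must be >= 0")
        if np.any(self.peak_rate_hz < self.baseline_rate_hz):
            raise ValueError("peak rate must be >= baseline rate")
        place = np.array([c == "place" for c in self.unit_class])
        if place.any() and np.any(self.field_sigma_cm[place] <= 0):
            raise ValueError("place-field sigma must be positive")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def rate_at(self, positions: np.ndarray, unit: int) -> np.ndarray:
        """Instantaneous rate lambda_i at positions (cm), vectorised."""
        p = np.asarray(positions, dtype=float)
        c = self.field_center[unit]
        if p.ndim == 1 and c.size == 1:
            d2 = (p - c[0]) ** 2
        else:
            d2 = np.sum((np.atleast_2d(p) - c) ** 2, axis=-1)
        b, pk, sig = (self.baseline_rate_hz[unit], self.peak_rate_hz[unit],
                      self.field_sigma_cm[unit])
        return b + (pk - b) * np.exp(-d2 / (2.0 * sig**2))


def _child_seed(seed: int, label: str) -> np.random.Generator:
    # stable across processes (unlike hash())
    tag = zlib.crc32(label.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def simulate_trajectory_2d(cfg: SimConfig, arena: ArenaSpec) -> Trajectory:
    """Open-field foraging: heading-persistent OU velocity, reflecting walls,
    stationary pauses entered at rate ``pause_prob`` per second.

    The OU stationary speed is calibrated so the session-mean speed
    (pauses included) matches ``mean_speed_cm_s``.
    """
    if arena.kind != "box2d":
        raise ValueError("simulate_trajectory_2d needs a box2d arena")
    rng = _child_seed(cfg.rng_seed, "traj2d")
    dt = 1.0 / cfg.sample_rate_hz
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    theta = 1.0  # 1/s velocity relaxation
    pause_frac = (cfg.pause_prob * cfg.mean_pause_s
                  / (1.0 + cfg.pause_prob * cfg.mean_pause_s))
    target_moving = cfg.mean_speed_cm_s / max(1.0 - pause_frac, 1e-9)
    sigma_c = target_moving * np.sqrt(2.0 / np.pi)  # per-component velocity std
    sigma_v = sigma_c * np.sqrt(2.0 * theta)

    pos = np.empty((n, 2))
    p = np.array([arena.width_cm / 2.0, arena.height_cm / 2.0])
    v = rng.normal(0, sigma_c, size=2)
    lo = np.zeros(2)
    hi = np.array([arena.width_cm, arena.height_cm])
    pause_left = 0.0
    noise = rng.normal(0.0, 1.0, size=(n, 2))
    pause_draws = rng.random(n)
    pause_lens = rng.exponential(cfg.mean_pause_s, size=n)
    for i in range(n):
        if pause_left > 0:
            pause_left -= dt
        else:
            if pause_draws[i] < cfg.pause_prob * dt:
                pause_left = pause_lens[i]
            else:
                v = v + (-theta * v) * dt + sigma_v * np.sqrt(dt) * noise[i]
                p = p + v * dt
                # reflect at walls
                for d in range(2):
                    if p[d] < lo[d]:
                        p[d] = 2 * lo[d] - p[d]
                        v[d] = -v[d]
                    elif p[d] > hi[d]:
                        p[d] = 2 * hi[d] - p[d]
                        v[d] = -v[d]
                p = np.clip(p, lo, hi)
        pos[i] = p
    t = np.arange(n) * dt
    return Trajectory(t, pos, arena)


def simulate_trajectory_z(cfg: SimConfig, arena: ArenaSpec) -> Trajectory:
    """Lap running on the Z-track in arc-length coordinates.

    The animal shuttles between 0 and the total track length at roughly
    ``mean_speed_cm_s`` with small OU speed fluctuations, dwelling at the
    corners and ends (reward sites) with mean ``mean_pause_s`` when
    ``pause_prob`` > 0; direction reverses at the ends.
    """
    if arena.kind != "ztrack":
        raise ValueError("simulate_trajectory_z needs a ztrack arena")
    rng = _child_seed(cfg.rng_seed, "trajz")
    dt = 1.0 / cfg.sample_rate_hz
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    total = arena.total_length_cm
    stops = np.concatenate([[0.0], np.cumsum(arena.segment_lengths_cm)])
    pos = np.empty(n)
    s = 0.0
    direction = 1.0
    speed = cfg.mean_speed_cm_s
    theta = 1.0
    sigma = 0.3 * cfg.mean_speed_cm_s * np.sqrt(2 * theta)
    dwell_left = 0.0
    passed_stop = np.zeros(len(stops), dtype=bool)
    noise = rng.normal(0.0, 1.0, size=n)
    dwell_lens = rng.exponential(cfg.mean_pause_s, size=n)
    dwell_draws = rng.random(n)
    for i in range(n):
        if dwell_left > 0:
            dwell_left -= dt
        else:
            speed = speed + theta * (cfg.mean_speed_cm_s - speed) * dt \
                + sigma * np.sqrt(dt) * noise[i]
            speed = max(speed, 0.0)
            s_new = s + direction * speed * dt
            # dwell when crossing a corner/end (reward sites)
            for j, stop in enumerate(stops):
                crossed = (s - stop) * (s_new - stop) < 0 or s_new in (0.0, total)
                if crossed and not passed_stop[j]:
                    if cfg.pause_prob > 0 and dwell_draws[i] < 0.8:
                        dwell_left = dwell_lens[i]
                    passed_stop[:] = False
                    passed_stop[j] = True
            if s_new >= total:
                s_new = total
                direction = -1.0
                passed_stop[:] = False
            elif s_new <= 0.0:
                s_new = 0.0
                direction = 1.0
                passed_stop[:] = False
            s = s_new
        pos[i] = s
    t = np.arange(n) * dt
    return Trajectory(t, pos, arena)


def make_tuning_set(cfg: SimConfig, arena: ArenaSpec,
                    seed: int | None = None) -> TuningSet:
    """Draw ground-truth tuning: place-field centres uniform over the arena,
    widths/peaks/baselines uniform in the configured ranges; interneurons get
    a rate several-fold above the top place-unit peak and no spatial
    modulation."""
    rng = _child_seed(seed if seed is not None else cfg.rng_seed, "tuning")
    n_p, n_i = cfg.n_place_units, cfg.n_interneurons
    if n_p < 0 or n_i < 0:
        raise ValueError("unit counts must be >= 0")
    n = n_p + n_i
    dims = arena.dims
    if dims == 2:
        centers = np.column_stack([
            rng.uniform(0, arena.width_cm, size=n),
            rng.uniform(0, arena.height_cm, size=n),
        ])
    else:
        centers = rng.uniform(0, arena.total_length_cm, size=(n, 1))
    sigmas = rng.uniform(*cfg.field_sigma_range_cm, size=n)
    peaks = rng.uniform(*cfg.peak_rate_range_hz, size=n)
    bases = rng.uniform(*cfg.baseline_rate_range_hz, size=n)
    classes = ["place"] * n_p + ["interneuron"] * n_i
    if n_i:
        top_peak = peaks[:n_p].max() if n_p else cfg.peak_rate_range_hz[1]
        inter_rate = cfg.interneuron_rate_factor * top_peak \
            * rng.uniform(0.9, 1.1, size=n_i)
        bases[n_p:] = inter_rate
        peaks[n_p:] = inter_rate  # flat: no spatial modulation
        sigmas[n_p:] = max(arena.width_cm if dims == 2 else arena.total_length_cm, 1.0)
    ids = [f"p{i:03d}" for i in range(n_p)] + [f"i{i:03d}" for i in range(n_i)]
    return TuningSet(ids, centers, sigmas, peaks, bases, classes)


def generate_spikes(tuning: TuningSet, traj: Trajectory,
                    cfg: SimConfig) -> SpikeData:
    """Inhomogeneous-Poisson spikes by thinning.

    lambda_i(t) = baseline + (peak - baseline) * exp(-||pos(t) - c||^2 / 2 sigma^2),
    with the position interpolated from the tracking trace.  When
    ``overdispersion_k`` is finite the rate is multiplied, per 1-s block, by
    an independent Gamma(k, 1/k) variate (mean 1), producing gamma-Poisson
    mixture counts with Fano factor > 1.
    """
    rng = _child_seed(cfg.rng_seed, "spikes")
    t0, t1 = traj.span
    dur = t1 - t0
    n_blocks = max(int(np.ceil(dur)), 1)
    all_times = []
    for u in range(tuning.n_units):
        if np.isfinite(cfg.overdispersion_k):
            gains = rng.gamma(cfg.overdispersion_k, 1.0 / cfg.overdispersion_k,
                              size=n_blocks)
        else:
            gains = np.ones(n_blocks)
        lam_max = tuning.peak_rate_hz[u] * gains.max()
        if lam_max <= 0:
            all_times.append(np.array([]))
            continue
        n_prop = rng.poisson(lam_max * dur)
        prop = np.sort(rng.uniform(t0, t1, size=n_prop))
        if n_prop == 0:
            all_times.append(prop)
            continue
        lam = tuning.rate_at(traj.interp(prop), u)
        block = np.minimum(((prop - t0)).astype(int), n_blocks - 1)
        lam = lam * gains[block]
        accept = rng.uniform(0, lam_max, size=n_prop) < lam
        all_times.append(prop[accept])
    return SpikeData(list(tuning.unit_ids), all_times, (t0, t1))


def simulate_session(cfg: SimConfig, arena: ArenaSpec | None = None
                     ) -> tuple[SpikeData, Trajectory, TuningSet]:
    """Convenience driver: trajectory + tuning + spikes from one config."""
    arena = arena or ArenaSpec()
    if arena.kind == "box2d":
        traj = simulate_trajectory_2d(cfg, arena)
    else:
        traj = simulate_trajectory_z(cfg, arena)
    tuning = make_tuning_set(cfg, arena)
    spikes = generate_spikes(tuning, traj, cfg)
    return spikes, traj, tuning
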