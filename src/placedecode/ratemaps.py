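"""Occupancy, smoothed firing-rate maps, the occupancy prior, and Skaggs
spatial information.

Spikes and dwell time are binned into 2 cm bins (square for the open field,
arc-length segments for the linearised track), each map is smoothed with a
truncated Gaussian kernel (sigma = 1.5 bins, radius 4 sigma), and the rate
is the ratio of smoothed spike counts to smoothed dwell time.  Smoothing
redistributes each source bin's mass over *visited* bins with renormalised
kernel weights, so total spike mass is conserved exactly and unvisited bins
never receive mass; away from edges this equals plain convolution.

Rates on visited bins are floored at ``rate_floor_hz`` so that Poisson
log-likelihoods (k * log rate) stay finite; unvisited bins carry no rate and
are excluded from decoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import SpikeData, Trajectory

logger = logging.getLogger("placedecode")

__all__ = [
    "RatemapSet",
    "OccupancyPrior",
    "compute_occupancy",
    "compute_ratemaps",
    "occupancy_prior",
    "skaggs_information",
]


@dataclass
class RatemapSet:
    """Per-unit firing-rate maps alpha_i(x) over visited spatial bins."""

    bin_centers: np.ndarray    # (bins, dims) cm, flattened grid
    occupancy_s: np.ndarray    # (bins,) raw dwell seconds
    rate_hz: np.ndarray        # (units, bins); NaN off the visited mask
    visited_mask: np.ndarray   # (bins,) bool
    unit_ids: list[str]
    bin_cm: float
    grid_shape: tuple[int, ...]

    @property
    def n_units(self) -> int:
        return self.rate_hz.shape[0]

    @property
    def visited_rates(self) -> np.ndarray:
        """(units, visited bins) — the decoding-ready rate matrix."""
        return self.rate_hz[:, self.visited_mask]

    @property
    def visited_centers(self) -> np.ndarray:
        return self.bin_centers[self.visited_mask]


@dataclass
class OccupancyPrior:
    """p(x): normalised dwell probability over visited bins."""

    prob: np.ndarray  # (visited bins,), sums to 1

    def __post_init__(self) -> None:
        if np.any(self.prob < 0):
            raise ValueError("prior probabilities must be non-negative")
        if abs(self.prob.sum() - 1.0) > 1e-9:
            raise ValueError("prior must sum to 1")


def _grid(traj_arena, bin_cm: float):
    """Bin edges / centres for the arena of a trajectory."""
    a = traj_arena
    if a.dims == 2:
        nx = max(int(np.ceil(a.width_cm / bin_cm)), 1)
        ny = max(int(np.ceil(a.height_cm / bin_cm)), 1)
        ex = np.arange(nx + 1) * bin_cm
        ey = np.arange(ny + 1) * bin_cm
        cx = (ex[:-1] + ex[1:]) / 2
        cy = (ey[:-1] + ey[1:]) / 2
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        centers = np.column_stack([gx.ravel(), gy.ravel()])
        return (ex, ey), centers, (nx, ny)
    n = max(int(np.ceil(a.total_length_cm / bin_cm)), 1)
    e = np.arange(n + 1) * bin_cm
    centers = ((e[:-1] + e[1:]) / 2).reshape(-1, 1)
    return (e,), centers, (n,)


def _bin_index(positions: np.ndarray, edges, grid_shape) -> np.ndarray:
    """Flat bin index of each position (clipped into the grid)."""
    if len(grid_shape) == 2:
        ix = np.clip(np.searchsorted(edges[0], positions[:, 0], "right") - 1,
                     0, grid_shape[0] - 1)
        iy = np.clip(np.searchsorted(edges[1], positions[:, 1], "right") - 1,
                     0, grid_shape[1] - 1)
        return ix * grid_shape[1] + iy
    s = positions.reshape(-1)
    return np.clip(np.searchsorted(edges[0], s, "right") - 1,
                   0, grid_shape[0] - 1)


def _gauss_kernel_1d(sigma_bins: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1)
    k = np.exp(-(x**2) / (2.0 * sigma_bins**2))
    return k / k.sum()


def _smooth_masked(values: np.ndarray, mask: np.ndarray, sigma_bins: float,
                   grid_shape) -> np.ndarray:
    """Mass-conserving truncated-Gaussian smoothing over visited bins.

    Each source bin's mass is spread over visited bins with kernel weights
    renormalised per source bin; with everything visited and away from edges
    this is ordinary separable convolution.
    """
    if sigma_bins <= 0:
        return values * mask
    from scipy.ndimage import convolve

    radius = int(np.ceil(4.0 * sigma_bins))
    k1 = _gauss_kernel_1d(sigma_bins, radius)
    v = (values * mask).reshape(grid_shape)
    m = mask.astype(float).reshape(grid_shape)
    if len(grid_shape) == 2:
        kern = np.outer(k1, k1)
    else:
        kern = k1
    # per-source normaliser: kernel mass landing on visited bins
    norm = convolve(m, kern, mode="constant", cval=0.0)
    src = np.where(m > 0, v / np.maximum(norm, 1e-300), 0.0)
    out = convolve(src, kern, mode="constant", cval=0.0) * m
    return out.ravel()


def compute_occupancy(traj: Trajectory, bin_cm: float = 2.0):
    """Dwell seconds per bin: each tracking sample contributes its
    inter-sample interval (the last sample contributes nothing), so the
    total equals the tracked duration exactly.

    Returns ``(occupancy_s, bin_centers, grid_shape)``.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    edges, centers, shape = _grid(traj.arena, bin_cm)
    pos = traj.positions if traj.arena.dims == 2 else traj.positions.reshape(-1, 1)
    idx = _bin_index(pos, edges, shape)
    dt = np.diff(traj.timestamps, append=traj.timestamps[-1])
    occ = np.bincount(idx, weights=dt, minlength=int(np.prod(shape)))
    return occ, centers, shape


def compute_ratemaps(spikes: SpikeData, traj: Trajectory, bin_cm: float = 2.0,
                     sigma_bins: float = 1.5,
                     rate_floor_hz: float = 0.01) -> RatemapSet:
    """Smoothed per-unit ratemaps: alpha_i = smoothed spikes / smoothed dwell.

    Spikes are assigned to the bin of the interpolated position at spike
    time; spikes outside the tracked span are ignored (a unit left with no
    spikes gets an all-floor map, with a warning).
    """
    occ, centers, shape = compute_occupancy(traj, bin_cm)
    edges, _, _ = _grid(traj.arena, bin_cm)
    visited = occ > 0
    occ_s = _smooth_masked(occ, visited, sigma_bins, shape)

    t0, t1 = traj.span
    n_bins = int(np.prod(shape))
    rate = np.full((spikes.n_units, n_bins), np.nan)
    for i, times in enumerate(spikes.spike_times):
        inside = times[(times >= t0) & (times <= t1)]
        if times.size and inside.size == 0:
            logger.warning("compute_ratemaps: unit %r has no spikes in the "
                           "tracked span; all-floor map",
                           spikes.unit_ids[i])
        pos = traj.interp(inside)
        pos = pos if traj.arena.dims == 2 else np.asarray(pos).reshape(-1, 1)
        smap = np.bincount(_bin_index(pos, edges, shape),
                           minlength=n_bins).astype(float)
        smap = _smooth_masked(smap, visited, sigma_bins, shape)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(visited & (occ_s > 0), smap / np.maximum(occ_s, 1e-300),
                         np.nan)
        r[visited] = np.maximum(r[visited], rate_floor_hz)
        rate[i] = r
    return RatemapSet(centers, occ, rate, visited, list(spikes.unit_ids),
                      bin_cm, shape)


def occupancy_prior(occupancy_s: np.ndarray, visited_mask: np.ndarray | None = None,
                    mode: str = "train_only") -> OccupancyPrior:
    """Normalise occupancy over visited bins into p(x).

    ``mode`` records which data segment produced the occupancy — the
    training split (leakage-safe default) or the full trial; the caller
    passes the matching occupancy array.
    """
    if mode not in ("train_only", "full_trial"):
        raise ValueError(f"unknown mode {mode!r}")
    occ = np.asarray(occupancy_s, dtype=float)
    if visited_mask is not None:
        occ = occ[visited_mask]
    total = occ.sum()
    if total <= 0:
        raise ValueError("all-zero occupancy")
    return OccupancyPrior(occ / total)


def skaggs_information(rate_map: np.ndarray, occupancy: np.ndarray) -> float:
    """Spatial information in bits per spike (Skaggs-style score from the
    place-field literature): sum_i p_i (l_i / lbar) log2(l_i / lbar) with
    lbar = sum_i p_i l_i.  Returns NaN for a silent unit."""
    r = np.asarray(rate_map, dtype=float).ravel()
    occ = np.asarray(occupancy, dtype=float).ravel()
    ok = np.isfinite(r) & (occ > 0)
    r, occ = r[ok], occ[ok]
    if r.size == 0:
        return float("nan")
    p = occ / occ.sum()
    lbar = float(np.sum(p * r))
    if lbar <= 0:
        return float("nan")
    ratio = r / lbar
    terms = np.where(ratio > 0, p * ratio * np.log2(np.maximum(ratio, 1e-300)), 0.0)
    return float(np.sum(terms))
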