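"""Poisson-likelihood Bayesian position decoding.

Given a spike-count vector K = (k_1..k_N) observed in a window of length T
and per-unit ratemaps alpha_i(x) over visited spatial bins, the likelihood
is the independent-Poisson product

    P(K|x) = prod_i (T alpha_i(x))^{k_i} / k_i! * exp(-T alpha_i(x)).

The flat-prior decoder normalises this over visited bins and reads out the
argmax bin centre (maximum likelihood).  The memory decoder multiplies in
the occupancy prior p(x) and, sequentially, a continuity term: a Gaussian in
the distance from each bin centre to the previously decoded position, with
sigma equal to the mean decoded step displacement over the last (up to) 15
steps times a scale factor (1 open field, 5 linear track), floored at
``min_sigma_cm``.

All likelihood math is in the log domain (log k! via gammaln); direct
products overflow for long windows with high-rate units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .features import WindowedCounts
from .io import RunConfig, SpikeData, Trajectory, validate_session
from .ratemaps import (OccupancyPrior, RatemapSet, compute_occupancy,
                       compute_ratemaps, occupancy_prior, skaggs_information)

__all__ = [
    "Posterior",
    "MemoryParams",
    "DecodedPath",
    "log_likelihood_map",
    "decode_flat",
    "decode_with_memory",
    "BayesianPositionDecoder",
    "BayesianDecoderResults",
]


@dataclass
class Posterior:
    """Per-window posterior over visited bins."""

    log_prob: np.ndarray  # (windows, visited bins), normalised in log domain
    bin_centers: np.ndarray

    @property
    def prob(self) -> np.ndarray:
        return np.exp(self.log_prob)


@dataclass
class MemoryParams:
    """Continuity-constraint parameters of the memory decoder."""

    history_len: int = 15
    scale: float = 1.0       # 1 open field, 5 linear track
    min_sigma_cm: float = 2.0  # one bin; keeps a stationary decode from collapsing

    def __post_init__(self) -> None:
        if self.history_len < 1:
            raise ValueError("history_len must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.min_sigma_cm <= 0:
            raise ValueError("min_sigma_cm must be positive")

    @property
    def continuity_disabled(self) -> bool:
        """scale = inf switches the continuity term off entirely."""
        return np.isinf(self.scale)


@dataclass
class DecodedPath:
    """Decoded bin centres per window (always visited-bin centres)."""

    positions: np.ndarray      # (windows, dims) cm
    bin_idx: np.ndarray        # (windows,) index into visited bins
    window_centers: np.ndarray
    posterior: Posterior | None = None


def _check_alignment(wc: WindowedCounts, maps: RatemapSet) -> None:
    if list(wc.unit_ids) != list(maps.unit_ids):
        raise ValueError("unit order of counts and ratemaps differ")


def log_likelihood_map(counts_k: np.ndarray, maps: RatemapSet,
                       T: float) -> np.ndarray:
    """log P(K|x) over visited bins for one window's counts.

    Computed as sum_i [k_i log(T alpha_i(x)) - T alpha_i(x) - log k_i!];
    finite everywhere because visited-bin rates are floored.
    """
    k = np.asarray(counts_k, dtype=float)
    if np.any(k < 0):
        raise ValueError("negative spike counts")
    if T <= 0:
        raise ValueError("window length must be positive")
    rates = maps.visited_rates  # (units, bins)
    if k.size != rates.shape[0]:
        raise ValueError("counts length does not match unit count")
    ll = k @ np.log(T * rates) - T * rates.sum(axis=0) - gammaln(k + 1).sum()
    return ll


def _normalise_rows(ll: np.ndarray) -> np.ndarray:
    return ll - logsumexp(ll, axis=1, keepdims=True)


def decode_flat(wc: WindowedCounts, maps: RatemapSet,
                return_posterior: bool = True) -> DecodedPath:
    """Maximum-likelihood decoding with a flat position prior.

    Per window the posterior is the normalised Poisson likelihood over
    visited bins; the decoded position is the argmax bin centre (ties to the
    lowest bin index).
    """
    _check_alignment(wc, maps)
    T = wc.window_len_s
    rates = maps.visited_rates
    log_rates = np.log(T * rates)
    const = -T * rates.sum(axis=0)
    k = wc.counts.T.astype(float)  # (windows, units)
    ll = k @ log_rates + const - gammaln(k + 1).sum(axis=1, keepdims=True)
    log_post = _normalise_rows(ll)
    idx = np.argmax(log_post, axis=1)
    centers = maps.visited_centers
    post = Posterior(log_post, centers) if return_posterior else None
    return DecodedPath(centers[idx], idx, wc.window_centers.copy(), post)


def decode_with_memory(wc: WindowedCounts, maps: RatemapSet,
                       prior: OccupancyPrior, mp: MemoryParams,
                       return_posterior: bool = False) -> DecodedPath:
    """Sequential decoding with occupancy prior and continuity constraint.

    Step t multiplies the prior-weighted likelihood by a Gaussian in the
    distance to the decoded position at t-1 whose sigma tracks recent
    decoded movement (see module docstring).  The first steps, before any
    decoded displacement exists, use prior x likelihood only.
    """
    _check_alignment(wc, maps)
    if prior.prob.size != maps.visited_centers.shape[0]:
        raise ValueError("prior length does not match visited bins")
    T = wc.window_len_s
    rates = maps.visited_rates
    log_rates = np.log(T * rates)
    const = -T * rates.sum(axis=0)
    k = wc.counts.T.astype(float)
    ll = k @ log_rates + const  # (windows, bins); per-window constants dropped
    with np.errstate(divide="ignore"):
        log_prior = np.log(prior.prob)
    centers = maps.visited_centers  # (bins, dims)

    n_win = wc.n_windows
    out_idx = np.empty(n_win, dtype=int)
    log_post_all = np.empty_like(ll) if return_posterior else None
    disp_hist: list[float] = []
    prev_pos: np.ndarray | None = None
    for t in range(n_win):
        lp = ll[t] + log_prior
        if prev_pos is not None and disp_hist and not mp.continuity_disabled:
            recent = disp_hist[-mp.history_len:]
            sigma = max(mp.scale * float(np.mean(recent)), mp.min_sigma_cm)
            d2 = np.sum((centers - prev_pos) ** 2, axis=1)
            lp = lp - d2 / (2.0 * sigma**2)
        lp = lp - logsumexp(lp)
        i = int(np.argmax(lp))
        out_idx[t] = i
        pos = centers[i]
        if prev_pos is not None:
            disp_hist.append(float(np.linalg.norm(pos - prev_pos)))
        prev_pos = pos
        if return_posterior:
            log_post_all[t] = lp
    post = Posterior(log_post_all, centers) if return_posterior else None
    return DecodedPath(centers[out_idx], out_idx, wc.window_centers.copy(), post)


# ---------------------------------------------------------------------------
# model / results presentation


class BayesianPositionDecoder:
    """Poisson Bayesian decoder as a fit/results pair.

    Construction takes the session; :meth:`fit` estimates the ratemaps and
    occupancy prior (optionally restricted to a training span) and returns a
    :class:`BayesianDecoderResults` that decodes windowed counts.
    """

    def __init__(self, spikes: SpikeData, trajectory: Trajectory,
                 config: RunConfig | None = None):
        self.spikes = spikes
        self.trajectory = trajectory
        self.config = config or RunConfig()
        self.report = validate_session(spikes, trajectory)

    def fit(self, train_intervals=None) -> "BayesianDecoderResults":
        """Estimate ratemaps/prior from the session (or the union of
        ``train_intervals`` = [(t0, t1), ...])."""
        cfg = self.config
        spikes, traj = self.spikes, self.trajectory
        if train_intervals is not None:
            traj_parts, spike_parts = [], None
            ts, ps = [], []
            for (a, b) in train_intervals:
                sub = traj.restrict(a, b)
                ts.append(sub.timestamps)
                ps.append(sub.positions)
            t_all = np.concatenate(ts)
            p_all = np.concatenate(ps)
            order = np.argsort(t_all)
            # restrict() on each interval + concatenation keeps per-interval
            # order; sort defensively against unordered interval lists
            traj = Trajectory(t_all[order],
                              p_all[order] if traj.arena.dims == 2
                              else p_all[order], traj.arena)
            times = []
            for tr in spikes.spike_times:
                keep = np.zeros(tr.size, dtype=bool)
                for (a, b) in train_intervals:
                    keep |= (tr >= a) & (tr < b)
                times.append(tr[keep])
            spikes = SpikeData(list(spikes.unit_ids), times, spikes.session_span)
        maps = compute_ratemaps(spikes, traj, cfg.bin_cm, cfg.smooth_sigma_bins,
                                cfg.rate_floor_hz)
        prior = occupancy_prior(maps.occupancy_s, maps.visited_mask,
                                mode="train_only" if train_intervals is not None
                                else "full_trial")
        return BayesianDecoderResults(self, maps, prior)


class BayesianDecoderResults:
    """Fitted ratemaps + prior with decode methods and a summary table."""

    def __init__(self, model: BayesianPositionDecoder, maps: RatemapSet,
                 prior: OccupancyPrior):
        self.model = model
        self.ratemaps = maps
        self.prior = prior

    def decode(self, wc: WindowedCounts, method: str = "flat",
               memory_params: MemoryParams | None = None,
               return_posterior: bool = False) -> DecodedPath:
        if method == "flat":
            return decode_flat(wc, self.ratemaps, return_posterior)
        if method == "memory":
            mp = memory_params or MemoryParams(
                history_len=self.model.config.memory_history,
                scale=self.model.config.memory_scale)
            return decode_with_memory(wc, self.ratemaps, self.prior, mp,
                                      return_posterior)
        raise ValueError(f"unknown method {method!r}")

    def summary(self) -> str:
        maps = self.ratemaps
        occ = maps.occupancy_s
        lines = [
            "Poisson Bayesian position decoder",
            "=" * 49,
            f"units: {maps.n_units}   visited bins: "
            f"{int(maps.visited_mask.sum())}/{maps.visited_mask.size} "
            f"({maps.bin_cm:g} cm)",
            f"tracked time: {occ.sum():.1f} s",
            "",
            f"{'unit':>8} {'mean rate Hz':>13} {'peak rate Hz':>13} "
            f"{'skaggs b/spk':>13}",
        ]
        for i, uid in enumerate(maps.unit_ids):
            r = maps.visited_rates[i]
            info = skaggs_information(r, occ[maps.visited_mask])
            mean_r = float(np.sum(r * occ[maps.visited_mask])
                           / occ[maps.visited_mask].sum())
            lines.append(f"{uid:>8} {mean_r:>13.3f} {np.nanmax(r):>13.2f} "
                         f"{info:>13.3f}")
        return "\n".join(lines)
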