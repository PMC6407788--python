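"""Knockout and gradient sensitivity analyses of a trained decoder.

Knockout without retraining: zero one unit's counts in the validation data,
re-predict, and measure the error increase — the larger the increase, the
more crucial the unit.  Gradient sensitivity: the magnitude of the loss
derivative with respect to every input count (a samples x seq_len x units
tensor from backpropagation through time), averaged along samples, units or
sequence position.  The two measures capture different notions of
importance (silencing vs small perturbation) but are expected to correlate
positively.

For the sensitivity-vs-rate curve, spike counts and gradient magnitudes are
normalised per unit by their own 99th percentile (the maximum is an outlier
for sparse units) before pooling across units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import SequenceDataset, knockout_unit
from .lstm import GradientTensor, LSTMRegressor

logger = logging.getLogger("placedecode")

__all__ = [
    "KnockoutReport",
    "GradientReport",
    "SensitivityCurve",
    "knockout_scan",
    "aggregate_gradients",
    "sensitivity_vs_rate_curve",
    "rank_correlation",
]


@dataclass
class KnockoutReport:
    """Per-unit knockout errors and ranking (rank 1 = most influential)."""

    table: pd.DataFrame  # unit, error_cm, delta_cm, rank
    baseline_error_cm: float
    baseline_std_cm: float = float("nan")

    def ranking(self) -> pd.Series:
        return self.table.set_index("unit")["rank"]


@dataclass
class GradientReport:
    unit_profile: pd.Series        # mean |grad| per unit
    temporal_profile: np.ndarray   # length seq_len
    grand_mean: float
    spatial_field: np.ndarray | None = None  # (units, bins) or None


@dataclass
class SensitivityCurve:
    """Mean normalised |gradient| per normalised-rate bin."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    mean_grad: np.ndarray
    n_per_bin: np.ndarray


def _euclid(pred: np.ndarray, targets: np.ndarray) -> np.ndarray:
    d = pred - targets
    if d.ndim == 1 or d.shape[1] == 1:
        return np.abs(d).reshape(-1)
    return np.linalg.norm(d, axis=1)


def knockout_scan(model: LSTMRegressor, val_data: SequenceDataset,
                  baseline_errors: np.ndarray | None = None,
                  baseline_std_cm: float = float("nan")) -> KnockoutReport:
    """Knockout-without-retraining scan over every unit.

    ``baseline_errors`` are the complete-model per-sample validation errors
    (computed here if omitted).  Deltas are vs the baseline mean; ranks are
    a permutation of 1..N with 1 the largest error increase.
    """
    if baseline_errors is None:
        baseline_errors = _euclid(model.predict(val_data.inputs),
                                  val_data.targets)
    base_mean = float(np.mean(baseline_errors))
    rows = []
    for unit in val_data.unit_ids:
        ko = knockout_unit(val_data, unit)
        err = _euclid(model.predict(ko.inputs), ko.targets)
        m = float(err.mean())
        rows.append({"unit": unit, "error_cm": m, "delta_cm": m - base_mean})
    df = pd.DataFrame(rows)
    # rank 1 = largest delta; ties broken by unit order for a true permutation
    order = np.lexsort((np.arange(len(df)), -df["delta_cm"].to_numpy()))
    rank = np.empty(len(df), dtype=int)
    rank[order] = np.arange(1, len(df) + 1)
    df["rank"] = rank
    return KnockoutReport(df, base_mean, baseline_std_cm)


def aggregate_gradients(g: GradientTensor, positions: np.ndarray | None = None,
                        bin_cm: float = 2.0,
                        grid_shape: tuple | None = None,
                        unit_ids: list[str] | None = None) -> GradientReport:
    """Average the D x T x N gradient tensor along its axes.

    Produces the per-unit profile (mean over samples and timesteps), the
    temporal profile (mean over samples and units), and — when per-sample
    true positions and a bin grid are supplied — a per-unit spatial
    "sensitivity field" that assigns each sample's final-timestep gradient
    to the bin of its true location.
    """
    a = g.abs_grad
    if a.ndim != 3:
        raise ValueError("gradient tensor must be samples x seq_len x units")
    n_units = a.shape[2]
    ids = unit_ids or [str(i) for i in range(n_units)]
    unit_profile = pd.Series(a.mean(axis=(0, 1)), index=ids)
    temporal = a.mean(axis=(0, 2))
    spatial = None
    if positions is not None and grid_shape is not None:
        pos = np.atleast_2d(np.asarray(positions, float))
        if pos.shape[0] != a.shape[0]:
            raise ValueError("one position per sample required")
        idx = np.zeros(len(pos), dtype=int)
        for d in range(pos.shape[1]):
            i_d = np.clip((pos[:, d] // bin_cm).astype(int), 0,
                          grid_shape[d] - 1)
            idx = idx * grid_shape[d] + i_d
        n_bins = int(np.prod(grid_shape))
        final = a[:, -1, :]  # (samples, units)
        counts = np.bincount(idx, minlength=n_bins)
        spatial = np.full((n_units, n_bins), np.nan)
        for u in range(n_units):
            s = np.bincount(idx, weights=final[:, u], minlength=n_bins)
            with np.errstate(invalid="ignore"):
                spatial[u] = np.where(counts > 0, s / np.maximum(counts, 1),
                                      np.nan)
    return GradientReport(unit_profile, temporal, float(a.mean()), spatial)


def sensitivity_vs_rate_curve(counts: np.ndarray, grads: np.ndarray,
                              pct: float = 99.0,
                              n_bins: int = 10) -> SensitivityCurve:
    """Normalised |gradient| as a function of normalised spike count.

    ``counts`` and ``grads`` are aligned (samples, seq_len, units) arrays.
    Each unit's counts and gradient magnitudes are divided by their own
    ``pct``-th percentile (so a few values exceed 1), pooled across units,
    and the mean normalised gradient is taken per normalised-count bin on
    [0, max].  Units with all-zero counts are excluded (logged).
    """
    c = np.asarray(counts, dtype=float)
    g = np.abs(np.asarray(grads, dtype=float))
    if c.shape != g.shape:
        raise ValueError("counts and grads must be aligned")
    c2 = c.reshape(-1, c.shape[-1])
    g2 = g.reshape(-1, g.shape[-1])
    norm_c, norm_g = [], []
    for u in range(c2.shape[1]):
        cu = c2[:, u]
        if cu.max() == 0:
            logger.info("sensitivity curve: unit %d has all-zero counts, "
                        "excluded", u)
            continue
        pc = np.percentile(cu, pct)
        pg = np.percentile(g2[:, u], pct)
        norm_c.append(cu / max(pc, 1e-300))
        norm_g.append(g2[:, u] / max(pg, 1e-300))
    if not norm_c:
        raise ValueError("no unit with non-zero counts")
    nc = np.concatenate(norm_c)
    ng = np.concatenate(norm_g)
    edges = np.linspace(0.0, nc.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.searchsorted(edges, nc, "right") - 1, 0, n_bins - 1)
    mean_g = np.full(n_bins, np.nan)
    n_per = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=ng, minlength=n_bins)
    np.divide(sums, n_per, out=mean_g, where=n_per > 0)
    centers = (edges[:-1] + edges[1:]) / 2
    return SensitivityCurve(edges, centers, mean_g, n_per)


def rank_correlation(scores_a, scores_b) -> tuple[float, float]:
    """Tie-corrected Spearman rho (and p-value) between two score vectors.

    Constant input makes the coefficient undefined: returns (nan, nan) with
    a log note.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length score vectors with >= 3 entries")
    if np.all(a == a[0]) or np.all(b == b[0]):
        logger.warning("rank_correlation: constant input, rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
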