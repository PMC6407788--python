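"""Shared toy constructors and direct-domain oracles for decoder tests."""

import math

import numpy as np

from placedecode.features import WindowedCounts
from placedecode.ratemaps import RatemapSet


def toy_maps(rates, bin_cm=2.0):
    """RatemapSet over a 1D row of bins with given (units, bins) rates."""
    rates = np.asarray(rates, dtype=float)
    n_bins = rates.shape[1]
    centers = np.column_stack([(np.arange(n_bins) + 0.5) * bin_cm,
                               np.zeros(n_bins)])
    return RatemapSet(
        bin_centers=centers, occupancy_s=np.ones(n_bins), rate_hz=rates,
        visited_mask=np.ones(n_bins, bool),
        unit_ids=[f"u{i}" for i in range(rates.shape[0])],
        bin_cm=bin_cm, grid_shape=(n_bins,))


def toy_wc(counts, window_len_s=1.0):
    counts = np.asarray(counts)
    return WindowedCounts(counts, np.arange(counts.shape[1], dtype=float),
                          window_len_s, window_len_s,
                          [f"u{i}" for i in range(counts.shape[0])])


def poisson_product(k, rates, T):
    """Direct (non-log) evaluation of the Poisson product likelihood."""
    out = np.ones(rates.shape[1])
    for i, ki in enumerate(k):
        lam = T * rates[i]
        out *= lam**ki / math.factorial(int(ki)) * np.exp(-lam)
    return out
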