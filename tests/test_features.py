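import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placedecode import (ArenaSpec, SpikeData, Trajectory, build_sequences,
                         count_in_windows, downsample_units, knockout_unit)


def _spikes(times_by_unit, span):
    ids = [f"u{i}" for i in range(len(times_by_unit))]
    return SpikeData(ids, [np.asarray(t, float) for t in times_by_unit], span)


class TestCountInWindows:
    def test_half_open_binning(self):
        sd = _spikes([[0.05, 0.10, 0.35]], (0.0, 0.4))
        wc = count_in_windows(sd, 0.2, 0.2, (0.0, 0.4))
        np.testing.assert_array_equal(wc.counts, [[2, 1]])

    def test_boundary_spike_counted_at_start_not_end(self):
        sd = _spikes([[0.0, 0.2]], (0.0, 0.4))
        wc = count_in_windows(sd, 0.2, 0.2, (0.0, 0.4))
        # spike at 0.2 belongs to the second window only
        np.testing.assert_array_equal(wc.counts, [[1, 1]])

    @pytest.mark.parametrize("window_s,expected", [(1.0, 0.8), (0.4, 0.5),
                                                   (0.2, 0.0)])
    def test_overlap_fraction(self, window_s, expected):
        sd = _spikes([[0.5]], (0.0, 10.0))
        wc = count_in_windows(sd, window_s, 0.2, (0.0, 10.0))
        assert wc.overlap_fraction == pytest.approx(expected)
        assert wc.overlap_fraction == pytest.approx(1 - 0.2 / window_s)

    def test_windows_past_span_dropped(self):
        sd = _spikes([[0.1]], (0.0, 1.0))
        wc = count_in_windows(sd, 0.4, 0.3, (0.0, 1.0))
        # starts at 0.0, 0.3, 0.6 fit; 0.9 + 0.4 > 1.0 dropped
        assert wc.n_windows == 3

    def test_empty_span_errors(self):
        sd = _spikes([[0.1]], (0.0, 1.0))
        with pytest.raises(ValueError):
            count_in_windows(sd, 0.2, 0.2, (1.0, 1.0))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 200), st.integers(0, 10**6))
    def test_count_conservation_non_overlapping(self, n_spikes, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 10, n_spikes))
        sd = _spikes([times], (0.0, 10.0))
        wc = count_in_windows(sd, 0.5, 0.5, (0.0, 10.0))
        covered = (times >= 0) & (times < wc.n_windows * 0.5)
        assert wc.counts.sum() == covered.sum()


class TestBuildSequences:
    @staticmethod
    def _traj(t0=0.0, t1=200.0):
        t = np.arange(t0, t1, 0.02)
        pos = np.column_stack([50 + 40 * np.sin(t / 7), 50 + 40 * np.cos(t / 9)])
        return Trajectory(t, pos, ArenaSpec())

    def test_sample_count_arithmetic(self, rng):
        sd = _spikes([np.sort(rng.uniform(0, 110, 300))], (0.0, 110.0))
        wc = count_in_windows(sd, 0.2, 0.2, (0.0, 100.0))
        assert wc.n_windows == 500
        ds = build_sequences(wc, self._traj(), 100)
        assert ds.n_samples == 401
        assert ds.inputs.shape == (401, 100, 1)

    def test_seq_len_one(self, rng):
        sd = _spikes([np.sort(rng.uniform(0, 50, 100))], (0.0, 50.0))
        wc = count_in_windows(sd, 0.2, 0.2, (0.0, 50.0))
        ds = build_sequences(wc, self._traj(), 1)
        assert ds.n_samples == wc.n_windows
        assert ds.inputs.shape[1] == 1

    def test_sample_spans_twenty_seconds(self, rng):
        """100 windows at 200 ms stride cover ~20 s of activity."""
        sd = _spikes([np.sort(rng.uniform(0, 50, 100))], (0.0, 50.0))
        wc = count_in_windows(sd, 0.2, 0.2, (0.0, 50.0))
        ds = build_sequences(wc, self._traj(), 100)
        i = ds.sample_to_window[0]
        first_start = wc.window_centers[i - 99] - 0.1
        last_end = wc.window_centers[i] + 0.1
        assert last_end - first_start == pytest.approx(20.0)

    def test_inputs_match_direct_slicing_oracle(self, rng):
        sd = _spikes([np.sort(rng.uniform(0, 30, 200)) for _ in range(3)],
                     (0.0, 30.0))
        wc = count_in_windows(sd, 0.4, 0.2, (0.0, 30.0))
        ds = build_sequences(wc, self._traj(), 10)
        for s in [0, 5, ds.n_samples - 1]:
            i = ds.sample_to_window[s]
            np.testing.assert_array_equal(ds.inputs[s],
                                          wc.counts[:, i - 9:i + 1].T)

    def test_targets_interpolated_at_centers(self, rng):
        sd = _spikes([np.sort(rng.uniform(0, 30, 50))], (0.0, 30.0))
        wc = count_in_windows(sd, 0.2, 0.2, (0.0, 30.0))
        traj = self._traj()
        ds = build_sequences(wc, traj, 5)
        t = wc.window_centers[ds.sample_to_window]
        np.testing.assert_allclose(ds.targets, traj.interp(t), atol=1e-9)


class TestKnockout:
    @staticmethod
    def _wc(rng):
        sd = _spikes([np.sort(rng.uniform(0, 20, 80)) for _ in range(4)],
                     (0.0, 20.0))
        return count_in_windows(sd, 0.5, 0.5, (0.0, 20.0))

    def test_conservation_and_copy(self, rng):
        wc = self._wc(rng)
        before = wc.counts.copy()
        ko = knockout_unit(wc, "u2")
        assert ko.counts.sum() == before.sum() - before[2].sum()
        assert np.all(ko.counts[2] == 0)
        np.testing.assert_array_equal(wc.counts, before)  # original untouched

    def test_silent_unit_noop(self, rng):
        wc = self._wc(rng)
        wc.counts[1] = 0
        ko = knockout_unit(wc, "u1")
        np.testing.assert_array_equal(ko.counts, wc.counts)

    def test_all_units_sequentially(self, rng):
        wc = self._wc(rng)
        for u in wc.unit_ids:
            wc = knockout_unit(wc, u)
        assert wc.counts.sum() == 0

    def test_unknown_unit(self, rng):
        with pytest.raises(KeyError):
            knockout_unit(self._wc(rng), "nope")

    def test_sequence_dataset_knockout(self, rng):
        wc = self._wc(rng)
        traj = TestBuildSequences._traj(0.0, 25.0)
        ds = build_sequences(wc, traj, 4)
        ko = knockout_unit(ds, "u0")
        assert np.all(ko.inputs[:, :, 0] == 0)
        np.testing.assert_array_equal(ko.inputs[:, :, 1:], ds.inputs[:, :, 1:])


class TestDownsample:
    @staticmethod
    def _population(rng, n=20):
        return _spikes([np.sort(rng.uniform(0, 10, 30)) for _ in range(n)],
                       (0.0, 10.0))

    def test_full_population_identity(self, rng):
        sd = self._population(rng)
        out = downsample_units(sd, 20, seed=0)
        assert out.unit_ids == sd.unit_ids

    def test_deterministic_per_seed(self, rng):
        sd = self._population(rng)
        a = downsample_units(sd, 5, seed=3)
        b = downsample_units(sd, 5, seed=3)
        assert a.unit_ids == b.unit_ids
        assert len(a.unit_ids) == 5

    def test_different_seeds_differ(self, rng):
        sd = self._population(rng, n=63)
        picks = {tuple(downsample_units(sd, 5, seed=s).unit_ids)
                 for s in range(8)}
        assert len(picks) > 1

    def test_bounds(self, rng):
        sd = self._population(rng, n=4)
        with pytest.raises(ValueError):
            downsample_units(sd, 5, seed=0)
        with pytest.raises(ValueError):
            downsample_units(sd, 0, seed=0)
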