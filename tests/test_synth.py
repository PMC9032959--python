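"""Generator properties: topography, overlap, determinism, noise structure."""

import numpy as np
import pandas as pd
import pytest

from handmap.config import CLUSTERS, FINGERS, ConfigError, StudyConfig
from handmap import peripheral, synth


def corr(a, b):
    return np.corrcoef(a, b)[0, 1]


class TestTuningMap:
    def test_zero_width_gives_one_hot_tuning(self):
        cfg = StudyConfig(n_voxels=50, tuning_width=0.0, seed=1)
        tm = synth.generate_tuning_map(cfg)
        assert np.all(np.sort(tm.weights, axis=1)[:, :-1] == 0)
        assert np.all(tm.weights.max(axis=1) == 1)

    def test_deterministic_under_seed(self, small_config):
        a = synth.generate_tuning_map(small_config, participant=3)
        b = synth.generate_tuning_map(small_config, participant=3)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.positions, b.positions)

    def test_max_weight_on_true_cluster_and_ordered_topography(self, small_config):
        tm = synth.generate_tuning_map(small_config)
        pref = np.argmax(tm.weights, axis=1)
        assert all(CLUSTERS[j] == lab for j, lab in zip(pref, tm.labels))
        # positions sorted => preferred finger indices non-decreasing
        assert np.all(np.diff(pref) >= 0)

    def test_neighbor_tuning_correlates_more_than_nonneighbor(self, small_config):
        tm = synth.generate_tuning_map(small_config)
        w = tm.weights
        neighbor = np.mean([corr(w[:, j], w[:, j + 1]) for j in range(4)])
        nonneighbor = np.mean(
            [corr(w[:, i], w[:, j]) for i in range(5) for j in range(i + 2, 5)]
        )
        assert neighbor > nonneighbor

    def test_invalid_voxel_count_rejected(self):
        with pytest.raises(ConfigError):
            StudyConfig(n_voxels=0)


class TestSessionPatterns:
    def test_zero_noise_betas_equal_noiseless_means(self, drives):
        cfg = StudyConfig(n_voxels=40, noise_sd=0.0, seed=2)
        tm = synth.generate_tuning_map(cfg)
        pats = synth.generate_session_patterns(tm, "baseline", cfg, drives)
        means = synth.noiseless_means(tm, "baseline", cfg, drives)
        for r in range(cfg.n_runs):
            assert np.allclose(pats.betas[r], means)

    def test_block_reduces_mean_d2_activity_in_c2(self, drives, blocked_drives):
        cfg = StudyConfig(n_voxels=100, noise_sd=0.0, seed=3)
        tm = synth.generate_tuning_map(cfg)
        base = synth.noiseless_means(tm, "baseline", cfg, drives)
        block = synth.noiseless_means(tm, "block", cfg, blocked_drives)
        c2 = tm.cluster_mask("C2")
        d2 = FINGERS.index("D2")
        assert block[d2, c2].mean() < base[d2, c2].mean()

    def test_residual_sample_covariance_near_identity(self):
        cfg = StudyConfig(n_voxels=20, n_timepoints=4000, noise_sd=1.0, n_runs=1, seed=4)
        tm = synth.generate_tuning_map(cfg)
        pats = synth.generate_session_patterns(
            tm, "baseline", cfg, peripheral.baseline_drives(peripheral.build_spread())
        )
        res = pats.residuals[0]
        cov = res.T @ res / res.shape[0]
        assert np.abs(cov - np.eye(20)).max() < 0.15

    def test_wrong_drive_dimension_raises(self, small_config):
        tm = synth.generate_tuning_map(small_config)
        bad = {f: peripheral.PeripheralDrive(condition=f, values=np.ones(5)) for f in FINGERS}
        object.__setattr__(bad["D3"], "values", np.ones(4))
        with pytest.raises(ValueError):
            synth.noiseless_means(tm, "baseline", small_config, bad)

    def test_winner_takes_all_recovers_truth_on_noiseless_baseline(self, drives):
        cfg = StudyConfig(n_voxels=200, noise_sd=0.0, seed=5)
        tm = synth.generate_tuning_map(cfg)
        means = synth.noiseless_means(tm, "baseline", cfg, drives)
        winners = np.argmax(means, axis=0)
        assert all(CLUSTERS[w] == lab for w, lab in zip(winners, tm.labels))

    def test_pattern_correlation_decreases_with_finger_distance(self, drives):
        cfg = StudyConfig(n_voxels=200, noise_sd=0.0, seed=6)
        tm = synth.generate_tuning_map(cfg)
        means = synth.noiseless_means(tm, "baseline", cfg, drives)
        d2 = FINGERS.index("D2")
        r_d2d3 = corr(means[d2], means[FINGERS.index("D3")])
        r_d2d5 = corr(means[d2], means[FINGERS.index("D5")])
        assert r_d2d3 > r_d2d5


class TestWaveRuns:
    def test_run_length_matches_schedule(self, small_config):
        tm = synth.generate_tuning_map(small_config)
        run = synth.generate_wave_run(tm, small_config, "forward")
        cycle = small_config.wave_on_seconds + small_config.wave_off_seconds
        expected = small_config.wave_cycles * cycle / small_config.tr_seconds
        assert run.n_samples == int(expected) == 100

    def test_single_voxel_timecourse_is_scaled_hrf_boxcar(self):
        cfg = StudyConfig(n_voxels=1, tuning_width=0.0, noise_sd=0.0, seed=7)
        tm = synth.generate_tuning_map(cfg)
        run = synth.generate_wave_run(tm, cfg, "forward")
        # reconstruct the convolved boxcar of this voxel's preferred finger
        from handmap import glm

        pref = CLUSTERS.index(tm.labels[0])
        n = run.n_samples
        box = glm.finger_boxcars(run.schedule, n, cfg.tr_seconds)[:, pref]
        kernel = glm.double_gamma_hrf(cfg.tr_seconds)
        kpad = np.zeros(n)
        kpad[: kernel.size] = kernel
        expected = np.real(np.fft.ifft(np.fft.fft(box) * np.fft.fft(kpad)))
        ratio = run.data[:, 0] / expected
        assert np.allclose(ratio, ratio[0])

    def test_forward_backward_schedules_are_time_reversals(self, small_config):
        fwd = synth.wave_schedule(small_config, "forward")
        bwd = synth.wave_schedule(small_config, "backward")
        fingers_fwd = [f for f, _, _ in fwd]
        fingers_bwd = [f for f, _, _ in bwd]
        assert fingers_bwd == fingers_fwd[::-1]


class TestPsychophysTrials:
    def test_forced_certain_success_gives_all_correct(self):
        tt = synth.generate_psychophys_trials(
            1.5, 2.0, n_per_width=5, seed=0, psychometric=lambda x: np.ones_like(x)
        )
        assert tt.trials["correct"].all()

    def test_empirical_accuracy_matches_generating_curve(self):
        from handmap import psychophys

        thr, slope, n = 1.5, 2.0, 10000
        tt = synth.generate_psychophys_trials(thr, slope, n_per_width=n, seed=11)
        scale, shape = psychophys.weibull_from_threshold(thr, slope)
        for w, acc in tt.accuracy_by_width().items():
            p = psychophys.weibull(w, scale, shape)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(acc - p) < 3 * se

    def test_fixed_seed_reproduces_table(self):
        a = synth.generate_psychophys_trials(1.5, 2.0, seed=42)
        b = synth.generate_psychophys_trials(1.5, 2.0, seed=42)
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_psychophys_trials(-1.0, 2.0)


def test_whole_study_regenerates_bit_identically(small_config):
    a = synth.simulate_participant(small_config, 0)
    b = synth.simulate_participant(small_config, 0)
    assert np.array_equal(a.patterns["block"].betas, b.patterns["block"].betas)
    assert np.array_equal(a.wave_runs[1].data, b.wave_runs[1].data)
    pd.testing.assert_frame_equal(
        a.trials[("block", "D2")].trials, b.trials[("block", "D2")].trials
    )
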