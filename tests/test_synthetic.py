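"""Distributional and determinism checks for the ground-truth generators."""

import numpy as np
import pytest

from polyquant import synthetic
from polyquant.synthetic import (
    simulate_mea_recording,
    simulate_smlm_field,
    simulate_trajectories,
    simulate_two_channel_image,
    stationary_distribution,
)

A2 = [[0.98, 0.02], [0.02, 0.98]]


class TestSmlmField:
    def test_single_cluster_no_background_all_labeled(self):
        locs, truth = simulate_smlm_field(
            n_clusters=1,
            detections_per_cluster_mean=100,
            background_density_per_um2=0.0,
            seed=1,
        )
        assert len(locs) > 0
        assert np.all(truth.detection_cluster_label == 0)

    def test_background_count_matches_poisson_thinning(self):
        # pure background on a 10x10 um field: detections ~ Poisson thinned
        # by the geometric blink multiplicity, mean = 100 * density * blinks
        density, blinks, n_seeds = 0.5, 2.0, 200
        counts = [
            len(
                simulate_smlm_field(
                    n_clusters=0,
                    background_density_per_um2=density,
                    blink_repeat_mean=blinks,
                    n_frames=100000,  # negligible end-of-acquisition truncation
                    seed=s,
                )[0]
            )
            for s in range(n_seeds)
        ]
        expected = 100.0 * density * blinks
        # var of a Poisson sum of geometric multiplicities: lam*E[m^2]
        var = 100.0 * density * (2 * blinks**2 - blinks)
        se = np.sqrt(var / n_seeds)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_zero_noise_single_blink_detections_at_emitters(self):
        locs, truth = simulate_smlm_field(
            n_clusters=3,
            localization_sigma_nm=0.0,
            blink_repeat_mean=1.0,
            background_density_per_um2=0.1,
            seed=2,
        )
        emit_xy = truth.emitter_xy_nm[truth.detection_emitter_index]
        assert np.allclose(np.column_stack([locs.x_nm, locs.y_nm]), emit_xy)

    def test_determinism_and_truth_conservation(self):
        a = simulate_smlm_field(n_clusters=5, seed=7)
        b = simulate_smlm_field(n_clusters=5, seed=7)
        assert np.array_equal(a[0].x_nm, b[0].x_nm)
        assert np.array_equal(a[1].detection_cluster_label, b[1].detection_cluster_label)
        assert len(a[1].detection_emitter_index) == len(a[0])
        assert len(a[1].emitter_cluster_label) == len(a[1].emitter_xy_nm)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            simulate_smlm_field(n_clusters=1, field_width_nm=-1, seed=0)
        with pytest.raises(ValueError):
            simulate_smlm_field(n_clusters=1, background_density_per_um2=-0.5, seed=0)


class TestTrajectories:
    def test_frozen_particle_positions_identical(self):
        traj, _ = simulate_trajectories([0.0], [[1.0]], n_trajectories=5, lengths=10, seed=3)
        for tid in range(5):
            sel = traj.trajectory_id == tid
            assert np.allclose(traj.x_um[sel], traj.x_um[sel][0])
            assert np.allclose(traj.y_um[sel], traj.y_um[sel][0])

    def test_brownian_displacement_variance(self):
        D, dt = 0.1, 0.02
        traj, _ = simulate_trajectories(
            [D], [[1.0]], n_trajectories=100, lengths=1001, dt_s=dt, seed=4
        )
        dx = []
        for tid in range(100):
            sel = traj.trajectory_id == tid
            dx.append(np.diff(traj.x_um[sel]))
        dx = np.concatenate(dx)
        n = len(dx)
        expected = 2 * D * dt  # 0.004 um^2 per axis
        se = expected * np.sqrt(2.0 / n)  # SE of a chi^2-distributed variance
        assert abs(dx.var() - expected) < 3 * se

    def test_geometric_dwell_times(self):
        # long chains so edge censoring of runs is negligible (~dwell/length)
        traj, truth = simulate_trajectories(
            [0.01, 0.1], A2, n_trajectories=25, lengths=25001, seed=5
        )
        runs = {0: [], 1: []}
        for states in truth.states:
            changes = np.flatnonzero(np.diff(states) != 0)
            bounds = np.r_[-1, changes, len(states) - 1]
            for a, b in zip(bounds[:-1], bounds[1:]):
                if a >= 0 and b < len(states) - 1:  # completed runs only
                    runs[states[a + 1]].append(b - a)
        for k in (0, 1):
            assert len(runs[k]) > 5000
            p = 1 - A2[k][k]
            assert np.mean(runs[k]) == pytest.approx(1 / p, rel=0.05)

    def test_stationary_initialization(self):
        A = [[0.95, 0.05], [0.01, 0.99]]
        pi = stationary_distribution(np.array(A))
        _, truth = simulate_trajectories(
            [0.01, 0.1], A, n_trajectories=20000, lengths=2, seed=6
        )
        first = np.array([s[0] for s in truth.states])
        frac = np.bincount(first, minlength=2) / len(first)
        assert np.allclose(frac, pi, atol=3 * np.sqrt(pi[0] * pi[1] / len(first)))

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_trajectories([0.1, 0.2], [[0.5, 0.4], [0.5, 0.5]], seed=0)
        with pytest.raises(ValueError):
            simulate_trajectories([-0.1], [[1.0]], seed=0)
        with pytest.raises(ValueError):
            simulate_trajectories([0.1], [[1.0]], lengths=1, seed=0)


class TestTwoChannelImage:
    def test_full_overlap_pairs_within_one_pixel(self):
        pair = simulate_two_channel_image(
            n_puncta_a=30, n_puncta_b=30, overlap_fraction=1.0, seed=7
        )
        d = np.linalg.norm(
            pair.centers_a[:, None, :] - pair.centers_b[None, :, :], axis=2
        )
        assert np.all(d.min(axis=1) <= 1.0 + 1e-9)

    def test_zero_overlap_min_separation(self):
        pair = simulate_two_channel_image(
            n_puncta_a=40, n_puncta_b=40, overlap_fraction=0.0, seed=8
        )
        d = np.linalg.norm(
            pair.centers_a[:, None, :] - pair.centers_b[None, :, :], axis=2
        )
        assert d.min() >= 5.0 * pair.psf_sigma_px

    def test_zero_amplitude_is_poisson_background(self):
        rate = 10.0
        pair = simulate_two_channel_image(
            shape=(256, 256), amplitude=1e-12, background_rate=rate, seed=9
        )
        for img in (pair.channel_a, pair.channel_b):
            se = np.sqrt(rate / img.size)
            assert abs(img.mean() - rate) < 3 * se

    def test_rejects_bad_psf_and_fraction(self):
        with pytest.raises(ValueError):
            simulate_two_channel_image(psf_sigma_px=0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_two_channel_image(overlap_fraction=1.5, seed=0)


class TestMeaRecording:
    def test_noise_only_sd(self):
        rec = simulate_mea_recording(1, 0.0, duration_s=60.0, noise_sd=2.5, seed=10)
        assert rec.traces.shape == (1, 600000)
        assert abs(np.std(rec.traces[0]) - 2.5) / 2.5 < 0.02
        assert len(rec.true_spike_times_s[0]) == 0

    def test_poisson_spike_count(self):
        rate, duration = 1.0, 600.0
        counts = [
            len(
                simulate_mea_recording(1, rate, duration_s=duration, seed=s)
                .true_spike_times_s[0]
            )
            for s in range(20)
        ]
        assert abs(np.mean(counts) - rate * duration) < 3 * np.sqrt(rate * duration / 20)

    def test_forced_collision_both_in_ground_truth(self):
        # two spikes 0.5 ms apart: templates overlap and sum, truth keeps both
        rec = simulate_mea_recording(
            1, 0.0, duration_s=1.0, spike_times_s=[np.array([0.5, 0.5005])], seed=11
        )
        assert np.allclose(rec.true_spike_times_s[0], [0.5, 0.5005])

    def test_template_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            simulate_mea_recording(
                1, 1.0, duration_s=0.001, spike_template=np.ones(100), seed=0
            )

    def test_determinism(self):
        a = simulate_mea_recording(2, 1.0, duration_s=5.0, seed=12)
        b = simulate_mea_recording(2, 1.0, duration_s=5.0, seed=12)
        assert np.array_equal(a.traces, b.traces)
        assert all(
            np.array_equal(x, y)
            for x, y in zip(a.true_spike_times_s, b.true_spike_times_s)
        )
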