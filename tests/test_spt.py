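"""Linking, MSD, diffusion estimation and motion classification."""

import numpy as np
import pytest

import smtirf as sm
from smtirf.spt import (ClassifierParams, LinkingParams, Trajectory,
                        classify_motion, compute_msd, estimate_D,
                        link_trajectories, mss_slope, diffusion_report)


def msd_oracle(p, n_max, dt):
    """Independent double-loop implementation of the time-averaged MSD."""
    N = len(p)
    out = np.zeros(n_max)
    for n in range(1, n_max + 1):
        acc = 0.0
        for i in range(1, N - 1 - n + 1):
            acc += (p[i + n, 0] - p[i, 0]) ** 2 + (p[i + n, 1] - p[i, 1]) ** 2
        out[n - 1] = acc / (N - 1 - n)
    return out


class TestMSD:
    def test_matches_double_loop_oracle(self, rng):
        for _ in range(25):
            N = int(rng.integers(10, 80))
            p = rng.normal(size=(N, 2))
            prof = compute_msd(p, n_max=5, dt=0.1)
            oracle = msd_oracle(p, 5, 0.1)
            np.testing.assert_allclose(prof.msd_values, oracle, rtol=1e-12)

    def test_stationary_track_zero(self):
        p = np.tile([2.0, 3.0], (50, 1))
        assert np.allclose(compute_msd(p, 5, 0.1).msd_values, 0.0)

    def test_uniform_linear_motion(self):
        d = 0.07
        p = np.column_stack([d * np.arange(40), np.zeros(40)])
        prof = compute_msd(p, 5, 0.1)
        np.testing.assert_allclose(prof.msd_values,
                                   (np.arange(1, 6) * d) ** 2, rtol=1e-12)

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError, match="n_max"):
            compute_msd(np.zeros((6, 2)), 5, 0.1)


class TestDiffusionEstimate:
    def test_exact_line_recovers_D(self):
        lags = np.arange(1, 6)
        prof = sm.MSDProfile(lags=lags, msd_values=4 * 0.1 * lags * 0.1,
                             counts=np.full(5, 10), dt=0.1)
        est = estimate_D(prof)
        assert est.D == pytest.approx(0.1, rel=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_negative_slope_floored_and_flagged(self):
        prof = sm.MSDProfile(lags=np.arange(1, 6),
                             msd_values=np.array([5, 4, 3, 2, 1.0]),
                             counts=np.full(5, 10), dt=0.1)
        est = estimate_D(prof)
        assert est.D == 0.0 and est.floored

    def test_immobile_jitter_near_zero_D(self, rng):
        Ds = []
        for _ in range(200):
            p = rng.normal(0, 0.02, size=(300, 2))
            Ds.append(estimate_D(compute_msd(p, 5, 0.1)).D)
        assert np.median(Ds) < 0.005

    def test_invariant_under_translation_and_rotation(self, rng):
        p = np.cumsum(rng.normal(0, 0.1, size=(100, 2)), axis=0)
        th = 0.7
        Rm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        p2 = p @ Rm.T + np.array([5.0, -3.0])
        D1 = estimate_D(compute_msd(p, 5, 0.1)).D
        D2 = estimate_D(compute_msd(p2, 5, 0.1)).D
        assert D1 == pytest.approx(D2, rel=1e-10)

    def test_rmse_shrinks_with_track_length(self):
        D = 0.1
        mot = sm.MotionModel("free", D=D)
        rmses = []
        for N in (50, 150, 300):
            geom = sm.AcquisitionGeometry(n_frames=N)
            paths = sm.sample_trajectories(mot, geom, np.zeros((800, 2)), 21)
            Ds = np.array([estimate_D(compute_msd(p, 5, 0.1)).D for p in paths])
            rmses.append(np.sqrt(np.mean((Ds - D) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]
        assert abs(np.mean(Ds) - D) < 0.1 * D     # N=300 near-unbiased


class TestLinking:
    def test_single_particle_full_track(self):
        dets = {f: np.array([[10.0 + 3 * f, 20.0]]) for f in range(30)}
        tracks = link_trajectories(dets)
        assert len(tracks) == 1 and tracks[0].n_frames == 30

    def test_jump_beyond_max_distance_splits_track(self):
        dets = {f: np.array([[10.0 + 3 * f + (8.0 if f >= 10 else 0.0), 20.0]])
                for f in range(20)}
        tracks = link_trajectories(dets, LinkingParams(min_track_length=2))
        assert len(tracks) == 2

    def test_gap_closed_across_missing_frame(self):
        dets = {f: np.array([[10.0 + f, 20.0]]) for f in range(20) if f != 9}
        tracks = link_trajectories(dets, LinkingParams(min_track_length=2))
        assert len(tracks) == 1
        assert tracks[0].n_frames == 19
        # interpolated positions fill the gap for MSD purposes
        assert len(tracks[0].filled_positions()) == 20

    def test_gap_beyond_limits_not_closed(self):
        dets = {f: np.array([[10.0 + f, 20.0]]) for f in range(20)
                if f not in (8, 9, 10)}
        tracks = link_trajectories(dets, LinkingParams(min_track_length=2))
        assert len(tracks) == 2

    def test_reproduces_ground_truth_when_unconstrained(self):
        mot = sm.MotionModel("free", D=0.2)
        geom = sm.AcquisitionGeometry(n_frames=50)
        path = sm.sample_trajectory(mot, geom, (20.0, 20.0), 3)
        dets = {f: path[f:f + 1] / 0.16 for f in range(50)}
        tracks = link_trajectories(dets, LinkingParams(max_distance=1e9,
                                                       gap_max_frames=0,
                                                       min_track_length=2))
        assert len(tracks) == 1
        np.testing.assert_allclose(tracks[0].positions, path, rtol=1e-12)

    def test_two_crossing_particles_assigned_globally(self):
        # two particles approach; global assignment keeps total displacement
        # minimal instead of greedily stealing the nearer detection
        a = np.column_stack([np.linspace(0, 20, 21), np.full(21, 10.0)])
        b = np.column_stack([np.linspace(20, 0, 21), np.full(21, 12.0)])
        dets = {f: np.array([a[f], b[f]]) for f in range(21)}
        tracks = link_trajectories(dets, LinkingParams(min_track_length=5))
        assert len(tracks) == 2
        assert all(t.n_frames == 21 for t in tracks)


class TestClassification:
    def test_three_modes_recognized(self):
        geom = sm.TRACKING_GEOMETRY
        n = 120
        free = sm.sample_trajectories(
            sm.MotionModel("free", D=0.27, localization_noise_sd=0.02),
            geom, np.zeros((n, 2)), 1)
        conf = sm.sample_trajectories(
            sm.MotionModel("confined", D=0.1, confinement_radius=0.2,
                           localization_noise_sd=0.02),
            geom, np.zeros((n, 2)), 2)
        imm = sm.sample_trajectories(
            sm.MotionModel("immobile", localization_noise_sd=0.02),
            geom, np.zeros((n, 2)), 3)
        acc = {}
        for name, paths in (("free", free), ("confined", conf), ("immobile", imm)):
            labels = [classify_motion(p, dt=0.1) for p in paths]
            acc[name] = np.mean([l == name for l in labels])
        assert acc["free"] >= 0.90
        assert acc["confined"] >= 0.85
        assert acc["immobile"] >= 0.95

    def test_short_track_unclassified(self, rng):
        assert classify_motion(rng.normal(size=(10, 2)), dt=0.1) == "unclassified"

    def test_mss_slope_half_for_free_motion(self):
        mot = sm.MotionModel("free", D=0.2)
        paths = sm.sample_trajectories(mot, sm.TRACKING_GEOMETRY,
                                       np.zeros((60, 2)), 7)
        slopes = [mss_slope(p, 0.1) for p in paths]
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.05)


class TestDiffusionReport:
    def test_all_free_input(self):
        mot = sm.MotionModel("free", D=0.2, localization_noise_sd=0.02)
        paths = sm.sample_trajectories(mot, sm.TRACKING_GEOMETRY,
                                       np.zeros((40, 2)), 9)
        tracks = [Trajectory(i, np.arange(300), p, 0.1)
                  for i, p in enumerate(paths)]
        rep = diffusion_report(tracks)
        assert rep["fractions"]["free"] >= 0.9
        assert rep["D_pooled"]["free"]["mean"] == pytest.approx(0.2, rel=0.15)

    def test_condition_ordering_of_mean_D(self):
        means = []
        for i, D in enumerate((0.2703, 0.0528)):
            mot = sm.MotionModel("free", D=D)
            paths = sm.sample_trajectories(mot, sm.TRACKING_GEOMETRY,
                                           np.zeros((60, 2)), 30 + i)
            tracks = [Trajectory(j, np.arange(300), p, 0.1)
                      for j, p in enumerate(paths)]
            rep = diffusion_report(tracks)
            means.append(rep["D_pooled"]["free"]["mean"])
        assert means[0] > means[1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            diffusion_report([])
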