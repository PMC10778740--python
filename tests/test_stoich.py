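"""Trace extraction, slope exclusion and photobleaching-step counting."""

import itertools

import numpy as np
import pytest

import smtirf as sm
from smtirf.stoich import (StepCounterParams, aggregate_stoichiometry,
                           count_steps, exclude_sloped, extract_trace,
                           optimal_segmentation, recalibrate_counts,
                           robust_noise_sd, slope_r2)


def brute_force_segmentation(y, penalty, min_seg, max_cp):
    """Exhaustive minimizer of the same penalized least-squares criterion."""
    y = np.asarray(y, float)
    T = len(y)

    def sse(a, b):
        seg = y[a:b]
        return float(np.sum((seg - seg.mean()) ** 2))

    best_bps, best_score = [], sse(0, T)
    for k in range(1, max_cp + 1):
        for bps in itertools.combinations(range(min_seg, T - min_seg + 1), k):
            if any(b2 - b1 < min_seg for b1, b2 in zip(bps, bps[1:])):
                continue
            edges = (0,) + bps + (T,)
            score = sum(sse(a, b) for a, b in zip(edges, edges[1:])) + penalty * k
            if score < best_score - 1e-12:
                best_score, best_bps = score, list(bps)
    return best_bps, best_score


class TestExtractTrace:
    @pytest.fixture()
    def monomer_movie(self):
        geom = sm.AcquisitionGeometry(image_shape=(24, 24), n_frames=60)
        p = sm.ParticleTruth(0, 1, np.array([30]),
                             np.repeat([[1.9, 2.1]], 60, axis=0), "immobile", 0.0)
        movie, _ = sm.render_movie([p], geom, sm.NoiseModel.off(), 0, 200.0)
        return movie

    def test_plateau_then_zero(self, monomer_movie):
        tr = extract_trace(monomer_movie, (11.4, 12.6))
        assert np.allclose(tr.intensities[30:], 0.0, atol=1e-6)
        assert tr.intensities[:30].std() < 1e-6
        assert tr.intensities[0] > 0

    def test_integrated_intensity_linear_in_oligomer_size(self):
        geom = sm.AcquisitionGeometry(image_shape=(24, 24), n_frames=4)
        plateaus = []
        for k in (1, 3):
            p = sm.ParticleTruth(0, k, np.full(k, 999),
                                 np.repeat([[1.9, 2.1]], 4, axis=0), "immobile", 0.0)
            movie, _ = sm.render_movie([p], geom, sm.NoiseModel.off(), 0, 200.0)
            plateaus.append(extract_trace(movie, (11.4, 12.6)).intensities[0])
        assert plateaus[1] == pytest.approx(3 * plateaus[0], rel=0.05)

    def test_edge_window_flagged_truncated(self, monomer_movie):
        tr = extract_trace(monomer_movie, (1.0, 1.0))
        assert tr.truncated


class TestSlopeExclusion:
    def test_linear_ramp_excluded(self, rng):
        y = np.linspace(100, 0, 400) + rng.normal(0, 1.0, 400)
        assert exclude_sloped(y)

    def test_quadratic_decay_excluded(self, rng):
        t = np.linspace(0, 1, 400)
        y = 200 * (1 - t) ** 2 + rng.normal(0, 2.0, 400)
        assert exclude_sloped(y)

    def test_ideal_single_step_retained(self, rng):
        y = np.concatenate([np.full(200, 10.0), np.zeros(200)])
        y = y + rng.normal(0, 1.0, 400)   # step = 10x noise sd
        assert not exclude_sloped(y)

    def test_ideal_multistep_staircases_retained(self, rng):
        for k in (2, 3, 4):
            y = np.repeat(np.arange(k, -1, -1, dtype=float), 400 // (k + 1))
            yn = y + rng.normal(0, 1 / 5, len(y))   # step/noise = 5
            assert not exclude_sloped(yn), f"k={k} staircase wrongly excluded"

    def test_constant_trace_retained(self):
        assert not exclude_sloped(np.full(100, 7.0))
        assert slope_r2(np.full(100, 7.0)) == 0.0


class TestCountSteps:
    def test_noiseless_staircase_exact(self):
        y = np.concatenate([np.full(100, 300.0), np.full(100, 200.0),
                            np.full(100, 100.0), np.full(100, 0.0)])
        res = count_steps(y)
        assert res.n_steps == 3
        assert list(res.step_frames) == [100, 200, 300]
        assert np.allclose(res.level_means, [300, 200, 100, 0])

    def test_monotone_increasing_trace_has_no_downward_steps(self):
        res = count_steps(np.linspace(0, 100, 200))
        assert res.n_steps == 0

    def test_level_means_weakly_decreasing(self, rng):
        for _ in range(20):
            k = rng.integers(1, 5)
            y, _ = sm.make_step_trace(int(k), 300, 50.0, 50.0 / 3, rng)
            res = count_steps(y)
            assert np.all(np.diff(res.level_means) <= 1e-9)

    def test_accuracy_at_step_noise_three(self, rng):
        for k in (1, 2, 3, 4):
            ok = sum(count_steps(sm.make_step_trace(k, 400, 300.0, 100.0, rng)[0]).n_steps == k
                     for _ in range(120))
            assert ok / 120 >= 0.95, f"k={k}: {ok}/120"

    def test_double_height_drop_counts_two_events(self):
        y = np.concatenate([np.full(100, 300.0), np.full(100, 100.0),
                            np.full(100, 0.0)])
        y = y + np.random.default_rng(0).normal(0, 3.0, 300)
        res = count_steps(y)
        assert res.n_steps == 3
        assert list(res.events) == [2, 1]

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            count_steps(np.zeros(4))

    def test_matches_brute_force_oracle_on_small_traces(self, rng):
        params = StepCounterParams()
        for i in range(12):
            k = int(rng.integers(0, 4))
            y, _ = sm.make_step_trace(k, int(rng.integers(30, 61)), 10.0, 2.0,
                                      rng, min_separation=5)
            sigma = max(robust_noise_sd(y), 1e-12)
            penalty = params.penalty_scale * sigma ** 2 * np.log(len(y))
            bps, score = optimal_segmentation(y, penalty,
                                              params.min_segment_length, 3)
            bps_bf, score_bf = brute_force_segmentation(
                y, penalty, params.min_segment_length, 3)
            assert bps == bps_bf
            assert score == pytest.approx(score_bf, rel=1e-10)


class TestRecalibration:
    def test_single_merged_drop_resolved_by_global_unit(self, rng):
        results = []
        # many clean monomer traces establish the unit ...
        for _ in range(20):
            y, _ = sm.make_step_trace(1, 200, 100.0, 5.0, rng)
            results.append(count_steps(y))
        # ... and one double-height single-drop trace (simultaneous bleach)
        y = np.concatenate([np.full(100, 200.0), np.zeros(100)])
        y = y + rng.normal(0, 5.0, 200)
        results.append(count_steps(y))
        counts = recalibrate_counts(results)
        assert counts[:-1] == [1] * 20
        assert counts[-1] == 2


class TestAggregation:
    def test_fraction_arithmetic(self):
        counts = [1] * 50 + [2] * 30 + [3] * 15 + [4] * 5
        dist = aggregate_stoichiometry(counts)
        assert np.allclose(dist.fractions, [0.50, 0.30, 0.15, 0.05])
        assert dist.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_identical_cells_zero_sd(self):
        counts = [1, 1, 2, 1, 1, 2]
        cells = [0, 0, 0, 1, 1, 1]
        dist = aggregate_stoichiometry(counts, cells)
        assert np.allclose(dist.sd, 0.0)

    def test_out_of_range_counts_reported_not_normalized(self):
        dist = aggregate_stoichiometry([0, 1, 2, 5, 1])
        assert dist.n_zero_step == 1 and dist.n_many_step == 1
        assert dist.n_traces == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_stoichiometry([])


class TestRecovery:
    def test_pure_monomer_no_noise_recovered_exactly(self):
        rep = sm.recovery_experiment((1.0, 0.0, 0.0, 0.0), 40, 0,
                                     step_noise_ratio=0.0)
        assert rep["estimated_fractions"][0] == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self):
        r1 = sm.recovery_experiment((0.5, 0.5, 0.0, 0.0), 60, 5)
        r2 = sm.recovery_experiment((0.5, 0.5, 0.0, 0.0), 60, 5)
        assert r1 == r2

    def test_monomer_fraction_monotone_in_truth(self):
        est = []
        for f1 in (0.1, 0.25, 0.4, 0.55, 0.7):
            rest = (1 - f1) / 3
            rep = sm.recovery_experiment((f1, rest, rest, rest), 150, 2,
                                         step_noise_ratio=3.0, n_frames=400)
            est.append(rep["estimated_fractions"][0])
        assert np.all(np.diff(est) > 0)
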