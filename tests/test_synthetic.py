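"""Tests of the synthetic experiment generator."""

import numpy as np
import pandas as pd
import pytest

import fcdecode as fc
from fcdecode.synthetic import (ConfigurationError, ReportMixture, bin_of,
                                driving_direction, iti_probabilities)

from conftest import make_fixed_direction_trials


def max_run_length(seq):
    best, cur = 1, 1
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


class TestTrialSequence:
    def test_session_geometry(self, session_trials):
        t = session_trials
        # 3 coherences x 16 trials = 48 per run; 160 per coherence; 20 per bin
        assert all(len(g) == 48 for _, g in t.groupby("run"))
        assert t["coherence"].value_counts().eq(160).all()
        for _, g in t.groupby("coherence"):
            assert g["bin_index"].value_counts().eq(20).all()

    def test_directions_lie_inside_their_bin(self, session_trials):
        assert (bin_of(session_trials["theta_s"])
                == session_trials["bin_index"]).all()

    @pytest.mark.parametrize("seed", range(60))
    def test_run_length_constraints_across_seeds(self, seed):
        t = fc.generate_trial_sequence(n_runs=2, seed=seed)
        for _, g in t.groupby("run"):
            assert max_run_length(list(g["bin_index"])) <= 2
            assert max_run_length(list(g["coherence"])) <= 3
            assert g["coherence"].value_counts().eq(16).all()

    def test_infeasible_bin_balance_raises(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            fc.generate_trial_sequence(n_runs=1, trials_per_coherence=12)

    def test_iti_frequencies_decrease(self):
        t = fc.generate_trial_sequence(n_runs=10, trials_per_coherence=48,
                                       seed=5)  # 1440 trials
        counts = t["iti"].value_counts().reindex([3.0, 5.0, 7.0, 9.0])
        assert counts.is_monotonic_decreasing
        assert np.all(np.diff(iti_probabilities()) < 0)

    def test_seeded_reproducibility(self):
        a = fc.generate_trial_sequence(n_runs=2, seed=7)
        b = fc.generate_trial_sequence(n_runs=2, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestReports:
    def test_pure_guessing_gives_chance_fca(self):
        t = fc.generate_trial_sequence(n_runs=40, trials_per_coherence=16, seed=3)
        mix = {k: ReportMixture(0, 0, 1, 5.0) for k in
               ("zero", "intermediate", "full")}
        r = fc.simulate_reports(t, mix, seed=4)
        mean_fca = np.mean(fc.fca(fc.circular_deviation(r["theta_s"], r["theta_r"])))
        assert mean_fca == pytest.approx(50.0, abs=1.5)

    def test_degenerate_detection_reproduces_target(self):
        t = fc.generate_trial_sequence(n_runs=2, seed=3)
        t = t[t["coherence"] != "zero"]
        mix = {k: ReportMixture(1, 0, 0, 5e4) for k in ("intermediate", "full")}
        r = fc.simulate_reports(t, mix, seed=4)
        assert np.max(fc.circular_deviation(r["theta_s"], r["theta_r"])) < 2.0

    def test_pure_opposite_reports_are_antipodal(self):
        t = fc.generate_trial_sequence(n_runs=2, seed=3)
        t = t[t["coherence"] == "full"]
        mix = {"full": ReportMixture(0, 1, 0, 5e4)}
        r = fc.simulate_reports(t, mix, seed=4)
        dev = fc.circular_deviation(r["theta_s"], r["theta_r"])
        assert np.all(np.abs(dev - 180.0) < 2.0)

    def test_zero_coherence_forced_to_guessing(self, session_trials):
        z = session_trials[session_trials["coherence"] == "zero"]
        assert (z["report_component"] == "guess").all()

    def test_invalid_weights_rejected(self):
        t = fc.generate_trial_sequence(n_runs=2, seed=3)
        mix = {k: ReportMixture(0.5, 0.1, 0.1, 5.0) for k in
               ("zero", "intermediate", "full")}
        with pytest.raises(ValueError, match="sum to 1"):
            fc.simulate_reports(t, mix, seed=4)

    def test_opposite_rate_converges_to_mixture_weight(self):
        w_o = 0.15
        t = fc.generate_trial_sequence(n_runs=40, trials_per_coherence=16, seed=6)
        t = t[t["coherence"] == "full"]  # 640 trials
        mix = {"full": ReportMixture(0.8, w_o, 0.05, 20.0)}
        r = fc.simulate_reports(t, mix, seed=7)
        emp = (r["report_component"] == "opposite").mean()
        se = np.sqrt(w_o * (1 - w_o) / len(r))
        assert abs(emp - w_o) < 3 * se


class TestVoxelPopulation:
    def test_uninformative_population_is_flat(self):
        v = fc.generate_voxel_population(
            20, tuning_spec=fc.TuningSpec(informative_fraction=0.0), seed=1)
        assert np.all(v.tuning_amplitude == 0)
        f = v.tuning([0.0, 90.0, 180.0])
        assert np.allclose(f, f[0])

    def test_amplitude_zero_iff_uninformative(self):
        v = fc.generate_voxel_population(200, grid_shape=(10, 10, 10), seed=2)
        assert np.array_equal(v.tuning_amplitude == 0, ~v.informative)

    def test_two_phase_offset_voxels_identify_direction(self):
        # two smooth bumps 90 degrees apart: the response pair is injective
        # over the 1-degree grid (checked by brute-force pairwise distances)
        v = fc.VoxelPopulation(
            coords=np.array([[0, 0, 0], [1, 0, 0]]),
            roi_label=np.array(["a", "a"]),
            tuning_amplitude=np.array([1.0, 1.0]),
            tuning_width=np.array([1.0, 1.0]),
            tuning_phase=np.array([0.0, 90.0]),
            baseline=np.zeros(2), noise_sd=np.zeros(2),
            informative=np.array([True, True]))
        grid = np.arange(1.0, 361.0)
        F = v.tuning(grid)
        d = np.linalg.norm(F[:, None, :] - F[None, :, :], axis=2)
        d[np.diag_indices(360)] = np.inf
        assert d.min() > 1e-4

    def test_seeded_population_bitwise_reproducible(self):
        a = fc.generate_voxel_population(50, seed=9)
        b = fc.generate_voxel_population(50, seed=9)
        assert np.array_equal(a.tuning_phase, b.tuning_phase)
        assert np.array_equal(a.tuning_amplitude, b.tuning_amplitude)

    def test_capacity_exceeded_raises(self):
        with pytest.raises(ConfigurationError, match="capacity"):
            fc.generate_voxel_population(1000, grid_shape=(4, 4, 4))

    def test_ball_coords_count(self):
        assert fc.ball_coords(4.0).shape == (257, 3)


class TestBetas:
    def test_noiseless_betas_equal_tuning(self):
        t = make_fixed_direction_trials(120.0, 5)
        v = fc.generate_voxel_population(
            4, tuning_spec=fc.TuningSpec(noise_sd=0.0), seed=3)
        b = fc.simulate_betas(t, v, seed=0)
        assert b.values.shape == (5, 4)
        assert np.allclose(b.values, v.tuning(np.full(5, 120.0)))

    def test_mean_converges_to_tuning_value(self):
        n = 10_000
        t = make_fixed_direction_trials(77.0, n)
        v = fc.generate_voxel_population(
            3, tuning_spec=fc.TuningSpec(noise_sd=0.5), seed=3)
        b = fc.simulate_betas(t, v, seed=4)
        truth = v.tuning(np.array([77.0]))[0]
        se = 0.5 / np.sqrt(n)
        assert np.all(np.abs(b.values.mean(axis=0) - truth) < 3 * se)

    def test_variance_converges_to_noise_variance(self):
        n = 10_000
        t = make_fixed_direction_trials(10.0, n)
        v = fc.generate_voxel_population(
            3, tuning_spec=fc.TuningSpec(noise_sd=0.7), seed=3)
        b = fc.simulate_betas(t, v, seed=4)
        var = b.values.var(axis=0)
        se = 0.7**2 * np.sqrt(2.0 / n)   # SE of a normal sample variance
        assert np.all(np.abs(var - 0.7**2) < 3 * se)

    def test_zero_coherence_driven_by_report_latent(self, session_trials):
        v = fc.generate_voxel_population(
            8, tuning_spec=fc.TuningSpec(noise_sd=0.0, informative_fraction=1.0),
            seed=5)
        b = fc.simulate_betas(session_trials, v, seed=6)
        z = session_trials["coherence"] == "zero"
        drive = driving_direction(session_trials)
        assert np.allclose(drive[z.to_numpy()],
                           session_trials.loc[z, "theta_r"])
        expect = v.tuning(session_trials.loc[z, "theta_r"].to_numpy())
        assert np.allclose(b.values[z.to_numpy()], expect)


class TestGaze:
    def test_excursion_outside_window_raises(self, session_trials):
        with pytest.raises(ValueError, match="stimulation window"):
            fc.simulate_gaze(session_trials.head(4), sampling_rate=100,
                             excursions=[(0, 1.9, 0.3, 3.0)])

    def test_quiet_gaze_sampled_at_fixed_rate(self):
        t = fc.generate_trial_sequence(n_runs=1, seed=2)
        g = fc.simulate_gaze(t, fixation_sd=0.05, sampling_rate=200, seed=1)
        dt = np.diff(g["time"].to_numpy())
        assert np.allclose(dt, 1.0 / 200)
        assert np.nanmax(np.hypot(g["x"], g["y"])) < 1.0
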