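"""Synthetic cohort generator: waveform closed forms, latency statistics,
INO injection, dropout bursts, and determinism."""

import numpy as np
import pytest

from saccadepipe.simulate import (
    SimulationConfig,
    apply_ino,
    inject_missingness,
    minimum_jerk_peak_velocity,
    minimum_jerk_position,
    simulate_cohort,
    simulate_trial,
)


class TestMinimumJerk:
    def test_midpoint_is_half_amplitude(self):
        assert minimum_jerk_position(18.4, 60.0, 30.0) == pytest.approx(9.2)

    def test_analytic_peak_velocity(self):
        # 1.875 * A / D, durations in ms -> deg/s
        assert minimum_jerk_peak_velocity(18.4, 60.0) == pytest.approx(575.0)

    def test_boundaries(self):
        t = np.array([-5.0, 0.0, 50.0, 80.0])
        pos = minimum_jerk_position(10.0, 50.0, t)
        assert pos[0] == 0.0 and pos[1] == 0.0
        assert pos[2] == 10.0 and pos[3] == 10.0

    def test_numeric_peak_velocity_matches_closed_form(self):
        t = np.linspace(0, 60, 60001)
        x = minimum_jerk_position(18.4, 60.0, t)
        v = np.gradient(x, t) * 1000.0  # deg/s
        assert v.max() == pytest.approx(575.0, rel=1e-6)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            minimum_jerk_position(10.0, 0.0, 5.0)


class TestSimulateTrial:
    def _trial(self, cfg, task="prosaccade", direction="right",
               eccentricity="far", seed=0):
        rng = np.random.default_rng(seed)
        return simulate_trial(task, direction, eccentricity, 1, "S01",
                              "HC", cfg, rng)

    def test_noise_free_unit_gain_lands_on_target(self):
        cfg = SimulationConfig(noise_sd_deg=0.0, gain_mean=1.0, gain_sd=0.0,
                               dropout_prob=0.0)
        trial, truth = self._trial(cfg)
        assert trial.x_left[-1] == pytest.approx(18.4, abs=1e-9)
        assert trial.x_right[-1] == pytest.approx(18.4, abs=1e-9)
        assert truth.true_amplitude_deg == pytest.approx(18.4)

    def test_certain_antisaccade_error_flags_every_trial(self):
        cfg = SimulationConfig(antisaccade_error_prob={"HC": 1.0, "MS": 1.0})
        for seed in range(10):
            _, truth = self._trial(cfg, task="antisaccade", seed=seed)
            assert truth.correct_direction is False
            assert truth.movement_direction == "right"  # toward the target

    def test_antisaccade_moves_opposite_target_when_correct(self):
        cfg = SimulationConfig(antisaccade_error_prob={"HC": 0.0, "MS": 0.0})
        _, truth = self._trial(cfg, task="antisaccade", direction="right")
        assert truth.movement_direction == "left"

    def test_latency_sample_mean_matches_truncated_normal(self):
        cfg = SimulationConfig(noise_sd_deg=0.0, dropout_prob=0.0)
        rng = np.random.default_rng(123)
        lat = [simulate_trial("prosaccade", "right", "far", 1, "S", "HC",
                              cfg, rng)[1].true_onset_ms
               for _ in range(4000)]
        se = np.std(lat, ddof=1) / np.sqrt(len(lat))
        assert abs(np.mean(lat) - 195.0) < 3 * se + 0.1

    def test_main_sequence_links_amplitude_and_duration(self):
        cfg = SimulationConfig()
        _, truth = self._trial(cfg, seed=5)
        A = truth.true_amplitude_deg
        assert truth.true_duration_ms["left"] == pytest.approx(2.2 * A + 21)
        assert truth.true_peak_velocity_deg_s["left"] == pytest.approx(
            1.875 * A / (truth.true_duration_ms["left"] / 1000.0))


class TestApplyIno:
    def _clean_trial(self, seed=0):
        cfg = SimulationConfig(noise_sd_deg=0.1, dropout_prob=0.0)
        rng = np.random.default_rng(seed)
        return simulate_trial("prosaccade", "right", "far", 1, "S01", "MS",
                              cfg, rng)[0]

    def test_factor_one_is_bitwise_identity(self):
        trial = self._clean_trial()
        out = apply_ino(trial, 1.0, "right")
        assert out.equals(trial)

    def test_adducting_peak_velocity_scaled_by_factor(self):
        trial = self._clean_trial()
        out = apply_ino(trial, 0.7, "right")
        truth = out.extras["truth"]
        # rightward saccade: left eye adducts
        assert truth.true_peak_velocity_deg_s["left"] == pytest.approx(
            0.7 * truth.true_peak_velocity_deg_s["right"])
        assert truth.true_duration_ms["left"] == pytest.approx(
            truth.true_duration_ms["right"] / 0.7)

    def test_opposite_direction_left_unchanged(self):
        trial = self._clean_trial()
        out = apply_ino(trial, 0.7, "left")  # trial moves rightward
        assert out.equals(trial)

    @pytest.mark.parametrize("factor", [0.0, -0.5, 1.2])
    def test_factor_outside_unit_interval_rejected(self, factor):
        with pytest.raises(ValueError):
            apply_ino(self._clean_trial(), factor, "right")


class TestMissingness:
    def _trial(self):
        cfg = SimulationConfig(noise_sd_deg=0.0, dropout_prob=0.0)
        rng = np.random.default_rng(0)
        return simulate_trial("prosaccade", "right", "far", 1, "S", "HC",
                              cfg, rng)[0]

    def test_zero_probability_is_identity(self):
        trial = self._trial()
        out = inject_missingness(trial, 0.0, 3.0, np.random.default_rng(0))
        assert out.equals(trial)

    def test_probability_one_invalidates_everything(self):
        out = inject_missingness(self._trial(), 1.0, 3.0,
                                 np.random.default_rng(0))
        assert (out.valid_left == 4).all() and (out.valid_right == 4).all()

    def test_expected_missing_fraction(self):
        rng = np.random.default_rng(99)
        trial = self._trial()
        fracs = [
            (inject_missingness(trial, 0.05, 3.0, rng).valid_left > 1).mean()
            for _ in range(400)]
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.05) < 3 * se + 1e-3

    def test_bursts_are_contiguous_with_requested_mean_length(self):
        rng = np.random.default_rng(7)
        lengths = []
        for _ in range(200):
            mask = inject_missingness(self._trial(), 0.1, 4.0, rng).valid_left > 1
            padded = np.concatenate(([False], mask, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(int)))
            lengths.extend(edges[1::2] - edges[::2])
        assert np.mean(lengths) == pytest.approx(4.0, rel=0.15)


class TestCohort:
    def test_structure_and_count(self):
        trials, truth = simulate_cohort(SimulationConfig(
            n_hc=2, n_ms=1, trials_per_condition=3, seed=0))
        assert len(trials) == 3 * 2 * 4 * 3  # subjects x tasks x cond x reps
        assert len(truth) == len(trials)
        assert set(truth["group"]) == {"HC", "MS"}

    def test_full_study_trial_count(self):
        cfg = SimulationConfig(n_hc=34, n_ms=33, trials_per_condition=20)
        n_subj = cfg.n_hc + cfg.n_ms
        assert n_subj * len(cfg.tasks) * 4 * cfg.trials_per_condition == 10720

    def test_same_seed_reproduces_cohort_exactly(self):
        cfg = SimulationConfig(n_hc=1, n_ms=1, trials_per_condition=2, seed=11)
        t1, g1 = simulate_cohort(cfg)
        t2, g2 = simulate_cohort(cfg)
        assert all(a.equals(b) for a, b in zip(t1, t2))
        assert g1.equals(g2)

    def test_different_seed_changes_latencies(self):
        a = simulate_cohort(SimulationConfig(n_hc=1, n_ms=0,
                                             trials_per_condition=2, seed=1))[1]
        b = simulate_cohort(SimulationConfig(n_hc=1, n_ms=0,
                                             trials_per_condition=2, seed=2))[1]
        assert not np.allclose(a["true_onset_ms"], b["true_onset_ms"])

    def test_ino_assignment_reaches_ground_truth(self):
        _, truth = simulate_cohort(SimulationConfig(
            n_hc=0, n_ms=2, n_ino=1, trials_per_condition=2, seed=3))
        affected = truth[truth["ino_affected"]]
        assert (affected["subject_id"] == "MS001").all()
        # first MS subject is affected leftward: the right eye adducts
        assert (affected["movement_direction"] == "left").all()
        assert (affected["true_pv_right_deg_s"]
                < affected["true_pv_left_deg_s"]).all()
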