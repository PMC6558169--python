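"""Saccade candidate detection, onset/offset location, fixation gating,
acceptance rules, and primary-saccade selection."""

import numpy as np
import pytest

from saccadepipe.config import StudyConfig
from saccadepipe.detection import (
    candidate_events,
    detect_events,
    fixation_precedes,
    locate_offset,
    locate_onset,
    primary_saccade,
)
from saccadepipe.kinematics import differentiate_trace
from saccadepipe.simulate import (
    SimulationConfig,
    minimum_jerk_position,
    simulate_trial,
)

from conftest import make_trial


def noise_free_trial(A=18.4, latency=200.0, direction="right", n=300):
    sign = 1 if direction == "right" else -1
    D = 2.2 * A + 21.0
    t = np.arange(n) * (1000 / 300)
    x = sign * minimum_jerk_position(A, D, t - latency)
    return make_trial(x=x, direction=direction,
                      eccentricity="far"), latency, D


class TestCandidates:
    def test_flat_trace_has_no_candidates(self, config):
        assert candidate_events(np.zeros(100), config) == []

    def test_single_supra_threshold_sample_insufficient(self, config):
        v = np.zeros(100)
        v[50] = 80.0
        assert candidate_events(v, config) == []

    def test_two_consecutive_samples_make_a_candidate(self, config):
        v = np.zeros(100)
        v[50:52] = 80.0
        [(peak, pv)] = candidate_events(v, config)
        assert peak in (50, 51) and pv == 80.0

    def test_noise_free_saccade_yields_one_candidate_at_peak(self, config):
        trial, latency, D = noise_free_trial()
        traces = differentiate_trace(trial, config)
        cands = candidate_events(traces.velocity_deg_s["left"], config)
        assert len(cands) == 1
        peak, pv = cands[0]
        true_peak_ms = latency + D / 2
        assert abs(traces.t_ms[peak] - true_peak_ms) <= 1000 / 300 + 1e-9

    def test_separate_runs_give_separate_candidates(self, config):
        v = np.zeros(100)
        v[20:25] = 80.0
        v[60:65] = -120.0
        cands = candidate_events(v, config)
        assert len(cands) == 2
        assert cands[0][1] == 80.0 and cands[1][1] == -120.0


class TestOnset:
    def test_noise_free_onset_within_two_samples(self, config):
        trial, latency, _ = noise_free_trial()
        traces = differentiate_trace(trial, config)
        vel = traces.velocity_deg_s["left"]
        acc = traces.acceleration_deg_s2["left"]
        [(peak, _)] = candidate_events(vel, config)
        onset, edge = locate_onset(acc, vel, peak, config, traces.valid_start)
        assert not edge
        assert abs(traces.t_ms[onset] - latency) <= 2 * 1000 / 300

    def test_strictly_positive_acceleration_falls_back_to_argmin(self, config):
        n = 100
        vel = np.zeros(n)
        vel[40:61] = np.linspace(0, 200, 21)  # accelerating throughout
        acc = np.full(n, 50.0)
        acc[40:61] = np.linspace(10.0, 300.0, 21)
        onset, _ = locate_onset(acc, vel, 60, config, 0)
        window = acc[45:61]  # 50 ms = 15 samples before the peak
        assert onset == 45 + int(np.argmin(np.abs(window)))

    def test_truncated_window_sets_edge_flag(self, config):
        vel = np.zeros(100)
        vel[:11] = np.linspace(0, 200, 11)
        acc = np.ones(100)
        _, edge = locate_onset(acc, vel, 10, config, valid_start=5)
        assert edge


class TestOffset:
    def test_noise_free_offset_within_two_samples(self, config):
        trial, latency, D = noise_free_trial()
        traces = differentiate_trace(trial, config)
        vel = traces.velocity_deg_s["left"]
        [(peak, _)] = candidate_events(vel, config)
        offset, edge = locate_offset(vel, peak, config, traces.valid_stop)
        assert not edge
        assert abs(traces.t_ms[offset] - (latency + D)) <= 2 * 1000 / 300

    def test_monotone_velocity_to_trace_end_flags_edge(self, config):
        vel = np.linspace(0, 400, 100)
        offset, edge = locate_offset(vel, 99 - 40, config, 100)
        assert edge

    def test_exact_zero_sample_is_the_offset(self, config):
        vel = np.concatenate([np.zeros(10), [100, 200, 100, 0.0, 50], np.zeros(5)])
        offset, edge = locate_offset(vel, 11, config, vel.size)
        assert offset == 13 and not edge


class TestFixation:
    def test_steady_fixation_on_cross_passes(self, config):
        pos = np.zeros(100)
        assert fixation_precedes(pos, 60, 0.0, config)

    def test_sample_outside_radius_fails(self, config):
        pos = np.zeros(100)
        pos[30] = 1.6
        assert not fixation_precedes(pos, 60, 0.0, config)

    def test_drift_of_exactly_0p6_fails(self, config):
        pos = np.linspace(0.0, 0.6, 60)  # range == 0.6, strict rule
        assert not fixation_precedes(np.concatenate([pos, np.zeros(40)]),
                                     60, 0.0, config)

    def test_empty_window_fails(self, config):
        assert not fixation_precedes(np.zeros(100), 5, 0.0, config,
                                     valid_start=5)


class TestAcceptance:
    def _events(self, latency, config, **kw):
        trial, _, _ = noise_free_trial(latency=latency, **kw)
        return detect_events(trial, config=config)["left"]

    def test_onset_before_100ms_rejected_latency_low(self, config):
        # latency bounds are inclusive, so place the onset clearly below
        [event] = self._events(80.0, config)
        assert not event.accepted
        assert "latency_low" in event.rejection_reasons

    def test_onset_after_600ms_rejected_latency_high(self, config):
        [event] = self._events(650.0, config)
        assert "latency_high" in event.rejection_reasons

    def test_valid_latency_accepted(self, config):
        [event] = self._events(200.0, config)
        assert event.accepted and event.rejection_reasons == []

    def test_minimum_duration_is_inclusive(self, config):
        event_cfg = config.replace(min_duration_ms=12.0)
        [event] = self._events(200.0, event_cfg)
        assert event.duration_ms >= 12.0
        strict_cfg = config.replace(min_duration_ms=event.duration_ms)
        [again] = self._events(200.0, strict_cfg)
        assert again.accepted  # duration exactly at the bound passes

    def test_too_short_reason_triggerable(self, config):
        [event] = self._events(200.0,
                               config.replace(min_duration_ms=500.0))
        assert "too_short" in event.rejection_reasons

    def test_unstable_fixation_rejected(self, config):
        trial, *_ = noise_free_trial(latency=300.0)
        trial.x_left[10:20] += 2.0  # excursion off the cross before onset
        events = detect_events(trial, config=config)["left"]
        primary_like = [e for e in events
                        if "no_fixation" in e.rejection_reasons]
        assert primary_like


class TestPrimary:
    def test_earliest_accepted_event_wins(self, config):
        t = np.arange(300) * (1000 / 300)
        x = (minimum_jerk_position(10.0, 43.0, t - 150.0)
             + minimum_jerk_position(8.0, 38.6, t - 400.0))
        trial = make_trial(x=x)
        primaries = primary_saccade(trial, config=config)
        assert primaries["left"] is not None
        assert abs(primaries["left"].onset_ms - 150.0) < 10.0

    def test_no_candidates_gives_none(self, config):
        assert primary_saccade(make_trial(n=300), config=config) == {
            "left": None, "right": None}

    def test_noise_free_cohort_onsets_match_ground_truth(self, config):
        sim = SimulationConfig(noise_sd_deg=0.0, dropout_prob=0.0,
                               gain_sd=0.0)
        rng = np.random.default_rng(0)
        dt = 1000 / 300
        for i in range(40):
            trial, truth = simulate_trial(
                "prosaccade", "left" if i % 2 else "right",
                "far" if i % 3 else "close", 3, "S", "HC", sim, rng)
            primaries = primary_saccade(trial, config=config)
            for eye in ("left", "right"):
                assert primaries[eye] is not None
                assert abs(primaries[eye].onset_ms
                           - truth.true_onset_ms) <= dt + 1e-9

    def test_detection_mirror_equivariance(self, config):
        trial, *_ = noise_free_trial(direction="right")
        mirrored = trial.copy(x_left=-trial.x_left, x_right=-trial.x_right,
                              direction="left")
        a = primary_saccade(trial, config=config)["left"]
        b = primary_saccade(mirrored, config=config)["left"]
        assert a.onset_idx == b.onset_idx and a.offset_idx == b.offset_idx
        assert a.direction == "right" and b.direction == "left"
        assert a.peak_velocity_deg_s == pytest.approx(b.peak_velocity_deg_s)
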