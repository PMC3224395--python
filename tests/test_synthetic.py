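"""Tests of the synthetic sEMG generator: activation structure, signal
statistics, protocol timing and reproducibility."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from semgpipe.features import rms
from semgpipe.synthetic import (GROUP_DEFAULTS, MUSCLES, PINCH_CLASSES,
                                ProtocolEvent, ProtocolSchedule, SubjectProfile,
                                draw_profiles, make_activation_matrix,
                                make_schedule, simulate_ar_process,
                                simulate_cohort, simulate_recording)


def profile_with(separability, group="senior"):
    return SubjectProfile(subject_id="X", group=group, max_force=3.0,
                          max_torque=5.0, separability=separability)


class TestActivationMatrix:
    def test_rest_column_is_zero_and_values_bounded(self, senior_profile):
        act = make_activation_matrix(senior_profile)
        assert np.all(act.values[:, 0] == 0)
        assert np.all((act.values >= 0) & (act.values <= 1))
        # every non-rest gesture engages at least one muscle
        assert np.all(act.values[:, 1:].max(axis=0) > 0)

    def test_fcu_marks_ulnar_over_radial_deviation(self, senior_profile):
        # FCU assists wrist flexion with ulnar deviation, so its activation
        # for ulnar deviation (class 4) must exceed radial deviation (class 3)
        act = make_activation_matrix(senior_profile)
        fcu = MUSCLES.index("FCU")
        assert act.column(4)[fcu] > act.column(3)[fcu]
        ecr = MUSCLES.index("ECR")
        assert act.column(3)[ecr] > act.column(4)[ecr]

    def test_adjacent_middle_ring_pinches_are_closest_pinch_pair(
            self, senior_profile):
        act = make_activation_matrix(senior_profile)
        cols = {c: act.column(c) for c in PINCH_CLASSES}
        dists = {(a, b): np.linalg.norm(cols[a] - cols[b])
                 for i, a in enumerate(PINCH_CLASSES)
                 for b in PINCH_CLASSES[i + 1:]}
        closest = sorted(dists, key=dists.get)[:2]
        assert set(map(frozenset, closest)) == {frozenset({6, 7}),
                                                frozenset({13, 14})}

    def test_separability_scales_between_class_contrast(self):
        hi = make_activation_matrix(profile_with(1.0)).values[:, 1:]
        lo = make_activation_matrix(profile_with(0.5)).values[:, 1:]
        d_hi = pdist(hi.T)
        d_lo = pdist(lo.T)
        assert np.all(d_hi > d_lo)


class TestSimulateARProcess:
    def test_zero_coefficients_give_white_noise(self):
        x = simulate_ar_process([0.0, 0.0], n=20000, noise_sd=1.0, seed=3)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.03

    def test_ar1_lag_one_autocorrelation_matches_theory(self):
        x = simulate_ar_process([0.9, 0, 0, 0], n=10000, noise_sd=1.0, seed=3)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(0.9, abs=0.03)

    def test_non_stationary_coefficients_rejected(self):
        with pytest.raises(ValueError, match="non-stationary"):
            simulate_ar_process([1.05], n=100, noise_sd=1.0, seed=0)
        with pytest.raises(ValueError, match="non-stationary"):
            simulate_ar_process([1.0], n=100, noise_sd=1.0, seed=0)

    def test_deterministic_under_seed(self):
        a = simulate_ar_process([0.5, -0.2], n=500, noise_sd=2.0, seed=9)
        b = simulate_ar_process([0.5, -0.2], n=500, noise_sd=2.0, seed=9)
        np.testing.assert_array_equal(a, b)


class TestSimulateRecording:
    def test_bit_identical_under_same_seed(self, short_schedule, young_profile):
        a = simulate_recording(short_schedule, young_profile, seed=7)
        b = simulate_recording(short_schedule, young_profile, seed=7)
        assert a.channels.tobytes() == b.channels.tobytes()
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_seed_changes_samples_not_labels(self, short_schedule, young_profile):
        a = simulate_recording(short_schedule, young_profile, seed=1)
        b = simulate_recording(short_schedule, young_profile, seed=2)
        assert not np.array_equal(a.channels, b.channels)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_rest_only_recording_sits_at_noise_floor(self, young_profile):
        sched = ProtocolSchedule(name="C", arm_position="pronation", events=())
        rec = simulate_recording(sched, young_profile, seed=4, duration_s=6.0)
        assert np.all(rec.labels == 1)
        for c in range(4):
            level = rms(rec.channels[c][1024:])
            assert level == pytest.approx(young_profile.noise_floor, rel=0.25)

    def test_active_muscles_louder_than_rest(self, short_recording):
        rec = short_recording
        grasp = rec.labels == 2
        rest = rec.labels == 1
        for c in range(4):
            assert (rms(rec.channels[c][grasp]) >
                    2 * rms(rec.channels[c][rest]))

    def test_protocol_d_torque_alternates_sign_three_times_per_repetition(
            self, protocol_d_recording):
        rec = protocol_d_recording
        # median torque per event: radial positive, ulnar negative
        signs = []
        prev = 1
        for start, dur, cid in _event_spans(rec.labels, rec.fs):
            mid = slice(start + dur // 4, start + 3 * dur // 4)
            signs.append(np.sign(np.median(rec.torque[mid])))
        # 3 repetitions x (R, U, R, U) => + - + - three alternations each
        assert signs == [1, -1, 1, -1] * 3

    def test_schedule_longer_than_recording_rejected(self, short_schedule,
                                                     young_profile):
        with pytest.raises(ValueError, match="lasts only"):
            simulate_recording(short_schedule, young_profile, seed=0,
                               duration_s=3.0)


def _event_spans(labels, fs):
    spans = []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    edges = np.r_[0, boundaries, len(labels)]
    for s0, s1 in zip(edges[:-1], edges[1:]):
        if labels[s0] != 1:
            spans.append((s0, s1 - s0, labels[s0]))
    return spans


class TestCohort:
    def test_profiles_distinct_and_deterministic(self):
        a = draw_profiles(12, "senior", seed=42)
        b = draw_profiles(12, "senior", seed=42)
        assert len({p.subject_id for p in a}) == 12
        assert a == b

    def test_senior_strength_below_young_on_average(self):
        seniors = draw_profiles(12, "senior", seed=42)
        young = draw_profiles(7, "young", seed=42)
        assert (np.mean([p.max_force for p in seniors]) <
                np.mean([p.max_force for p in young]))
        assert (np.mean([p.separability for p in seniors]) <
                np.mean([p.separability for p in young]))

    def test_each_protocol_recording_has_six_seconds_of_gesture_data(self):
        recs = simulate_cohort(1, "young", seed=3)
        assert len(recs) == 6
        for rec in recs:
            assert np.sum(rec.labels != 1) >= 6 * 1024

    def test_group_parameter_defaults_order(self):
        assert (GROUP_DEFAULTS["senior"]["sep_mean"] <
                GROUP_DEFAULTS["young"]["sep_mean"])
        assert (GROUP_DEFAULTS["senior"]["force_mean"] <
                GROUP_DEFAULTS["young"]["force_mean"])


class TestScheduleValidation:
    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            ProtocolSchedule(name="C", arm_position="pronation", events=(
                ProtocolEvent(2, 0.0, 2.0, 0.5),
                ProtocolEvent(3, 1.0, 2.0, 0.5),
            ))

    def test_mvc_levels_per_protocol_kind(self):
        # sustained-force protocols run at 50% MVC; pinches at a
        # comfortable sub-maximal level
        for name in ("C", "D", "FC", "FD"):
            sched = make_schedule(name)
            assert all(ev.envelope_level == 0.5 for ev in sched.events)
        for name in ("E", "FE"):
            sched = make_schedule(name)
            assert all(ev.envelope_level < 0.5 for ev in sched.events)

    def test_supinated_protocols_use_supination_classes(self):
        for name in ("FC", "FD", "FE"):
            sched = make_schedule(name)
            assert sched.arm_position == "supination"
            assert all(ev.class_id >= 9 for ev in sched.events)
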