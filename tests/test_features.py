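"""Feature extractors: closed forms, oracle equivalence, AR recovery and
scale equivariance."""

import numpy as np
import pytest

from semgpipe.features import (ARModelSpec, EMGFeatureExtractor, FEATURE_NAMES,
                               ar_coefficients, extract_features, rms,
                               waveform_length)
from semgpipe.segmentation import Segment
from semgpipe.synthetic import simulate_ar_process


def brute_wl(x):
    total = 0.0
    for r in range(1, len(x)):
        total += abs(x[r] - x[r - 1])
    return total


def brute_rms(x):
    total = 0.0
    for v in x:
        total += v * v
    return (total / len(x)) ** 0.5


class TestWaveformLength:
    def test_constant_signal_is_zero(self):
        assert waveform_length([5, 5, 5, 5]) == 0.0

    def test_alternating_signal(self):
        assert waveform_length([0, 1, 0, 1]) == 3.0

    def test_matches_brute_force_on_random_windows(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 300))
            assert waveform_length(x) == pytest.approx(brute_wl(x), rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            waveform_length([1.0])


class TestRMS:
    def test_constant_gives_absolute_value(self):
        assert rms([-3.0] * 10) == pytest.approx(3.0)

    def test_two_point_closed_form(self):
        assert rms([3, 4]) == pytest.approx(np.sqrt(12.5))

    def test_sine_over_whole_periods_gives_amplitude_over_sqrt2(self):
        for A in (1.0, 2.5):
            t = np.arange(4096) / 1024
            x = A * np.sin(2 * np.pi * 8 * t)  # 32 whole periods
            assert rms(x) == pytest.approx(A / np.sqrt(2), abs=1e-6)

    def test_matches_brute_force_on_random_windows(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(1, 300))
            assert rms(x) == pytest.approx(brute_rms(x), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms([])


AR4_TRUE = np.array([0.55, -0.25, 0.10, -0.05])


class TestARCoefficients:
    @pytest.mark.parametrize("method", ["burg", "yule_walker"])
    def test_white_noise_coefficients_near_zero(self, method):
        x = simulate_ar_process([0.0], n=4096, noise_sd=1.0, seed=21)
        q = ar_coefficients(x, ARModelSpec(4, method))
        assert np.all(np.abs(q) < 0.08)

    @pytest.mark.parametrize("method", ["burg", "yule_walker"])
    def test_ar4_round_trip_recovery(self, method):
        x = simulate_ar_process(AR4_TRUE, n=8192, noise_sd=1.0, seed=8)
        q = ar_coefficients(x, ARModelSpec(4, method))
        np.testing.assert_allclose(q, AR4_TRUE, atol=0.05)

    def test_ar1_sign_convention_positive(self):
        # prediction form: positively lag-1-correlated data => q1 ~ +0.9
        x = simulate_ar_process([0.9, 0, 0, 0], n=8192, noise_sd=1.0, seed=2)
        q = ar_coefficients(x, ARModelSpec(4, "burg"))
        assert 0.85 <= q[0] <= 0.95

    def test_bias_shrinks_with_window_length(self):
        errs = []
        for n in (512, 2048, 8192):
            e = []
            for seed in range(6):
                x = simulate_ar_process(AR4_TRUE, n=n, noise_sd=1.0, seed=seed)
                q = ar_coefficients(x, ARModelSpec(4, "burg"))
                e.append(np.abs(q - AR4_TRUE).max())
            errs.append(np.mean(e))
        assert errs[0] > errs[1] > errs[2]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ar_coefficients(np.ones(256), ARModelSpec())

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            ar_coefficients(np.arange(3.0), ARModelSpec(order=4))


class TestScaleEquivariance:
    def test_amplitude_features_scale_ar_invariant(self, rng):
        x = rng.normal(size=256)
        for a in (0.5, 3.0, 1e3):
            assert waveform_length(a * x) == pytest.approx(
                a * waveform_length(x), rel=1e-9)
            assert rms(a * x) == pytest.approx(a * rms(x), rel=1e-9)
            np.testing.assert_allclose(ar_coefficients(a * x, ARModelSpec()),
                                       ar_coefficients(x, ARModelSpec()),
                                       atol=1e-6)


class TestExtractFeatures:
    def _segment(self, rng, label=2):
        return Segment(samples=rng.normal(size=(4, 256)), window_index=0,
                       start_sample=0, label=label, subject_id="T")

    def test_vector_has_24_features(self, rng):
        fv = extract_features(self._segment(rng))
        assert fv.values.shape == (24,)
        assert len(FEATURE_NAMES) == 24
        assert fv.label == 2

    def test_identical_segments_identical_features(self, rng):
        seg = self._segment(rng)
        a = extract_features(seg)
        b = extract_features(seg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_error_names_offending_channel(self, rng):
        seg = self._segment(rng)
        seg.samples[2] = 0.0  # FCU constant
        with pytest.raises(ValueError, match="FCU"):
            extract_features(seg)

    def test_active_window_has_larger_rms_than_rest(self, short_recording):
        from semgpipe.segmentation import segment_and_label
        segs = segment_and_label(short_recording, 256, 128,
                                 event_margin_s=0.25)
        rest = next(s for s in segs if s.label == 1)
        grasp = next(s for s in segs if s.label == 2)
        fr = extract_features(rest).values
        fg = extract_features(grasp).values
        rms_idx = [FEATURE_NAMES.index(f"{m}_rms")
                   for m in ("ED", "PL", "FCU", "ECR")]
        assert np.all(fg[rms_idx] > fr[rms_idx])


class TestEMGFeatureExtractorTransformer:
    def test_matches_functional_extraction(self, rng):
        X = rng.normal(size=(5, 4, 256))
        tf = EMGFeatureExtractor().fit(X)
        out = tf.transform(X)
        assert out.shape == (5, 24)
        seg = Segment(samples=X[0], window_index=0, start_sample=0)
        np.testing.assert_allclose(out[0], extract_features(seg).values)

    def test_rejects_wrong_shape(self, rng):
        tf = EMGFeatureExtractor().fit(rng.normal(size=(2, 4, 64)))
        with pytest.raises(ValueError):
            tf.transform(rng.normal(size=(2, 3, 64)))

    def test_sklearn_params_round_trip(self):
        tf = EMGFeatureExtractor(ar_order=3, ar_method="yule_walker")
        assert tf.get_params() == {"ar_order": 3, "ar_method": "yule_walker"}
        tf.set_params(ar_order=4)
        assert tf.ar_order == 4


class TestFeatureProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=64))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_wl_nonnegative_and_bounded_by_range_walk(self, xs):
        x = np.asarray(xs)
        wl = waveform_length(x)
        assert wl >= 0
        # each step is at most the full range, so wl <= (n-1) * range
        assert wl <= (len(x) - 1) * (x.max() - x.min()) + 1e-9

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=64))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_rms_between_mean_abs_and_max_abs(self, xs):
        x = np.asarray(xs)
        r = rms(x)
        assert np.mean(np.abs(x)) - 1e-9 <= r <= np.max(np.abs(x)) + 1e-9
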