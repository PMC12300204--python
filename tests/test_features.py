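import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazeid as gz
from gazeid.errors import ValidationError
from gazeid.features import (
    CHANNELS,
    fit_channel_scalers,
    raw_segment_channels,
    scale_channels,
)
from gazeid.segmentation import PositionWindow, split_segments


def brute_force_dft_amplitude(a):
    """Independent double-loop evaluation of |sum_m a_m e^{-2 pi i m k / n}|."""
    n = len(a)
    out = np.empty(n)
    for k in range(n):
        acc = 0j
        for m in range(n):
            acc += a[m] * np.exp(-2j * np.pi * m * k / n)
        out[k] = abs(acc)
    return out


def window_from(x):
    return PositionWindow("s", "r", 0, np.asarray(x, dtype=float))


class TestDerivative:
    def test_constant_sequence_gives_zeros(self):
        np.testing.assert_array_equal(gz.derivative(np.full(10, 3.3)), np.zeros(9))

    def test_forced_by_definition(self):
        np.testing.assert_allclose(
            gz.derivative(np.array([0.0, 1.0, 3.0, 6.0])), [1000.0, 2000.0, 3000.0]
        )

    def test_length_shrinks_by_one(self):
        assert gz.derivative(np.zeros(303)).size == 302

    def test_chain_on_window_leaves_300(self):
        x = np.random.default_rng(0).random(303)
        j = gz.derivative(gz.derivative(gz.derivative(x)))
        assert j.size == 300

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            gz.derivative(np.array([1.0]))


class TestPctChange:
    def test_direct_formula(self):
        np.testing.assert_allclose(gz.pct_change(np.array([2.0, 3.0, 3.0])), [0.5, 0.0])

    def test_zero_denominator_guard(self):
        np.testing.assert_array_equal(gz.pct_change(np.array([0.0, 5.0])), [0.0])

    @given(c=st.floats(0.5, 100).flatmap(lambda v: st.sampled_from([v, -v])))
    @settings(deadline=None, max_examples=30)
    def test_scale_invariance(self, c):
        base = np.array([1.0, 2.0, 4.0])
        np.testing.assert_allclose(gz.pct_change(c * base), [1.0, 1.0], rtol=1e-12)


class TestAmplitudeSpectrum:
    def test_constant_signal_is_dc_only(self):
        spec = gz.amplitude_spectrum(np.full(100, 2.5))
        assert spec[0] == pytest.approx(250.0)
        np.testing.assert_allclose(spec[1:], 0.0, atol=1e-10)

    def test_unit_impulse_is_flat(self):
        x = np.zeros(100)
        x[0] = 1.0
        np.testing.assert_allclose(gz.amplitude_spectrum(x), np.ones(100), atol=1e-12)

    def test_conjugate_symmetry_on_real_input(self):
        spec = gz.amplitude_spectrum(np.random.default_rng(1).random(100))
        np.testing.assert_allclose(spec[1:], spec[1:][::-1], rtol=1e-10)

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(20):
            x = rng.normal(0, 1, 100)
            ref = brute_force_dft_amplitude(x)
            got = gz.amplitude_spectrum(x)
            worst = max(worst, np.max(np.abs(got - ref) / np.maximum(ref, 1e-30)))
        assert worst < 1e-9

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            gz.amplitude_spectrum(np.zeros(99))


class TestMinMaxScale:
    def test_definition(self):
        np.testing.assert_allclose(gz.minmax_scale(np.array([2.0, 4.0, 6.0]), 2, 6), [0, 0.5, 1])

    def test_degenerate_range_maps_to_zeros(self):
        np.testing.assert_array_equal(gz.minmax_scale(np.full(5, 7.0), 7, 7), np.zeros(5))

    def test_out_of_range_values_clip(self):
        assert gz.minmax_scale(np.array([10.0]), 0, 5)[0] == 1.0
        assert gz.minmax_scale(np.array([-3.0]), 0, 5)[0] == 0.0


class TestTimeSeriesFeatures:
    def test_three_segments_of_shape_100x7(self, cohort_recordings, schedule):
        rec = next(iter(cohort_recordings.values()))
        w = gz.extract_window(rec, 0, schedule)
        feats = gz.build_ts_features(w)
        assert len(feats) == 3
        for f in feats:
            assert f.data.shape == (100, len(CHANNELS))

    def test_linear_ramp_has_zero_acceleration_and_jerk(self):
        w = window_from(np.linspace(0, 3, 303))
        for f in gz.build_ts_features(w):
            np.testing.assert_allclose(f.channel("a"), 0.0, atol=1e-6)
            np.testing.assert_allclose(f.channel("j"), 0.0, atol=1e-3)

    def test_scaled_channels_within_unit_interval(self):
        rng = np.random.default_rng(3)
        windows = [window_from(np.cumsum(rng.normal(0, 0.01, 303))) for _ in range(4)]
        raw = np.concatenate([raw_segment_channels(w) for w in windows])
        scalers = fit_channel_scalers(raw[:6])  # fit on half, apply to all
        scaled = scale_channels(raw, scalers)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0

    def test_extraction_is_deterministic(self):
        w = window_from(np.sin(np.linspace(0, 8, 303)))
        a = raw_segment_channels(w)
        b = raw_segment_channels(window_from(w.raw_x.copy()))
        np.testing.assert_array_equal(a, b)

    def test_pct_channels_are_right_padded_to_100(self):
        w = window_from(np.cumsum(np.random.default_rng(0).normal(0, 0.01, 303)))
        raw = raw_segment_channels(w)
        for col in (3, 4, 5):
            assert raw[0, -1, col] == raw[0, -2, col]  # repeated final value


class TestStatFeatures:
    def test_population_std_oracle(self):
        ts = gz.TimeSeriesFeatures(np.tile([1, 2, 3, 4], 25)[:, None] * np.ones((1, 7)))
        stats = gz.build_stat_features(ts)
        # v quadruple: min, max, mean, population std of {1,2,3,4} repeated
        assert stats.values[0] == 1.0
        assert stats.values[1] == 4.0
        assert stats.values[2] == pytest.approx(2.5)
        assert stats.values[3] == pytest.approx(np.sqrt(1.25))

    def test_constant_channel_has_zero_std(self):
        ts = gz.TimeSeriesFeatures(np.full((100, 7), 3.0))
        v = gz.build_stat_features(ts).values
        assert v.tolist() == [3.0, 3.0, 3.0, 0.0] * 4

    def test_vector_has_16_ordered_entries(self, cohort_recordings, schedule):
        rec = next(iter(cohort_recordings.values()))
        w = gz.extract_window(rec, 1, schedule)
        for ts in gz.build_ts_features(w):
            vals = gz.build_stat_features(ts).values
            assert vals.shape == (16,)
            for q in range(4):
                mn, mx, mean, _ = vals[4 * q : 4 * q + 4]
                assert mn <= mean <= mx
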