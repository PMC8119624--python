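import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdiv import (
    SyntheticStudyConfig,
    analytic_amplitude,
    as_clean,
    binarize,
    flatten,
    generate_participant,
    lz76_count,
    lzc_for_recording,
    normalized_lzc,
)
from eegdiv.preprocessing import bandpass_fir

from .conftest import make_recording
from .oracles import lz76_count_brute


class TestAnalyticAmplitude:
    def test_unit_sinusoid_has_unit_envelope(self):
        t = np.arange(2500) / 250.0
        amp = analytic_amplitude(np.sin(2 * np.pi * 10 * t)[None, :])
        central = amp[0, 250:-250]
        np.testing.assert_allclose(central, 1.0, rtol=0.02)

    def test_am_tone_envelope_recovered(self):
        t = np.arange(5000) / 250.0
        modulator = 0.5 + 0.25 * np.sin(2 * np.pi * 1.0 * t)
        amp = analytic_amplitude((modulator * np.sin(2 * np.pi * 20 * t))[None, :])
        core = slice(250, -250)
        r = np.corrcoef(amp[0, core], modulator[core])[0, 1]
        assert r > 0.95

    def test_zero_signal_zero_amplitude(self):
        amp = analytic_amplitude(np.zeros((2, 100)))
        np.testing.assert_array_equal(amp, 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            analytic_amplitude(np.zeros((1, 32)))


class TestBinarize:
    def test_constant_channel_is_all_zeros(self):
        out = binarize(np.full((1, 100), 3.3))
        np.testing.assert_array_equal(out, 0)

    def test_sinusoidal_envelope_half_ones(self):
        t = np.arange(10_000) / 250.0
        envelope = 1.0 + 0.5 * np.sin(2 * np.pi * 0.7 * t)
        frac = binarize(envelope[None, :]).mean()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_per_channel_threshold_scale_invariance(self, rng):
        amp = np.abs(rng.standard_normal((2, 500)))
        scaled = amp * np.array([[1.0], [250.0]])
        np.testing.assert_array_equal(binarize(amp), binarize(scaled))


class TestFlatten:
    def test_observation_major_trace(self):
        mat = np.array([[1, 0, 1], [0, 0, 1]], dtype=np.uint8)
        np.testing.assert_array_equal(flatten(mat), [1, 0, 0, 0, 1, 1])

    def test_single_row_is_identity(self):
        row = np.array([[1, 0, 1, 1]], dtype=np.uint8)
        np.testing.assert_array_equal(flatten(row), row[0])

    def test_channel_permutation_preserves_length(self, rng):
        mat = rng.integers(0, 2, (4, 50)).astype(np.uint8)
        assert len(flatten(mat[::-1])) == len(flatten(mat))

    def test_channel_major_option(self):
        mat = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        np.testing.assert_array_equal(flatten(mat, "channel_major"), [1, 0, 0, 1])


class TestLz76Count:
    def test_canonical_values(self):
        assert lz76_count("0") == 1
        assert lz76_count("0000000000") == 2  # parse 0 | 000000000
        assert lz76_count("0001101001000101") == 6

    def test_accepts_arrays_and_strings(self):
        assert lz76_count(np.array([0, 0, 0, 1, 1, 0, 1], np.uint8)) == lz76_count(
            "0001101"
        )

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            lz76_count("0102")
        with pytest.raises(ValueError):
            lz76_count(np.array([0, 2]))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet="01", min_size=1, max_size=200))
    def test_matches_brute_force_definition(self, s):
        assert lz76_count(s) == lz76_count_brute(s)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="01", min_size=1, max_size=100),
        st.text(alphabet="01", max_size=50),
    )
    def test_bounds_and_monotone_under_extension(self, s, t):
        c = lz76_count(s)
        assert 1 <= c <= len(s)
        assert lz76_count(s + t) >= c


class TestNormalizedLzc:
    def test_iid_string_scores_near_one(self, rng):
        s = rng.integers(0, 2, 10_000).astype(np.uint8)
        score = normalized_lzc(s, seed=7)
        assert score.normalized == pytest.approx(1.0, abs=0.05)

    def test_periodic_string_scores_near_zero(self):
        s = np.tile([0, 1], 5_000).astype(np.uint8)
        score = normalized_lzc(s, seed=7)
        assert score.normalized < 0.05

    def test_deterministic_for_fixed_seed(self, rng):
        mat = rng.integers(0, 2, (4, 500)).astype(np.uint8)
        a = normalized_lzc(mat, seed=3)
        b = normalized_lzc(mat, seed=3)
        assert a == b

    def test_single_symbol_rejected(self):
        with pytest.raises(ValueError, match="single-symbol"):
            normalized_lzc(np.zeros((2, 50), np.uint8))


class TestLzcForRecording:
    def test_window_count_arithmetic(self, rng):
        rec = as_clean(make_recording(rng.standard_normal((4, 15_000))))
        result = lzc_for_recording(rec, window_s=10.0, seed=0)
        assert result.n_windows == 6
        assert result.score == pytest.approx(
            np.mean([w.normalized for w in result.window_scores])
        )

    def test_shared_sinusoid_scores_low(self):
        t = np.arange(5000) / 250.0
        shared = np.sin(2 * np.pi * 10 * t)
        rec = as_clean(make_recording(np.tile(shared, (8, 1))))
        result = lzc_for_recording(rec, window_s=10.0, seed=0)
        assert result.score < 0.2

    def test_amplitude_scaling_invariance(self, rng):
        data = rng.standard_normal((4, 5000))
        gains = np.array([[1.0], [10.0], [0.1], [1000.0]])
        a = lzc_for_recording(as_clean(make_recording(data)), seed=5)
        b = lzc_for_recording(as_clean(make_recording(data * gains)), seed=5)
        assert a.score == pytest.approx(b.score, abs=1e-12)

    def test_no_complete_window_is_an_error(self, rng):
        rec = as_clean(make_recording(rng.standard_normal((2, 1000))))
        with pytest.raises(ValueError, match="window"):
            lzc_for_recording(rec, window_s=10.0)


class TestDiversityKnob:
    def participant_score(self, knob, idx, seed=11):
        config = SyntheticStudyConfig(
            n_participants=3,
            duration_meditation_s=30.0,
            duration_mind_wandering_s=30.0,
            diversity_knob={"meditation": knob, "mind_wandering": knob},
            master_seed=seed,
        )
        med, _ = generate_participant(config, idx)
        return lzc_for_recording(as_clean(bandpass_fir(med)), seed=seed).score

    def test_mean_lzc_monotone_decreasing_in_knob(self):
        means = [
            np.mean([self.participant_score(k, i) for i in range(3)])
            for k in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_equal_knobs_give_no_systematic_difference(self):
        config = SyntheticStudyConfig(
            n_participants=8,
            duration_meditation_s=30.0,
            duration_mind_wandering_s=30.0,
            diversity_knob={"meditation": 0.0, "mind_wandering": 0.0},
            master_seed=2,
        )
        deltas = []
        for i in range(8):
            med, mw = generate_participant(config, i)
            s_med = lzc_for_recording(as_clean(bandpass_fir(med)), seed=1).score
            s_mw = lzc_for_recording(as_clean(bandpass_fir(mw)), seed=1).score
            deltas.append(s_med - s_mw)
        assert abs(np.mean(deltas)) < 0.01
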