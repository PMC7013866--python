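import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from henvox.audio_io import AudioClip
from henvox.features import (
    FEATURE_NAMES,
    FeatureVector,
    estimate_formants,
    estimate_pitch,
    extract_features,
    jitter,
    shimmer,
    spectral_centroid,
    spectral_energy,
    spectral_spread,
    zero_crossing_rate,
)

from .conftest import RATE, tone


class TestPitch:
    def test_pure_sine_within_1hz(self):
        track = estimate_pitch(tone(440.0, 1.0), 200, 4000)
        voiced = track.f0[track.voicing]
        assert len(voiced) > 10
        assert np.abs(voiced - 440.0).max() < 1.0

    def test_two_harmonic_tone_no_octave_error(self):
        """Energy at 500 + 1000 Hz must read as 500, not 1000."""
        t = np.arange(RATE) / RATE
        x = np.sin(2 * np.pi * 500 * t) + 0.8 * np.sin(2 * np.pi * 1000 * t)
        track = estimate_pitch(AudioClip(samples=x, rate=RATE), 200, 4000)
        voiced = track.f0[track.voicing]
        assert np.abs(voiced - 500.0).max() < 1.0

    def test_white_noise_mostly_unvoiced(self):
        rng = np.random.default_rng(0)
        clip = AudioClip(samples=rng.standard_normal(RATE), rate=RATE)
        track = estimate_pitch(clip, 200, 4000)
        assert (~track.voicing).mean() >= 0.9

    def test_too_short_event_is_all_unvoiced(self):
        clip = tone(440.0, 0.005)  # << 2 periods at fmin=200
        track = estimate_pitch(clip, 200, 4000)
        assert not track.voicing.any()

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            estimate_pitch(tone(440), 4000, 200)


class TestFormants:
    def _resonator_noise(self, freqs=(1000.0, 2500.0, 4000.0), rate=RATE,
                         seed=1, duration=1.0):
        """White noise through a parallel resonator bank (formant synthesis)."""
        rng = np.random.default_rng(seed)
        src = rng.standard_normal(int(duration * rate))
        x = np.zeros_like(src)
        for f, w in zip(freqs, (1.0, 0.7, 0.5)):
            b, a = sps.iirpeak(f, Q=10, fs=rate)
            x += w * sps.lfilter(b, a, src)
        return AudioClip(samples=x / np.abs(x).max(), rate=rate)

    def test_recovers_known_resonators_within_10pct(self):
        clip = self._resonator_noise()
        track = estimate_formants(clip, 3)
        means = np.nanmean(track.freqs, axis=0)
        for est, true in zip(means, (1000.0, 2500.0, 4000.0)):
            assert abs(est - true) / true < 0.10

    def test_rate_invariance_of_first_formant(self):
        """F1 agrees across sampling rates when the all-pole order scales
        with the bandwidth being modelled."""
        f1_16k = np.nanmean(estimate_formants(self._resonator_noise(), 3).freqs[:, 0])
        clip8 = self._resonator_noise(freqs=(1000.0, 2500.0, 3800.0), rate=8000)
        f1_8k = np.nanmean(
            estimate_formants(clip8, 3, lpc_order=6, frame_len=256).freqs[:, 0])
        assert abs(f1_16k - f1_8k) / f1_16k < 0.10

    def test_white_noise_still_yields_finite_perturbations(self):
        rng = np.random.default_rng(2)
        clip = AudioClip(samples=rng.standard_normal(RATE // 2), rate=RATE)
        track = estimate_formants(clip, 3)
        j = jitter(track.freqs[:, 0])
        s = shimmer(track.amps[:, 0])
        for v in (j, s):
            assert np.isnan(v) or (np.isfinite(v) and v >= 0)

    def test_fewer_than_three_formants_rejected(self):
        with pytest.raises(ValueError):
            estimate_formants(tone(440), 2)


class TestJitterShimmer:
    def test_constant_track_is_zero(self):
        assert jitter(np.array([300.0, 300.0, 300.0])) == 0.0
        assert shimmer(np.array([1.0, 1.0, 1.0])) == 0.0

    def test_hand_computed_jitter(self):
        # diffs 2,2,2 -> mean 2; mean value 101 -> 0.0198
        assert jitter(np.array([100.0, 102.0, 100.0, 102.0])) == pytest.approx(
            2 / 101, abs=1e-6)

    def test_hand_computed_shimmer(self):
        # diffs 0.5, 0.5 -> mean 0.5; mean amp 0.8333 -> 0.6
        assert shimmer(np.array([1.0, 0.5, 1.0])) == pytest.approx(0.6, abs=1e-9)

    def test_fewer_than_two_values_flagged_missing(self):
        assert np.isnan(jitter(np.array([100.0])))
        assert np.isnan(jitter(np.array([np.nan, 100.0])))

    @given(st.lists(st.floats(1.0, 1e4), min_size=2, max_size=30),
           st.floats(0.01, 100.0))
    @settings(max_examples=150, deadline=None)
    def test_scale_invariance(self, values, k):
        v = np.asarray(values)
        assert jitter(k * v) == pytest.approx(jitter(v), rel=1e-9)


class TestZeroCrossingRate:
    def test_alternating_signs_maximal(self):
        frame = np.tile([1.0, -1.0], 256)
        assert zero_crossing_rate(frame) == 1.0

    def test_all_positive_is_zero(self):
        assert zero_crossing_rate(np.ones(512)) == 0.0

    def test_1khz_sine_rate(self):
        x = tone(1000.0, 512 / RATE).samples
        expected = 2 * 1000 / RATE  # two crossings per cycle
        assert zero_crossing_rate(x) == pytest.approx(expected, abs=1 / 511)

    def test_zeros_count_as_positive(self):
        assert zero_crossing_rate(np.array([0.0, -1.0, 0.0, -1.0])) == 1.0


class TestSpectralFeatures:
    def test_single_bin_energy_is_zero(self):
        e = np.zeros(257)
        e[40] = 7.0
        assert spectral_energy(e) == 0.0

    def test_equal_bins_attain_log10_L(self):
        assert spectral_energy(np.ones(257)) == pytest.approx(np.log10(257))

    def test_energy_matches_brute_force_sum(self):
        """Term-by-term evaluation of the normalised-energy sum."""
        rng = np.random.default_rng(3)
        e = rng.uniform(0, 5, 257)
        brute = np.log10(sum((x / e.max()) ** 2 for x in e))
        assert spectral_energy(e) == pytest.approx(brute, abs=1e-12)

    def test_centroid_single_and_symmetric_bins(self):
        freqs = np.array([1000.0, 2000.0, 3000.0])
        assert spectral_centroid(np.array([0, 5, 0.0]), freqs) == 2000.0
        assert spectral_centroid(np.array([1, 0, 1.0]), freqs) == 2000.0

    def test_spread_of_two_equal_bins_is_half_separation(self):
        freqs = np.array([1000.0, 3000.0])
        assert spectral_spread(np.array([1.0, 1.0]), freqs) == pytest.approx(1000.0)
        assert spectral_spread(np.array([1.0, 0.0]), freqs) == 0.0

    def test_moments_match_weighted_mean_oracle(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 1, 257)
        f = np.fft.rfftfreq(512, 1 / RATE)
        c = float(np.average(f, weights=m))
        s = float(np.sqrt(np.average((f - c) ** 2, weights=m)))
        assert spectral_centroid(m, f) == pytest.approx(c, rel=1e-12)
        assert spectral_spread(m, f) == pytest.approx(s, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_centroid_between_min_and_max_frequency(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0, 1, 64) + 1e-9
        f = np.linspace(100, 8000, 64)
        assert 100 <= spectral_centroid(m, f) <= 8000


class TestExtractFeatures:
    def test_feature_order_matches_canonical_layout(self):
        assert FEATURE_NAMES == (
            "jitter_f0", "jitter_F1", "jitter_F2", "shimmer_F1", "shimmer_F3",
            "zcr", "spectral_spread", "spectral_energy", "spectral_centroid",
        )

    def test_deterministic_on_identical_audio(self, class_specs):
        from henvox.synth import synth_call

        clip, _ = synth_call(class_specs["gakel"], RATE, 5)
        a = extract_features(clip)
        b = extract_features(clip)
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_silence_dropped(self):
        clip = AudioClip(samples=np.zeros(2048), rate=RATE)
        assert extract_features(clip) is None

    def test_gain_invariance_of_full_vector(self, class_specs):
        """All nine features survive a +-20 dB gain change."""
        from henvox.synth import synth_call

        clip, _ = synth_call(class_specs["others"], RATE, 6)
        base = extract_features(clip).values
        for gain_db in (-20.0, 20.0):
            scaled = AudioClip(samples=clip.samples * 10 ** (gain_db / 20),
                               rate=RATE)
            vals = extract_features(scaled).values
            np.testing.assert_allclose(vals, base, rtol=1e-6, equal_nan=True)

    def test_gakel_less_jittery_than_squawk(self, class_specs):
        """Generator construction orders the classes by pitch perturbation."""
        from henvox.synth import synth_call

        rng = np.random.default_rng(7)
        gakel = np.nanmean([
            extract_features(synth_call(class_specs["gakel"], RATE, rng)[0]).values[0]
            for _ in range(8)])
        squawk = np.nanmean([
            extract_features(synth_call(class_specs["squawk"], RATE, rng)[0]).values[0]
            for _ in range(8)])
        assert gakel < squawk

    def test_class_separation_in_feature_space(self, small_corpus, cfg):
        """At least 5 of 9 features separate some class pair at d >= 1."""
        from henvox.pipeline import corpus_features

        X, y, _ = corpus_features(small_corpus.clips, small_corpus.truth_events,
                                  cfg, use_truth_intervals=True)
        classes = sorted(set(y))
        separated = 0
        for f in range(9):
            best_d = 0.0
            for i, a in enumerate(classes):
                for b in classes[i + 1:]:
                    xa, xb = X[y == a, f], X[y == b, f]
                    xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
                    if len(xa) < 2 or len(xb) < 2:
                        continue
                    pooled = np.sqrt((xa.var(ddof=1) + xb.var(ddof=1)) / 2)
                    if pooled > 0:
                        best_d = max(best_d, abs(xa.mean() - xb.mean()) / pooled)
            if best_d >= 1.0:
                separated += 1
        assert separated >= 5


def test_feature_vector_requires_nine_values():
    with pytest.raises(ValueError):
        FeatureVector(values=np.zeros(8))
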