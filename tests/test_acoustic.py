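"""Pitch tracking and the jitter/shimmer/HNR feature families."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voicepd as v
from voicepd.acoustic import (
    MIN_CYCLES,
    NoVoicedSpeechError,
    PitchTrack,
    hnr,
    jitter_features,
    pitch_features,
    shimmer_features,
    track_pitch,
)
from voicepd.preprocess import Waveform


def tone_wave(freq=150.0, duration_s=2.0, rate=16000, amp=0.8):
    t = np.arange(int(duration_s * rate)) / rate
    return Waveform(amp * np.sin(2 * np.pi * freq * t), rate)


def synthetic_track(periods_s, amps=None) -> PitchTrack:
    """PitchTrack carrying given periods/amplitudes, for arithmetic tests."""
    periods_s = np.asarray(periods_s, dtype=float)
    if amps is None:
        amps = np.ones_like(periods_s)
    n = periods_s.size
    return PitchTrack(
        frame_times=np.arange(n) * 0.01,
        f0=np.full(n, 1.0 / periods_s.mean()),
        voiced=np.ones(n, dtype=bool),
        cycle_times=np.concatenate([[0], np.cumsum(periods_s)]),
        periods=periods_s,
        peak_amps=np.asarray(amps, dtype=float),
        rate=16000,
    )


class TestTrackPitch:
    def test_pure_tone_f0(self):
        pt = track_pitch(tone_wave(150.0))
        assert np.median(pt.voiced_f0) == pytest.approx(150.0, abs=1.0)
        assert np.allclose(pt.periods, 1 / 150, atol=1 / 150 * 0.02)

    def test_white_noise_mostly_unvoiced(self):
        unvoiced_fracs = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(24000) * 0.3
            try:
                pt = track_pitch(Waveform(x, 16000))
                unvoiced_fracs.append(1 - pt.voiced.mean())
            except NoVoicedSpeechError:
                unvoiced_fracs.append(1.0)
        assert np.mean(unvoiced_fracs) >= 0.90

    def test_jittered_tone_period_spread(self):
        # 150 Hz tone with 3% period jitter, built sample-exact
        rng = np.random.default_rng(7)
        rate, periods = 16000, []
        t, phases = 0.0, []
        while t < 2.0:
            T = (1 / 150) * (1 + 0.03 * rng.standard_normal())
            periods.append(T)
            phases.append(t)
            t += T
        x = np.zeros(int(2.05 * rate))
        samp = np.arange(x.size) / rate
        for t0, T in zip(phases, periods):
            k = (samp >= t0) & (samp < t0 + T)
            x[k] = np.sin(2 * np.pi * (samp[k] - t0) / T)
        pt = track_pitch(Waveform(0.8 * x, rate))
        rel_sd = np.std(pt.periods) / np.mean(pt.periods)
        assert rel_sd == pytest.approx(0.03, rel=0.3)

    def test_silence_raises(self):
        with pytest.raises(NoVoicedSpeechError):
            track_pitch(Waveform(np.zeros(16000) + 1e-6, 16000))

    def test_period_amp_pairing(self):
        pt = track_pitch(tone_wave())
        assert pt.periods.size == pt.peak_amps.size
        assert np.all(pt.periods > 0)


class TestJitterFeatures:
    def test_alternating_periods_hand_oracle(self):
        # T = 10,12 ms alternating, 12 periods: 11 diffs of 2 ms
        T = np.array([10, 12] * 6) / 1000.0
        f = jitter_features(synthetic_track(T))
        assert f["LocalJitter"] == pytest.approx(2 / 11, rel=1e-9)
        assert f["LocalAbsoluteJitter"] == pytest.approx(0.002, rel=1e-9)

    def test_constant_periods_all_zero(self):
        f = jitter_features(synthetic_track(np.full(20, 0.007)))
        for name, val in f.items():
            assert val == pytest.approx(0.0, abs=1e-15), name

    @given(st.lists(st.floats(min_value=0.003, max_value=0.02), min_size=12, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ddp_is_three_times_rap(self, periods):
        f = jitter_features(synthetic_track(np.array(periods)))
        assert f["DdpJitter"] == pytest.approx(3 * f["RapJitter"], abs=1e-12)

    def test_too_few_periods_marked_missing(self):
        f = jitter_features(synthetic_track(np.full(MIN_CYCLES - 1, 0.006)))
        assert all(np.isnan(val) for val in f.values())


class TestShimmerFeatures:
    def test_alternating_amps_hand_oracle(self):
        A = np.array([1.0, 1.1] * 6)
        f = shimmer_features(synthetic_track(np.full(12, 0.006), A))
        assert f["LocalShimmer"] == pytest.approx(0.1 / 1.05, rel=1e-9)
        assert f["LocaldbShimmer"] == pytest.approx(20 * np.log10(1.1), rel=1e-9)

    def test_constant_amps_all_zero(self):
        f = shimmer_features(synthetic_track(np.full(20, 0.006), np.full(20, 0.5)))
        for name, val in f.items():
            assert val == pytest.approx(0.0, abs=1e-15), name

    @given(st.lists(st.floats(min_value=0.05, max_value=2.0), min_size=12, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dda_is_three_times_apq3(self, amps):
        f = shimmer_features(synthetic_track(np.full(len(amps), 0.006), np.array(amps)))
        assert f["DdaShimmer"] == pytest.approx(3 * f["Apq3Shimmer"], abs=1e-12)

    def test_nonpositive_amp_dropped(self):
        A = np.concatenate([np.full(15, 1.0), [0.0]])
        f = shimmer_features(synthetic_track(np.full(16, 0.006), A))
        assert f["LocalShimmer"] == pytest.approx(0.0, abs=1e-15)


class TestAmplitudeInvariance:
    def test_dimensionless_features_scale_invariant(self):
        p = v.VoiceParams(f0_base=140, jitter_frac=0.02, shimmer_frac=0.06,
                          hnr_db=25, seed=11, duration_s=1.5)
        w = v.synthesize_voice(p)
        tw, _ = v.trim_to_speech(w)
        half = Waveform(tw.samples * 0.5, tw.rate)
        f1 = {**jitter_features(track_pitch(tw)), **shimmer_features(track_pitch(tw))}
        f2 = {**jitter_features(track_pitch(half)), **shimmer_features(track_pitch(half))}
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], abs=1e-6), name


class TestHNR:
    def test_clean_tone_high_hnr(self):
        w = tone_wave(150.0)
        assert hnr(w, track_pitch(w)) >= 30.0

    def test_generator_calibration_recovered(self):
        p = v.VoiceParams(f0_base=160, f0_drift_sd=0, jitter_frac=0, shimmer_frac=0,
                          hnr_db=10, seed=1, duration_s=2.0)
        w = v.synthesize_voice(p)
        tw, _ = v.trim_to_speech(w)
        est = hnr(tw, track_pitch(tw))
        assert est == pytest.approx(10.0, abs=3.0)

    def test_noise_with_forced_voicing_nonpositive(self):
        rng = np.random.default_rng(2)
        w = Waveform(rng.standard_normal(24000) * 0.4, 16000)
        n_frames = 1 + (w.samples.size - 640) // 160
        pt = PitchTrack(
            frame_times=np.arange(n_frames) * 0.01,
            f0=np.full(n_frames, 150.0),
            voiced=np.ones(n_frames, dtype=bool),
            cycle_times=np.array([]), periods=np.array([]),
            peak_amps=np.array([]), rate=16000,
        )
        assert hnr(w, pt) <= 0.0

    def test_hnr_decreases_with_generator_noise(self):
        ests = []
        for hnr_db in (30, 20, 10):
            p = v.VoiceParams(f0_base=150, f0_drift_sd=0, jitter_frac=0.003,
                              shimmer_frac=0.01, hnr_db=hnr_db, seed=5, duration_s=1.5)
            w = v.synthesize_voice(p)
            tw, _ = v.trim_to_speech(w)
            ests.append(hnr(tw, track_pitch(tw)))
        assert ests[0] > ests[1] > ests[2]


def test_local_jitter_monotone_in_generator_jitter():
    """Mean extracted LocalJitter is nondecreasing over jitter levels."""
    levels = [0.0, 0.01, 0.02, 0.04]
    means = []
    for level in levels:
        vals = []
        for seed in range(10):
            p = v.VoiceParams(f0_base=150, f0_drift_sd=0, jitter_frac=level,
                              shimmer_frac=0.02, hnr_db=30, seed=100 + seed,
                              duration_s=1.2, pad_pre_s=0.1, pad_post_s=0.1)
            w = v.synthesize_voice(p)
            tw, _ = v.trim_to_speech(w)
            vals.append(jitter_features(track_pitch(tw))["LocalJitter"])
        means.append(np.mean(vals))
    assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))


def test_pitch_features_match_contour():
    pt = track_pitch(tone_wave(200.0))
    f = pitch_features(pt)
    assert f["MedianPitch"] == pytest.approx(200.0, abs=1.5)
    assert f["MeanPitch"] == pytest.approx(200.0, abs=1.5)
    assert f["StdDevPitch"] < 3.0
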