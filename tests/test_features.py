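"""Acoustic descriptor contracts: MFCC, chroma, spectral statistics,
pitch tracking, harmonic counting, assembly and standardization."""

import numpy as np
import pandas as pd
import pytest

from manavoc import features
from manavoc.features import (
    SET1_NAMES,
    SET2_NAMES,
    assemble_features,
    compute_chroma,
    compute_mfcc,
    compute_spectral_stats,
    detect_harmonics,
    detect_harmonics_spectrum,
    estimate_pitch_track,
    peak_frequency,
    standardize,
    summarize_pitch,
)
from manavoc.synth import Vocalization

from conftest import simple_squeak, simple_squeal

SR = 48000


def tone(freq, duration=0.3, amp=0.8, sr=SR):
    t = np.arange(int(duration * sr)) / sr
    return Vocalization("t", amp * np.sin(2 * np.pi * freq * t), sr)


class TestMfcc:
    def test_deterministic(self):
        v = simple_squeak(seed=2)
        assert np.array_equal(compute_mfcc(v), compute_mfcc(v))

    def test_gain_invariance(self):
        # a global gain shifts every log-mel energy by a constant, which
        # projects only onto the omitted 0th DCT basis
        v = simple_squeak(seed=2)
        scaled = Vocalization("s", v.samples * 10, SR)
        assert np.max(np.abs(compute_mfcc(v) - compute_mfcc(scaled))) < 1e-6

    def test_distinct_spectra_distinct_vectors(self):
        rng = np.random.default_rng(0)
        stack = simple_squeak(seed=0)
        rms = np.sqrt(np.mean(stack.samples**2))
        noise = Vocalization("n", rng.standard_normal(len(stack.samples)) * rms, SR)
        assert np.linalg.norm(compute_mfcc(stack) - compute_mfcc(noise)) > 0

    def test_silent_input_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            compute_mfcc(Vocalization("s", np.zeros(4800), SR))


class TestChroma:
    def test_a440_maps_to_pitch_class_a(self):
        assert np.argmax(compute_chroma(tone(440))) == 0

    def test_octave_equivalence(self):
        assert np.argmax(compute_chroma(tone(880))) == np.argmax(
            compute_chroma(tone(440))
        )

    def test_chromatic_cluster_near_uniform(self):
        # 12 equal-amplitude semitones spanning one octave in the call
        # band (where the 2048-sample STFT resolves semitones); the
        # profile should be near-uniform
        t = np.arange(int(0.3 * SR)) / SR
        freqs = [3520 * 2 ** (k / 12) for k in range(12)]
        sig = 0.2 * sum(
            np.sin(2 * np.pi * f * t + 0.7 * k) for k, f in enumerate(freqs)
        )
        c = compute_chroma(Vocalization("c", sig, SR))
        assert (c.max() - c.min()) / c.max() < 0.2

    def test_values_in_unit_interval(self):
        c = compute_chroma(simple_squeak(seed=1))
        assert np.all(c >= 0) and np.all(c <= 1)


class TestSpectralStats:
    def test_pure_tone_concentrated_spectrum(self):
        # tone placed on an exact STFT bin centre
        f = 171 * SR / 2048  # ~4008 Hz
        c, flat, _, _, _, ent = compute_spectral_stats(tone(f))
        assert abs(c - f) <= SR / 2048
        assert flat < 0.05
        assert ent < 1.2  # Hann-window leakage bounds tone entropy near 0.9 nats

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(0)
        v = Vocalization("n", 0.5 * rng.standard_normal(int(0.3 * SR)), SR)
        stats = compute_spectral_stats(v)
        assert stats[1] > 0.5  # flatness
        assert stats[5] > 4.0  # entropy far above any tonal call

    def test_stationary_signal_zero_flux(self):
        v = Vocalization("c", np.full(int(0.3 * SR), 0.5), SR)
        assert compute_spectral_stats(v)[2] == pytest.approx(0.0, abs=1e-9)


class TestPitchTrack:
    def test_constant_stack_recovered_within_one_percent(self):
        v = simple_squeak(f0=3000.0, snr=np.inf, ambient=-np.inf)
        track = estimate_pitch_track(v)
        assert np.median(track.f0_hz[track.voiced]) == pytest.approx(3000.0, rel=0.01)

    def test_out_of_band_tone_unvoiced(self):
        track = estimate_pitch_track(tone(500))
        assert not track.voiced.any()

    def test_squeal_less_voiced_than_squeak(self):
        squeal = estimate_pitch_track(simple_squeal(seed=5))
        squeak = estimate_pitch_track(simple_squeak(snr=10.0, seed=5))
        assert squeal.voicing_prob.mean() < squeak.voicing_prob.mean()

    def test_median_error_below_two_percent_at_snr10(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            f0 = float(rng.uniform(2500, 4000))
            v = simple_squeak(
                f0=f0, n_harmonics=int(rng.integers(3, 13)), snr=10.0, seed=seed
            )
            track = estimate_pitch_track(v)
            got = np.median(track.f0_hz[track.voiced])
            errs.append(abs(got - f0) / f0)
        assert np.median(errs) < 0.02

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            estimate_pitch_track(simple_squeak(), fmin=8000, fmax=1000)


class TestSummarizePitch:
    def test_max_voicing_frame_defines_estimate(self):
        track = features.PitchTrack(
            times=np.array([0.0, 0.1, 0.2]),
            f0_hz=np.array([3000.0, 3200.0, 3100.0]),
            voicing_prob=np.array([0.5, 0.9, 0.7]),
        )
        v = Vocalization("x", np.ones(4800) * 0.1, SR)
        f0_mean, f0_max, f0_min, mod, dur = summarize_pitch(track, v)
        assert (f0_mean, f0_max, f0_min, mod) == (3200.0, 3200.0, 3000.0, 200.0)
        assert dur == pytest.approx(0.1)

    def test_constant_track_zero_modulation(self):
        track = features.PitchTrack(
            times=np.array([0.0, 0.1]),
            f0_hz=np.array([3000.0, 3000.0]),
            voicing_prob=np.array([0.9, 0.9]),
        )
        v = Vocalization("x", np.ones(4800) * 0.1, SR)
        assert summarize_pitch(track, v)[3] == 0.0

    def test_fully_unvoiced_band_floor_sentinel(self):
        track = features.PitchTrack(
            times=np.array([0.0]),
            f0_hz=np.array([np.nan]),
            voicing_prob=np.array([0.0]),
        )
        v = Vocalization("x", np.ones(4800) * 0.1, SR)
        f0_mean, f0_max, f0_min, mod, _ = summarize_pitch(track, v, fmin=1000.0)
        assert f0_mean == f0_max == f0_min == 1000.0
        assert mod == 0.0


class TestPeakAndHarmonics:
    def test_tone_peak_within_one_bin(self):
        v = tone(4000.0)
        assert abs(peak_frequency(v) - 4000.0) <= SR / len(v.samples)

    def test_dominant_harmonic_by_construction(self):
        v = simple_squeak(
            f0=3000.0, n_harmonics=3, amps=[0.2, 1.0, 0.5],
            snr=np.inf, ambient=-np.inf, formant_gain_db=0.0, tilt_db_per_khz=0.0,
            formant_bw_hz=2500.0,
        )
        assert abs(peak_frequency(v) - 6000.0) <= SR / len(v.samples)
        prof = detect_harmonics(v, 3000.0)
        assert prof.n_harmonics == 3
        assert prof.dominant_harmonic == 2

    def test_single_tone_one_harmonic(self):
        v = tone(5000.0)
        prof = detect_harmonics(v, 5000.0)
        assert prof.n_harmonics == 1
        assert prof.dominant_harmonic == 1

    def test_off_multiple_peak_not_counted(self):
        t = np.arange(int(0.3 * SR)) / SR
        sig = 0.5 * np.sin(2 * np.pi * 3000 * t) + 0.5 * np.sin(2 * np.pi * 7400 * t)
        prof = detect_harmonics(Vocalization("x", sig, SR), 3000.0)
        assert prof.n_harmonics == 1  # 7400 = 2.47 f0, outside +-50 Hz of 6000

    def test_equal_magnitude_tie_goes_to_lowest_index(self):
        freqs = np.linspace(0, 24000, 4801)
        mag = np.full_like(freqs, 1e-6)
        for f in (3000.0, 6000.0):  # identical triangular peaks
            k = int(round(f / 5))
            mag[k - 1 : k + 2] += [0.5, 1.0, 0.5]
        prof = detect_harmonics_spectrum(freqs, mag, 3000.0)
        assert prof.n_harmonics == 2
        assert prof.dominant_harmonic == 1

    def test_f0_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            detect_harmonics(tone(4000), 30000.0)


def brute_force_harmonics(freqs, mag, f0, tol=50.0, thr_db=-40.0):
    """Independent oracle: explicit scan of every k and every smoothed-
    spectrum local maximum."""
    sm = np.convolve(mag, np.ones(3) / 3.0, mode="same")
    peaks = [
        i for i in range(1, len(sm) - 1) if sm[i] > sm[i - 1] and sm[i] > sm[i + 1]
    ]
    if not peaks:
        return 0, 0
    floor = max(sm[i] for i in peaks) * 10 ** (thr_db / 20)
    counted = {}
    k = 1
    while k * f0 < freqs[-1]:
        best = None
        for i in peaks:
            if abs(freqs[i] - k * f0) <= tol and sm[i] >= floor:
                if best is None or sm[i] > sm[best]:
                    best = i
        if best is not None:
            counted[k] = sm[best]
        k += 1
    if not counted:
        return 0, 0
    best_mag = max(counted.values())
    dominant = min(kk for kk, m in counted.items() if m == best_mag)  # tie -> lowest k
    return len(counted), dominant


def random_spectrum(rng):
    freqs = np.linspace(0, 24000, 2401)
    mag = rng.uniform(0, 1e-4, len(freqs))
    f0 = float(rng.uniform(1200, 5000))
    def add_peak(idx, amp):
        mag[idx - 1 : idx + 2] += np.array([0.5, 1.0, 0.5]) * amp

    for k in range(1, int(rng.integers(1, 12)) + 1):
        f = k * f0 + rng.uniform(-60, 60)
        if f >= freqs[-1] - 30:
            break
        add_peak(int(round(f / 10)), rng.uniform(0.001, 1.0))
    for _ in range(int(rng.integers(0, 5))):  # spurious peaks
        add_peak(int(rng.integers(50, len(freqs) - 50)), rng.uniform(0.001, 1.0))
    return freqs, mag, f0


def test_harmonic_counter_matches_brute_force_oracle():
    rng = np.random.default_rng(123)
    for _ in range(200):
        freqs, mag, f0 = random_spectrum(rng)
        prof = detect_harmonics_spectrum(freqs, mag, f0)
        n_ref, dom_ref = brute_force_harmonics(freqs, mag, f0)
        assert (prof.n_harmonics, prof.dominant_harmonic) == (n_ref, dom_ref)


class TestAssembleAndStandardize:
    def test_set_lengths_and_prefix_consistency(self):
        v = simple_squeak(seed=6)
        s1 = assemble_features(v, "SET1")
        s2 = assemble_features(v, "SET2")
        assert len(s1.values) == 30 and s1.names == tuple(SET1_NAMES)
        assert len(s2.values) == 38 and s2.names == tuple(SET2_NAMES)
        assert np.array_equal(s2.values[:30], s1.values)

    def test_error_carries_call_id(self):
        silent = Vocalization("v", np.zeros(4800), SR, call_id="bad_call")
        with pytest.raises(ValueError, match="bad_call"):
            assemble_features(silent, "SET1")

    def test_batch_table_complete(self, tiny_cohort_table):
        assert not tiny_cohort_table.isna().any().any()
        assert set(SET2_NAMES).issubset(tiny_cohort_table.columns)

    def test_standardize_train_statistics(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame(rng.normal(3, 2, size=(50, 4)), columns=list("abcd"))
        out_train, out_apply = standardize(train, train)
        assert np.allclose(out_train.mean(), 0, atol=1e-9)
        assert np.allclose(out_train.var(ddof=0), 1, atol=1e-6)
        assert out_apply.equals(out_train)

    def test_standardize_constant_column_zeroed(self):
        train = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        out, _ = standardize(train, train)
        assert np.allclose(out["a"], 0.0)

    def test_standardize_row_at_mean_maps_to_zero(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        probe = pd.DataFrame([train.mean()], columns=train.columns)
        _, out = standardize(train, probe)
        assert np.allclose(out.iloc[0], 0.0, atol=1e-12)

    def test_standardize_column_mismatch_rejected(self):
        a = pd.DataFrame({"x": [1.0, 2.0]})
        b = pd.DataFrame({"y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            standardize(a, b)
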