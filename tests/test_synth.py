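"""Generator contracts: cohort marginals, determinism, waveform structure."""

import numpy as np
import pytest

from manavoc import features, synth

from conftest import simple_squeak, simple_squeal


class TestGenerateCohort:
    def test_requested_marginals_reference_shape(self):
        cat = synth.generate_cohort(20, 0.75, 0.25, seed=42)
        sexes = [s.sex for s in cat.subjects]
        ages = [s.age_class for s in cat.subjects]
        assert sexes.count("female") == 15 and sexes.count("male") == 5
        assert ages.count("juvenile") == 5

    def test_exact_proportions_small_cohort(self):
        cat = synth.generate_cohort(4, 0.5, 0.5, seed=1)
        sexes = [s.sex for s in cat.subjects]
        ages = [s.age_class for s in cat.subjects]
        assert sexes.count("female") == 2 and sexes.count("male") == 2
        assert ages.count("juvenile") == 2

    def test_same_seed_identical_catalogs(self):
        a = synth.generate_cohort(8, 0.5, 0.25, seed=7)
        b = synth.generate_cohort(8, 0.5, 0.25, seed=7)
        assert a == b

    def test_age_conditional_sizes_and_call_counts(self):
        cat = synth.generate_cohort(30, 0.5, 0.4, seed=3)
        for s in cat.subjects:
            lo, hi = (1.70, 2.20) if s.age_class == "juvenile" else (2.20, 3.00)
            assert lo <= s.body_size_m <= hi
            assert 31 <= s.n_calls <= 88

    def test_atypical_fraction(self):
        cat = synth.generate_cohort(20, 0.5, 0.25, seed=5, atypical_fraction=0.10)
        assert sum(s.idiosyncrasy.atypical for s in cat.subjects) == 2

    @pytest.mark.parametrize(
        "kwargs", [dict(n_subjects=2), dict(female_fraction=1.5), dict(juvenile_fraction=-0.1)]
    )
    def test_invalid_arguments_raise(self, kwargs):
        args = dict(n_subjects=8, female_fraction=0.5, juvenile_fraction=0.25, seed=0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            synth.generate_cohort(**args)


class TestReferenceCohort:
    def test_structure_matches_capture_catalog(self):
        cat = synth.reference_cohort()
        assert cat.n_subjects == 20
        assert cat.total_calls == 1285
        sexes = [s.sex for s in cat.subjects]
        assert sexes.count("female") == 15
        juv = [s for s in cat.subjects if s.age_class == "juvenile"]
        assert len(juv) == 5
        assert min(s.body_size_m for s in juv) == pytest.approx(1.70)

    def test_squeal_reduced_complement(self):
        cat = synth.reference_cohort()
        squealers = [s for s in cat.subjects if s.squeal_fraction > 0.3]
        assert {s.subject_id for s in squealers} == {"S07", "S18", "S23", "S27"}
        kept = [s for s in cat.subjects if s.squeal_fraction <= 0.3]
        assert len(kept) == 16
        assert sum(s.n_calls for s in kept) == 1018


class TestSynthesizeCall:
    def test_harmonic_stack_spectrum_has_planted_peaks(self):
        v = simple_squeak(
            f0=3000.0, n_harmonics=3, amps=[1.0, 1.0, 1.0],
            snr=np.inf, ambient=-np.inf, formant_gain_db=0.0, tilt_db_per_khz=0.0,
        )
        freqs = np.fft.rfftfreq(len(v.samples), 1 / v.sample_rate_hz)
        mag = np.abs(np.fft.rfft(v.samples * np.hanning(len(v.samples))))
        bin_hz = freqs[1]
        floor = mag.max() * 10 ** (-40 / 20)
        peak_bins = freqs[
            np.flatnonzero((mag[1:-1] > mag[:-2]) & (mag[1:-1] > mag[2:]) & (mag[1:-1] > floor)) + 1
        ]
        assert len(peak_bins) == 3
        for expect, got in zip((3000, 6000, 9000), sorted(peak_bins)):
            assert abs(got - expect) <= bin_hz

    def test_squeal_flatter_than_squeak(self):
        squeal = simple_squeal(snr=-5.0, seed=4)
        squeak = simple_squeak(seed=4)
        flat_squeal = features.compute_spectral_stats(squeal)[1]
        flat_squeak = features.compute_spectral_stats(squeak)[1]
        assert flat_squeal > flat_squeak

    def test_f0_ramp_modulation_recovered(self):
        # long enough that frame-edge gating trims little of the ramp
        v = simple_squeak(f0=[3000.0, 3200.0], duration=0.8, snr=25.0)
        track = features.estimate_pitch_track(v)
        _, _, _, mod, _ = features.summarize_pitch(track, v)
        assert 160.0 <= mod <= 240.0  # generator contour range 200 Hz +- tracker error

    def test_peak_amplitude_normalized(self):
        v = simple_squeak()
        assert np.max(np.abs(v.samples)) == pytest.approx(0.9, rel=1e-6)

    def test_nyquist_harmonics_dropped_and_counted(self):
        v = simple_squeak(f0=5000.0, n_harmonics=10, sr=48000)
        assert v.meta["n_harmonics_dropped"] == 6  # k>=5 exceeds 0.98*24 kHz

    def test_determinism(self):
        a = simple_squeak(seed=11)
        b = simple_squeak(seed=11)
        assert np.array_equal(a.samples, b.samples)


class TestGenerateDataset:
    def test_reference_catalog_call_count(self):
        # structural check only: metadata honours the catalog's 1,285 calls
        cat = synth.reference_cohort()
        rows = sum(s.n_calls for s in cat.subjects)
        assert rows == 1285

    def test_metadata_rows_and_determinism(self):
        cat = synth.generate_cohort(4, 0.5, 0.5, seed=2, n_calls_range=(5, 8))
        v1, m1 = synth.generate_dataset(cat, seed=2)
        v2, m2 = synth.generate_dataset(cat, seed=2)
        assert len(v1) == cat.total_calls == len(m1)
        assert m1.equals(m2)
        assert all(np.array_equal(a.samples, b.samples) for a, b in zip(v1, v2))
        assert set(m1.columns) == {
            "call_id", "subject_id", "sex", "age_class", "size_m", "call_type"
        }

    def test_per_subject_call_counts_honoured(self):
        cat = synth.generate_cohort(5, 0.6, 0.4, seed=8, n_calls_range=(5, 15))
        _, meta = synth.generate_dataset(cat, seed=8)
        counts = meta.groupby("subject_id").size()
        for s in cat.subjects:
            assert counts[s.subject_id] == s.n_calls

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_dataset(synth.CohortCatalog(subjects=(), seed=0), seed=0)

    def test_squeal_fraction_realized(self):
        cat = synth.reference_cohort(n_calls_override=20)
        _, meta = synth.generate_dataset(cat, seed=6)
        frac = (meta["call_type"] == "squeal").groupby(meta["subject_id"]).mean()
        assert frac["S18"] == pytest.approx(0.82, abs=0.05)
        assert frac["S03"] == 0.0
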