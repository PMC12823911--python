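"""Shared fixtures: small synthetic cohorts rendered once per session.

The default cohort mirrors the 20-subject reference catalog with reduced
per-subject call counts (15) and the generator's default effect sizes;
building it costs a few seconds, so feature tables are session-scoped.
"""

import numpy as np
import pytest

from manavoc import features, preprocess, synth

#: a deliberately strong sex-envelope effect with no age effect, used for
#: parameter-recovery checks
STRONG_SEX_EFFECT = {
    "sex_formant_shift_hz": 500.0,
    "sex_tilt_db_per_khz": 4.0,
    "age_f0_offset_hz": 0.0,
}

#: every demographic coupling zeroed: features carry only individual
#: idiosyncrasy and noise, so any demographic classifier must be at chance
NULL_EFFECT = {
    "sex_formant_shift_hz": 0.0,
    "sex_tilt_db_per_khz": 0.0,
    "age_f0_offset_hz": 0.0,
    "size_formant_hz_per_m": 0.0,
    "size_tilt_db_per_khz_per_m": 0.0,
    "size_bw_hz_per_m": 0.0,
    "size_gain_db_per_m": 0.0,
}


def build_feature_table(
    seed=1,
    atypical_ids=("S14",),
    effects=None,
    n_calls=15,
    set_id="SET2",
    catalog=None,
):
    """Render a cohort, preprocess, and extract one feature table."""
    cat = catalog or synth.reference_cohort(
        seed=seed, atypical_ids=atypical_ids, n_calls_override=n_calls
    )
    vocs, meta = synth.generate_dataset(cat, effect_config=effects, seed=seed)
    processed = [preprocess.highpass(v) for v in vocs]
    return features.extract_table(processed, meta, set_id)


def simple_squeak(
    f0=3000.0,
    duration=0.3,
    n_harmonics=5,
    amps=None,
    snr=20.0,
    ambient=-25.0,
    sr=48000,
    seed=0,
    **env,
):
    """One controlled squeak with sensible envelope defaults."""
    env.setdefault("formant_center_hz", 4500.0)
    env.setdefault("formant_bw_hz", 900.0)
    env.setdefault("formant_gain_db", 10.0)
    env.setdefault("tilt_db_per_khz", -2.0)
    contour = np.atleast_1d(np.asarray(f0, dtype=float))
    spec = synth.CallSpec(
        f0_contour=contour,
        duration_s=duration,
        n_harmonics_true=n_harmonics,
        harmonic_amplitudes=(
            np.asarray(amps, float) if amps is not None
            else np.arange(1, n_harmonics + 1, dtype=float) ** -0.8
        ),
        call_type="squeak",
        noise_snr_db=snr,
        ambient_db=ambient,
        **env,
    )
    return synth.synthesize_call(spec, sr, seed)


def simple_squeal(snr=-5.0, duration=0.3, sr=48000, seed=0):
    spec = synth.CallSpec(
        f0_contour=np.array([3000.0]),
        duration_s=duration,
        n_harmonics_true=1,
        harmonic_amplitudes=np.array([1.0]),
        call_type="squeal",
        formant_center_hz=4500.0,
        formant_bw_hz=900.0,
        formant_gain_db=10.0,
        tilt_db_per_khz=-2.0,
        noise_snr_db=snr,
        ambient_db=-25.0,
    )
    return synth.synthesize_call(spec, sr, seed)


@pytest.fixture(scope="session")
def default_table():
    """SET2 feature table for the default reference-shaped cohort."""
    return build_feature_table(seed=1)


@pytest.fixture(scope="session")
def tiny_cohort_table():
    """A 6-subject cohort for cheap pipeline-structure tests."""
    cat = synth.generate_cohort(
        6, 0.5, 0.5, seed=9, atypical_fraction=0.0, n_calls_range=(8, 12)
    )
    return build_feature_table(seed=9, catalog=cat)
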