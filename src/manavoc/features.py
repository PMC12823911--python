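"""Acoustic descriptors per call.

Two feature sets are assembled per vocalization:

* SET1 (30 values): 12 MFCCs (coefficients 1-12, the 0th/gain coefficient
  omitted), 12 chroma pitch-class energies, and six spectral shape
  statistics (centroid, flatness, flux, skewness, kurtosis, entropy), all
  computed frame-wise and averaged over the call.
* SET2 (38 values): SET1 plus eight temporal-frequency and harmonic
  descriptors — call duration, f0 at the maximum-voicing frame, f0
  max/min, peak frequency, frequency modulation (f0 range), number of
  harmonics, and the index of the dominant harmonic.

Framing defaults: 2048-sample Hann window, 512 hop for MFCC/statistics,
1536 hop for chroma; 128 mel bands spanning 0 to Nyquist.  The pitch
tracker is a YIN-family estimator (cumulative-mean-normalized difference
function with parabolic lag refinement and a spectral-peak touch-up) that
reports a per-frame voicing probability; frames may be unvoiced.

Fully unvoiced calls — expected for broadband squeals — get pitch
summaries pinned to the tracking-band floor (``fmin``) with a single
counted harmonic and a flag in the profile, mimicking the pitch-floor
artifact a tracker shows on residual noise near the high-pass cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft, rfftfreq

from .synth import Vocalization

__all__ = [
    "FrameSpec",
    "PitchTrack",
    "HarmonicProfile",
    "FeatureVector",
    "SET1_NAMES",
    "SET2_NAMES",
    "compute_mfcc",
    "compute_chroma",
    "compute_spectral_stats",
    "estimate_pitch_track",
    "summarize_pitch",
    "peak_frequency",
    "detect_harmonics",
    "detect_harmonics_spectrum",
    "assemble_features",
    "extract_table",
    "standardize",
]

log = logging.getLogger(__name__)

_SILENCE_RMS = 1e-8

SET1_NAMES = (
    [f"mfcc_{i}" for i in range(1, 13)]
    + [f"chroma_{i}" for i in range(1, 13)]
    + [
        "spectral_centroid",
        "spectral_flatness",
        "spectral_flux",
        "spectral_skewness",
        "spectral_kurtosis",
        "spectral_entropy",
    ]
)
SET2_NAMES = SET1_NAMES + [
    "duration_s",
    "f0_mean",
    "f0_max",
    "f0_min",
    "peak_freq_hz",
    "freq_modulation_hz",
    "n_harmonics",
    "dominant_harmonic",
]


@dataclass(frozen=True)
class FrameSpec:
    fft_size: int = 2048
    hop: int = 512
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.hop > self.fft_size:
            raise ValueError("hop must not exceed fft_size")
        if self.window != "hann":
            raise ValueError("only hann windows are supported")


CHROMA_FRAMES = FrameSpec(fft_size=2048, hop=1536)


@dataclass(frozen=True)
class PitchTrack:
    times: np.ndarray
    f0_hz: np.ndarray  # NaN where unvoiced
    voicing_prob: np.ndarray

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0_hz)


@dataclass(frozen=True)
class HarmonicProfile:
    n_harmonics: int
    dominant_harmonic: int
    peak_freqs_hz: tuple[float, ...]
    unvoiced_fallback: bool = False


@dataclass(frozen=True)
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def _check_not_silent(v: Vocalization) -> None:
    if float(np.sqrt(np.mean(v.samples**2))) <= _SILENCE_RMS:
        raise ValueError(f"silent call {v.call_id or '<unnamed>'}")


def _frames(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    """(n_frames, n_fft) frame matrix; short signals are zero-padded."""
    x = np.asarray(x, dtype=float)
    if len(x) < n_fft:
        x = np.pad(x, (0, n_fft - len(x)))
    n_frames = 1 + (len(x) - n_fft) // hop
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _stft_mag(x: np.ndarray, frames: FrameSpec) -> np.ndarray:
    """Magnitude spectrogram, shape (n_frames, n_fft//2 + 1)."""
    fm = _frames(x, frames.fft_size, frames.hop)
    win = np.hanning(frames.fft_size)
    return np.abs(rfft(fm * win, axis=1))


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(sr: int, n_fft: int, n_mels: int) -> np.ndarray:
    """Triangular mel filterbank over 0..Nyquist, shape (n_mels, n_bins)."""
    freqs = rfftfreq(n_fft, 1.0 / sr)
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(sr / 2.0), n_mels + 2))
    fb = np.zeros((n_mels, len(freqs)))
    for m in range(n_mels):
        lo, ctr, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def compute_mfcc(
    v: Vocalization, frames: FrameSpec = FrameSpec(), n_mels: int = 128
) -> np.ndarray:
    """Mean MFCC vector (coefficients 1..12) over all frames.

    Log mel energies are DCT-II (orthonormal) transformed per frame and the
    0th coefficient dropped, which makes the result invariant to global
    gain: a scalar volume change adds a constant to every log-mel energy,
    and a constant projects only onto the omitted basis function.
    """
    _check_not_silent(v)
    S = _stft_mag(v.samples, frames) ** 2
    fb = _mel_filterbank(v.sample_rate_hz, frames.fft_size, n_mels)
    mel_e = S @ fb.T
    log_e = np.log(np.maximum(mel_e, 1e-30))
    cc = dct(log_e, type=2, norm="ortho", axis=1)
    return cc[:, 1:13].mean(axis=0)


def compute_chroma(v: Vocalization, frames: FrameSpec = CHROMA_FRAMES) -> np.ndarray:
    """12 pitch-class energies (A440 reference), frame-averaged.

    Each STFT bin's energy is folded onto the pitch class of its nearest
    equal-tempered semitone; profiles are max-normalized per frame (values
    in [0, 1]) before averaging, so loud and quiet frames weigh equally.
    Index 0 is pitch class A.
    """
    _check_not_silent(v)
    S = _stft_mag(v.samples, frames) ** 2
    freqs = rfftfreq(frames.fft_size, 1.0 / v.sample_rate_hz)
    cls = np.full(len(freqs), -1)
    pos = freqs > 0
    cls[pos] = np.mod(np.round(12.0 * np.log2(freqs[pos] / 440.0)).astype(int), 12)
    prof = np.zeros((S.shape[0], 12))
    for c in range(12):
        sel = cls == c
        if sel.any():
            prof[:, c] = S[:, sel].sum(axis=1)
    mx = prof.max(axis=1, keepdims=True)
    prof = np.where(mx > 0, prof / np.maximum(mx, 1e-30), 0.0)
    return prof.mean(axis=0)


def compute_spectral_stats(
    v: Vocalization, frames: FrameSpec = FrameSpec()
) -> np.ndarray:
    """Six spectral shape statistics, frame-averaged.

    centroid (Hz) and skewness/kurtosis treat the normalized magnitude
    spectrum as a distribution over frequency (kurtosis is the raw 4th
    standardized moment, not excess); flatness is the geometric/arithmetic
    mean ratio of the power spectrum; flux is the L2 norm of successive
    magnitude-spectrum differences (0 for a single frame); entropy is the
    Shannon entropy, in nats, of the normalized power spectrum.
    """
    _check_not_silent(v)
    S = _stft_mag(v.samples, frames)
    P = S**2
    freqs = rfftfreq(frames.fft_size, 1.0 / v.sample_rate_hz)

    msum = S.sum(axis=1, keepdims=True)
    pmag = S / np.maximum(msum, 1e-30)
    centroid = (pmag * freqs).sum(axis=1)
    mu = centroid
    var = (pmag * (freqs[None, :] - mu[:, None]) ** 2).sum(axis=1)
    sd = np.sqrt(np.maximum(var, 1e-30))
    skew = (pmag * (freqs[None, :] - mu[:, None]) ** 3).sum(axis=1) / sd**3
    kurt = (pmag * (freqs[None, :] - mu[:, None]) ** 4).sum(axis=1) / sd**4

    tiny = 1e-12
    flat = np.exp(np.mean(np.log(P + tiny), axis=1)) / (np.mean(P, axis=1) + tiny)

    if S.shape[0] > 1:
        flux = np.sqrt(((np.diff(S, axis=0)) ** 2).sum(axis=1))
        flux_mean = float(flux.mean())
    else:
        flux_mean = 0.0

    ppow = P / np.maximum(P.sum(axis=1, keepdims=True), 1e-30)
    ent = -(ppow * np.log(np.maximum(ppow, 1e-30))).sum(axis=1)

    return np.array(
        [
            float(centroid.mean()),
            float(flat.mean()),
            flux_mean,
            float(skew.mean()),
            float(kurt.mean()),
            float(ent.mean()),
        ]
    )


def _yin_frame(x: np.ndarray, tau_min: int, tau_max: int) -> tuple[float, float]:
    """One YIN step: returns (refined lag, cmndf value at the minimum)."""
    w = len(x) - tau_max
    if w < tau_max:
        raise ValueError("frame too short for the requested f0 band")
    # difference function d(tau) over tau = 0..tau_max via correlation
    taus = np.arange(tau_max + 1)
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))
    p0 = csum2[w]
    p_tau = csum2[taus + w] - csum2[taus]
    # cross terms c(tau) = sum_{j<w} x_j x_{j+tau} by FFT correlation
    nfft = int(2 ** np.ceil(np.log2(len(x) + tau_max + 1)))
    A = np.fft.rfft(x[:w], nfft)
    B = np.fft.rfft(x, nfft)
    G = np.conj(A) * B
    xcorr = np.fft.irfft(G, nfft)[: tau_max + 1]
    d = np.maximum(p0 + p_tau - 2.0 * xcorr, 0.0)
    d[0] = 0.0
    # cumulative-mean normalization
    cm = np.cumsum(d[1:]) / np.arange(1, tau_max + 1)
    cmndf = np.ones_like(d)
    cmndf[1:] = d[1:] / np.maximum(cm, 1e-30)

    # Candidate dips are local minima of the cmndf in band.  Every period
    # multiple dips for periodic input, and integer-lag quantization can
    # make a multiple's dip look deeper than the true period's (the dip
    # narrows as harmonic count grows), so each candidate's lag is refined
    # parabolically and its depth re-evaluated at the FRACTIONAL lag —
    # exact band-limited evaluation via phase shift of the correlation
    # spectrum — before depths are compared.  The smallest comparably-deep
    # lag wins; a plain global argmin causes octave-down errors.
    def d_frac(tf: float) -> float:
        k = np.arange(len(G))
        rot = np.exp(2j * np.pi * k * tf / nfft)
        c = (G[0].real + 2.0 * np.sum((G[1:-1] * rot[1:-1]).real) + (G[-1] * rot[-1]).real) / nfft
        pt = float(np.interp(tf, taus, p_tau))
        return max(p0 + pt - 2.0 * c, 0.0)

    cands: list[tuple[float, float]] = []  # (refined lag, refined cmndf)
    for t in range(tau_min, tau_max + 1):
        a, b, c = cmndf[t - 1], cmndf[t], cmndf[min(t + 1, tau_max)]
        if not (b <= a and b <= c):
            continue
        denom = a - 2 * b + c
        delta = 0.0
        if abs(denom) > 1e-30:
            delta = float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
        tf = t + delta
        cm_f = float(np.interp(tf, np.arange(1, tau_max + 1), cm))
        cands.append((tf, d_frac(tf) / max(cm_f, 1e-30)))
    if not cands:
        band = np.arange(tau_min, tau_max + 1)
        t = int(band[np.argmin(cmndf[band])])
        return float(t), float(cmndf[t])
    best_val = min(v for _, v in cands)
    accept = max(0.1, best_val * 1.3, best_val + 0.02)
    tau, val = min((c for c in cands if c[1] <= accept), key=lambda c: c[0])
    return float(tau), float(val)


def estimate_pitch_track(
    v: Vocalization,
    fmin: float = 1000.0,
    fmax: float = 8000.0,
    frames: FrameSpec = FrameSpec(),
    unvoiced_threshold: float = 0.7,
    energy_gate: float = 0.1,
) -> PitchTrack:
    """Per-frame f0 candidates with voicing probabilities (YIN family).

    The cumulative-mean-normalized difference function is minimized within
    the lag band [sr/fmax, sr/fmin]; the lag is refined parabolically and
    then snapped to the nearest spectral peak (quadratic interpolation on
    the log-magnitude spectrum) for sub-bin accuracy.  Voicing probability
    is ``1 - cmndf`` at the chosen lag, clipped to [0, 1]; frames whose
    cmndf exceeds ``unvoiced_threshold`` are marked unvoiced (NaN), as are
    low-energy frames (RMS below ``energy_gate`` of the loudest frame)
    where only ambient noise remains under the amplitude envelope.
    """
    sr = v.sample_rate_hz
    if not (0 < fmin < fmax < sr / 2):
        raise ValueError("need 0 < fmin < fmax < Nyquist")
    _check_not_silent(v)
    tau_min = max(2, int(np.floor(sr / fmax)))
    tau_max = int(np.ceil(sr / fmin))

    fm = _frames(v.samples, frames.fft_size, frames.hop)
    win = np.hanning(frames.fft_size)
    bin_hz = sr / frames.fft_size

    times = (np.arange(fm.shape[0]) * frames.hop + frames.fft_size / 2) / sr
    f0 = np.full(fm.shape[0], np.nan)
    prob = np.zeros(fm.shape[0])
    frame_rms = np.sqrt((fm**2).mean(axis=1))
    rms_gate = max(energy_gate * float(frame_rms.max()), _SILENCE_RMS)
    for i, frame in enumerate(fm):
        if frame_rms[i] < rms_gate:
            continue
        frame = frame - frame.mean()
        tau, val = _yin_frame(frame, tau_min, tau_max)
        prob[i] = float(np.clip(1.0 - val, 0.0, 1.0))
        if val > unvoiced_threshold:
            continue
        cand = sr / tau
        # spectral touch-up: quadratic peak interpolation near the candidate
        mag = np.abs(rfft(frame * win))
        lo = max(1, int(np.floor((cand * 0.94) / bin_hz)))
        hi = min(len(mag) - 2, int(np.ceil((cand * 1.06) / bin_hz)))
        if hi > lo:
            k = lo + int(np.argmax(mag[lo : hi + 1]))
            if 0 < k < len(mag) - 1 and mag[k] > 0:
                la, lb, lc = np.log(np.maximum(mag[k - 1 : k + 2], 1e-30))
                denom = la - 2 * lb + lc
                delta = 0.5 * (la - lc) / denom if abs(denom) > 1e-30 else 0.0
                cand_spec = (k + float(np.clip(delta, -0.5, 0.5))) * bin_hz
                if abs(cand_spec - cand) / cand < 0.06:
                    cand = cand_spec
        if fmin <= cand <= fmax:
            f0[i] = cand
    return PitchTrack(times=times, f0_hz=f0, voicing_prob=prob)


def summarize_pitch(
    track: PitchTrack, v: Vocalization, fmin: float = 1000.0
) -> tuple[float, float, float, float, float]:
    """(f0_mean, f0_max, f0_min, freq_modulation_hz, duration_s).

    ``f0_mean`` is the f0 at the frame of maximum voicing probability (the
    single best pitch estimate for the call); max/min range over all voiced
    frames; modulation is their difference.  A fully unvoiced call returns
    the band-floor sentinel (``fmin``) for all pitch slots with zero
    modulation — the pitch-floor artifact of trackers fed broadband noise.
    """
    duration = v.duration_s
    voiced = track.voiced
    if not voiced.any():
        log.info("fully unvoiced call %s: pitch summaries pinned to band floor", v.call_id)
        return float(fmin), float(fmin), float(fmin), 0.0, duration
    f0v = track.f0_hz[voiced]
    pv = track.voicing_prob[voiced]
    f0_best = float(f0v[np.argmax(pv)])
    f0_max = float(f0v.max())
    f0_min = float(f0v.min())
    return f0_best, f0_max, f0_min, f0_max - f0_min, duration


def _call_spectrum(v: Vocalization) -> tuple[np.ndarray, np.ndarray]:
    win = np.hanning(len(v.samples))
    mag = np.abs(rfft(v.samples * win))
    freqs = rfftfreq(len(v.samples), 1.0 / v.sample_rate_hz)
    return freqs, mag


def peak_frequency(v: Vocalization) -> float:
    """Frequency (Hz) of the maximum of the full-call magnitude spectrum."""
    _check_not_silent(v)
    freqs, mag = _call_spectrum(v)
    return float(freqs[int(np.argmax(mag))])


def _smooth3(mag: np.ndarray) -> np.ndarray:
    kernel = np.ones(3) / 3.0
    return np.convolve(mag, kernel, mode="same")


def detect_harmonics_spectrum(
    freqs: np.ndarray,
    mag: np.ndarray,
    f0: float,
    tolerance_hz: float = 50.0,
    threshold_db: float = -40.0,
) -> HarmonicProfile:
    """Count harmonics of ``f0`` in a magnitude spectrum.

    The spectrum is smoothed by a 3-bin moving average; strict local
    maxima above ``threshold_db`` relative to the tallest peak qualify.
    Harmonic k (k·f0 below Nyquist) is counted when a qualifying peak lies
    within ±``tolerance_hz`` of k·f0; the dominant harmonic is the counted
    k with the greatest peak magnitude (ties go to the lowest k).
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    nyquist = float(freqs[-1])
    if f0 >= nyquist:
        raise ValueError("f0 must be below Nyquist")
    sm = _smooth3(np.asarray(mag, dtype=float))
    is_peak = np.zeros(len(sm), dtype=bool)
    is_peak[1:-1] = (sm[1:-1] > sm[:-2]) & (sm[1:-1] > sm[2:])
    peak_idx = np.flatnonzero(is_peak)
    if len(peak_idx) == 0:
        return HarmonicProfile(0, 0, ())
    floor = sm[peak_idx].max() * 10.0 ** (threshold_db / 20.0)
    peak_idx = peak_idx[sm[peak_idx] >= floor]
    pk_freqs = freqs[peak_idx]
    pk_mags = sm[peak_idx]

    counted: list[tuple[int, float, float]] = []  # (k, freq, mag)
    k = 1
    while k * f0 < nyquist:
        target = k * f0
        sel = np.abs(pk_freqs - target) <= tolerance_hz
        if sel.any():
            j = int(np.argmax(pk_mags[sel]))
            counted.append((k, float(pk_freqs[sel][j]), float(pk_mags[sel][j])))
        k += 1
    if not counted:
        return HarmonicProfile(0, 0, ())
    mags = np.array([c[2] for c in counted])
    dominant = counted[int(np.argmax(mags))][0]  # argmax keeps lowest index on ties
    return HarmonicProfile(
        n_harmonics=len(counted),
        dominant_harmonic=dominant,
        peak_freqs_hz=tuple(c[1] for c in counted),
    )


def detect_harmonics(
    v: Vocalization,
    f0: float,
    tolerance_hz: float = 50.0,
    threshold_db: float = -40.0,
) -> HarmonicProfile:
    _check_not_silent(v)
    freqs, mag = _call_spectrum(v)
    return detect_harmonics_spectrum(freqs, mag, f0, tolerance_hz, threshold_db)


def assemble_features(
    v: Vocalization,
    set_id: str = "SET1",
    *,
    fmin: float = 1000.0,
    fmax: float = 8000.0,
    tolerance_hz: float = 50.0,
    threshold_db: float = -40.0,
) -> FeatureVector:
    """Full per-call feature vector in canonical order (SET1=30, SET2=38)."""
    if set_id not in ("SET1", "SET2"):
        raise ValueError(f"set_id must be SET1 or SET2, got {set_id!r}")
    try:
        mfcc = compute_mfcc(v)
        chroma = compute_chroma(v)
        stats = compute_spectral_stats(v)
        values = np.concatenate([mfcc, chroma, stats])
        if set_id == "SET2":
            track = estimate_pitch_track(v, fmin, fmax)
            f0_best, f0_max, f0_min, fmod, duration = summarize_pitch(track, v, fmin)
            pk = peak_frequency(v)
            if track.voiced.any():
                prof = detect_harmonics(v, f0_best, tolerance_hz, threshold_db)
                n_h = max(prof.n_harmonics, 1)
                dom = max(prof.dominant_harmonic, 1)
            else:
                n_h, dom = 1, 1
            values = np.concatenate(
                [values, [duration, f0_best, f0_max, f0_min, pk, fmod, n_h, dom]]
            )
    except ValueError as exc:
        raise ValueError(f"feature extraction failed for call {v.call_id!r}: {exc}") from exc
    names = tuple(SET1_NAMES if set_id == "SET1" else SET2_NAMES)
    return FeatureVector(names=names, values=values)


def extract_table(
    vocs, metadata: pd.DataFrame, set_id: str = "SET1", **kwargs
) -> pd.DataFrame:
    """Feature table for a batch of calls, keyed by call_id/subject_id.

    Metadata columns (sex, age_class, size_m, call_type) are carried
    through so downstream stages need only this one table.
    """
    meta = metadata.set_index("call_id")
    rows = []
    for v in vocs:
        fv = assemble_features(v, set_id, **kwargs)
        row = {"call_id": v.call_id, "subject_id": v.subject_id}
        row.update(dict(zip(fv.names, fv.values)))
        rows.append(row)
    out = pd.DataFrame(rows)
    for col in ("sex", "age_class", "size_m", "call_type"):
        if col in meta.columns:
            out[col] = meta.loc[out["call_id"], col].to_numpy()
    return out


def standardize(
    train: pd.DataFrame, apply_to: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zero-mean unit-variance scaling fitted on ``train`` only.

    Both tables are transformed with the train statistics (leakage-safe).
    Zero-variance train columns map to all zeros with a logged warning.
    """
    if train.empty:
        raise ValueError("train table is empty")
    if list(train.columns) != list(apply_to.columns):
        raise ValueError("column mismatch between train and apply tables")
    mean = train.mean(axis=0)
    std = train.std(axis=0, ddof=0)
    degenerate = std <= 0
    if degenerate.any():
        log.warning(
            "zero-variance feature columns mapped to 0: %s",
            list(train.columns[degenerate]),
        )
    std = std.where(~degenerate, 1.0)
    return (train - mean) / std, (apply_to - mean) / std
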