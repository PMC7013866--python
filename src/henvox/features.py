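"""The nine source-filter and spectral features computed per call event.

Vocal production is modelled source-filter style: a glottal source with
fundamental frequency f0 shaped by a vocal-tract filter whose resonances
are the formants F1-F3.  Frame-to-frame perturbation of frequency (jitter)
and of formant amplitude (shimmer), plus frame-level spectral statistics,
give the feature vector used for call classification, in this fixed order:

    1 jitter_f0   2 jitter_F1   3 jitter_F2   4 shimmer_F1   5 shimmer_F3
    6 zcr         7 spectral_spread           8 spectral_energy
    9 spectral_centroid

"Consecutive periods" in jitter/shimmer is realised as consecutive voiced
analysis frames: period-level glottal extraction is fragile on noisy barn
audio and the whole pipeline is frame-based.  Missing components (e.g. too
few voiced frames for jitter) are flagged NaN, never silently zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .audio_io import AudioClip

log = logging.getLogger(__name__)

FEATURE_NAMES = (
    "jitter_f0",
    "jitter_F1",
    "jitter_F2",
    "shimmer_F1",
    "shimmer_F3",
    "zcr",
    "spectral_spread",
    "spectral_energy",
    "spectral_centroid",
)
N_FEATURES = len(FEATURE_NAMES)

DEFAULT_FMIN = 200.0
DEFAULT_FMAX = 4000.0
DEFAULT_LPC_ORDER = 12
MAX_FORMANT_BANDWIDTH_HZ = 700.0
VOICING_THRESHOLD = 0.35
# Pitch/formant tracks use short contiguous (non-overlapping) frames so that
# "consecutive periods" in jitter/shimmer are genuinely disjoint stretches of
# signal; spectral features keep the pipeline's 512-sample 50%-overlap frames.
TRACK_FRAME_LEN = 256


@dataclass(frozen=True)
class PitchTrack:
    """Per-frame f0 estimates; unvoiced frames have f0 = NaN, voicing False."""

    times: np.ndarray
    f0: np.ndarray
    voicing: np.ndarray

    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voicing]


@dataclass(frozen=True)
class FormantTrack:
    """Per-frame formant frequencies (Hz) and linear amplitudes; NaN = absent.

    ``freqs`` and ``amps`` have shape (n_frames, 3) for F1..F3 / A1..A3.
    """

    times: np.ndarray
    freqs: np.ndarray
    amps: np.ndarray


@dataclass(frozen=True)
class FeatureVector:
    """The nine ordered features for one event; NaN marks a missing feature."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if v.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


# --- pitch ------------------------------------------------------------------


def estimate_pitch(
    event_audio: AudioClip,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
    frame_len: int = 512,
    hop: int | None = None,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> PitchTrack:
    """Autocorrelation pitch tracking with parabolic peak interpolation.

    Per frame, the normalised autocorrelation is maximised over lags in
    [rate/fmax, rate/fmin]; a parabola through the peak and its neighbours
    refines the lag.  Frames whose normalised peak falls below
    ``voicing_threshold`` are flagged unvoiced.  Events shorter than two
    pitch periods at fmin come back all-unvoiced.
    """
    rate = event_audio.rate
    if not 0 < fmin < fmax < rate / 2:
        raise ValueError(f"need 0 < fmin < fmax < Nyquist; got ({fmin}, {fmax})")
    hop = hop or frame_len // 2
    frames = _frames_for_analysis(event_audio, frame_len, hop)
    if frames is None:
        return PitchTrack(np.zeros(0), np.zeros(0), np.zeros(0, dtype=bool))
    blocks, times = frames
    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = min(frame_len - 2, int(np.ceil(rate / fmin)))
    n = len(blocks)
    f0 = np.full(n, np.nan)
    voicing = np.zeros(n, dtype=bool)
    if lag_max <= lag_min or len(event_audio.samples) < 2 * rate / fmin:
        return PitchTrack(times, f0, voicing)
    os = 8  # ACF oversampling: integer-lag sampling of sharp peaks is what
    # makes a far multiple of a non-integer true period win the argmax
    nfft = int(2 ** np.ceil(np.log2(2 * frame_len)))
    j_max = (lag_max + 1) * os
    lags = np.arange(j_max + 1) / os
    unbias = frame_len / np.maximum(frame_len - lags, 1.0)
    j_min = lag_min * os
    for i, block in enumerate(blocks):
        x = block - block.mean()
        if not x.any():
            continue
        spec = np.fft.rfft(x, nfft)
        acf = np.fft.irfft(np.abs(spec) ** 2, n=nfft * os)[: j_max + 1] * os
        if acf[0] <= 0:
            continue
        acf = acf / acf[0] * unbias
        j = int(np.argmax(acf[j_min : j_max + 1])) + j_min
        peak = acf[j]
        if min(peak, 1.0) < voicing_threshold:
            continue
        # the global argmax may sit on any multiple of the true period (all
        # multiples peak near 1 after unbiasing); take the *first* local peak
        # nearly as strong as the global one
        seg = acf[j_min : j_max + 1]
        strong = (seg >= 0.97 * peak)
        local = np.zeros_like(strong)
        local[1:-1] = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
        cand = np.nonzero(strong & local)[0]
        best_j = int(cand[0]) + j_min if len(cand) else j
        # parabolic refinement on the oversampled grid
        delta = 0.0
        if 0 < best_j < len(acf) - 1:
            y0, y1, y2 = acf[best_j - 1], acf[best_j], acf[best_j + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
        candidate = rate * os / (best_j + delta)
        if fmin <= candidate <= fmax:
            f0[i] = candidate
            voicing[i] = True
    return PitchTrack(times, f0, voicing)


# --- formants ---------------------------------------------------------------


def _levinson(r: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Levinson-Durbin recursion; returns LPC coefficients [1, a1..ap] and
    the final prediction-error power."""
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    for i in range(1, order + 1):
        acc = r[i] + np.dot(a[1:i], r[i - 1 : 0 : -1])
        k = -acc / err
        a[1 : i + 1] = a[1 : i + 1] + k * a[i - 1 :: -1][: i]
        err *= 1 - k * k
        if err <= 0:
            break
    return a, max(err, 0.0)


def estimate_formants(
    event_audio: AudioClip,
    n_formants: int = 3,
    lpc_order: int = DEFAULT_LPC_ORDER,
    frame_len: int = 512,
    hop: int | None = None,
    max_bandwidth_hz: float = MAX_FORMANT_BANDWIDTH_HZ,
) -> FormantTrack:
    """Per-frame linear-prediction formant estimates.

    Each frame is pre-emphasised, Hamming-windowed and fit with an
    order-``lpc_order`` all-pole model; resonances are the upper-half-plane
    roots of the prediction polynomial, converted to frequency/bandwidth.
    Broad resonances (bandwidth > ``max_bandwidth_hz``) are discarded as
    spurious; surviving resonances sorted ascending fill F1..Fn, missing
    ones stay NaN.  The per-formant amplitude is the frame's spectral
    magnitude integrated under a Gaussian weight centred on the *track
    median* of that formant's frequency: a point evaluation of the all-pole
    envelope is far too sensitive to pole-radius noise to carry shimmer,
    and re-centring the band on every frame's own resonance estimate would
    leak frequency jitter into the amplitude track.
    """
    if n_formants < 3:
        raise ValueError("n_formants must be >= 3")
    rate = event_audio.rate
    hop = hop or frame_len // 2
    frames = _frames_for_analysis(event_audio, frame_len, hop)
    if frames is None:
        z = np.zeros((0, n_formants))
        return FormantTrack(np.zeros(0), z, z.copy())
    blocks, times = frames
    n = len(blocks)
    freqs = np.full((n, n_formants), np.nan)
    amps = np.full((n, n_formants), np.nan)
    win = np.hamming(frame_len)
    bin_freqs = np.fft.rfftfreq(frame_len, d=1.0 / rate)
    amp_sigma = 300.0  # Hz; Gaussian integration width for formant amplitude
    powers = np.zeros((n, len(bin_freqs)))
    for i, block in enumerate(blocks):
        x = np.append(block[0], block[1:] - 0.97 * block[:-1]) * win
        if not x.any():
            continue
        powers[i] = np.abs(np.fft.rfft(block * win)) ** 2
        r = np.correlate(x, x, mode="full")[frame_len - 1 : frame_len + lpc_order]
        if r[0] <= 0:
            continue
        a, _ = _levinson(r, lpc_order)
        roots = np.roots(a)
        roots = roots[roots.imag > 1e-8]
        cand = []
        for root in roots:
            mag = min(abs(root), 1.0 - 1e-6)
            f = np.angle(root) * rate / (2 * np.pi)
            bw = -rate / np.pi * np.log(mag)
            if 90.0 < f < rate / 2 - 50.0 and bw < max_bandwidth_hz:
                cand.append(f)
        cand.sort()
        for j, f in enumerate(cand[:n_formants]):
            freqs[i, j] = f
    centres = np.asarray([
        np.nanmedian(col) if np.isfinite(col).any() else np.nan
        for col in freqs.T
    ])
    has_energy = powers.sum(axis=1) > 0
    for j, centre in enumerate(centres):
        if not np.isfinite(centre):
            continue
        weight = np.exp(-((bin_freqs - centre) ** 2) / (2 * amp_sigma**2))
        amps[has_energy, j] = np.sqrt(powers[has_energy] @ weight)
    return FormantTrack(times, freqs, amps)


def _frames_for_analysis(clip: AudioClip, frame_len: int, hop: int):
    """Unwindowed analysis blocks; short events are zero-padded to one frame."""
    x = clip.samples
    if len(x) == 0:
        return None
    if len(x) < frame_len:
        block = np.zeros(frame_len)
        block[: len(x)] = x
        blocks = block[None, :]
        times = np.array([clip.start_offset + len(x) / (2 * clip.rate)])
        return blocks, times
    n_frames = (len(x) - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    blocks = x[idx]
    times = clip.start_offset + (hop * np.arange(n_frames) + frame_len / 2) / clip.rate
    return blocks, times


# --- scalar features --------------------------------------------------------


def _trim_edges(track: np.ndarray, fraction: float = 0.25) -> np.ndarray:
    """Drop the first/last ``fraction`` of a track when enough frames remain."""
    k = int(len(track) * fraction)
    return track[k : len(track) - k] if len(track) - 2 * k >= 2 else track


def jitter(track_values: np.ndarray) -> float:
    """Mean |consecutive difference| / mean value; NaN if < 2 values present."""
    v = np.asarray(track_values, dtype=np.float64)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        return float("nan")
    mean = v.mean()
    if mean == 0:
        return float("nan")
    return float(np.abs(np.diff(v)).mean() / mean)


def shimmer(track_amplitudes: np.ndarray) -> float:
    """Jitter applied to per-frame formant amplitudes."""
    return jitter(track_amplitudes)


def zero_crossing_rate(frame: np.ndarray) -> float:
    """Fraction of consecutive-sample pairs with a sign change (zeros count
    as positive)."""
    x = np.asarray(frame, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("frame must have at least 2 samples")
    signs = np.where(x >= 0, 1, -1)
    return float(np.count_nonzero(signs[1:] != signs[:-1]) / (len(x) - 1))


def spectral_energy(spectrum: np.ndarray) -> float:
    """log10 of the sum of squared max-normalised bin energies.

    With the normalisation by the maximal bin, a single nonzero bin gives 0
    and L equal bins give log10(L), the attainable maximum.
    """
    e = np.asarray(spectrum, dtype=np.float64)
    if len(e) < 1:
        raise ValueError("spectrum must have at least one bin")
    peak = e.max()
    if peak <= 0:
        return float("nan")
    return float(np.log10(np.sum((e / peak) ** 2)))


def spectral_centroid(spectrum: np.ndarray, bin_freqs: np.ndarray) -> float:
    """Magnitude-weighted mean frequency (the spectrum's centre of gravity)."""
    m = np.asarray(spectrum, dtype=np.float64)
    f = np.asarray(bin_freqs, dtype=np.float64)
    total = m.sum()
    if total <= 0:
        return float("nan")
    return float(np.dot(f, m) / total)


def spectral_spread(spectrum: np.ndarray, bin_freqs: np.ndarray) -> float:
    """Square root of the magnitude-weighted second central moment (Hz)."""
    m = np.asarray(spectrum, dtype=np.float64)
    f = np.asarray(bin_freqs, dtype=np.float64)
    total = m.sum()
    if total <= 0:
        return float("nan")
    c = np.dot(f, m) / total
    return float(np.sqrt(np.dot((f - c) ** 2, m) / total))


# --- per-event assembly -----------------------------------------------------


def extract_features(
    event_audio: AudioClip,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
    frame_len: int = 512,
    lpc_order: int = DEFAULT_LPC_ORDER,
) -> FeatureVector | None:
    """Compute the nine-feature vector for one event's audio.

    Frame-level quantities (ZCR, spectral moments/energy) are averaged over
    the event's frames; jitter/shimmer come from the pitch and formant
    tracks.  Returns None (event dropped, logged) when every feature is
    missing — e.g. pure post-denoise silence.
    """
    hop = frame_len // 2
    frames = _frames_for_analysis(event_audio, frame_len, hop)
    vals = np.full(N_FEATURES, np.nan)
    if frames is None:
        log.info("event with no audio dropped")
        return None
    blocks, _ = frames
    nonsilent = blocks[np.abs(blocks).max(axis=1) > 0]
    if len(nonsilent):
        win = np.hamming(frame_len)
        mags = np.abs(np.fft.rfft(nonsilent * win, axis=1))
        energies = mags**2
        bin_freqs = np.fft.rfftfreq(frame_len, d=1.0 / event_audio.rate)
        vals[5] = float(np.mean([zero_crossing_rate(b) for b in nonsilent]))
        per_frame = [
            (
                spectral_spread(m, bin_freqs),
                spectral_energy(e),
                spectral_centroid(m, bin_freqs),
            )
            for m, e in zip(mags, energies)
        ]
        arr = np.asarray(per_frame)
        with np.errstate(invalid="ignore"):
            vals[6], vals[7], vals[8] = np.nanmean(arr, axis=0)
    pitch = estimate_pitch(
        event_audio, fmin, fmax, frame_len=TRACK_FRAME_LEN, hop=TRACK_FRAME_LEN
    )
    vals[0] = jitter(pitch.f0)
    formants = estimate_formants(
        event_audio, n_formants=3, lpc_order=lpc_order,
        frame_len=TRACK_FRAME_LEN, hop=TRACK_FRAME_LEN,
    )
    if len(formants.times):
        vals[1] = jitter(formants.freqs[:, 0])
        vals[2] = jitter(formants.freqs[:, 1])
        # amplitude perturbation is measured on the central portion of the
        # track: the deterministic onset/offset ramp is not shimmer
        vals[3] = shimmer(_trim_edges(formants.amps[:, 0]))
        vals[4] = shimmer(_trim_edges(formants.amps[:, 2]))
    if np.isnan(vals).all():
        log.info("event at %.3f s dropped: all nine features missing",
                 event_audio.start_offset)
        return None
    return FeatureVector(values=vals)
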