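"""Frame-level acoustic features aggregated per recording.

The per-recording feature vector concatenates the mean and population
standard deviation over frames of: a 12-bin chromagram (tonality), 13
mel-frequency cepstral coefficients (spectral envelope), RMS energy
(volume), zero-crossing rate (voicing/noisiness, crossings per second),
onset envelope (spectral flux, tracking abrupt energy rises such as
syllable starts), spectral bandwidth and spectral centroid — plus one
global tempo estimate in beats per minute from the onset-envelope
autocorrelation.  Total dimensionality: (12+13+1+1+1+1+1) x 2 + 1 = 61.

Silent recordings follow a zero convention: RMS, ZCR, centroid and
bandwidth are 0 where the spectrum carries no energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.fftpack import dct

from .audio import FRAME_LENGTH_S, AudioSignal, FrameMatrix, frame_audio
from .transcripts import SilenceStats

N_CHROMA = 12
N_MFCC = 13
N_MEL_FILTERS = 26
_TEMPO_BPM_RANGE = (30.0, 300.0)


def _names() -> tuple[str, ...]:
    names: list[str] = []
    for i in range(1, N_CHROMA + 1):
        names += [f"chroma_{i:02d}_mean", f"chroma_{i:02d}_std"]
    for i in range(1, N_MFCC + 1):
        names += [f"mfcc_{i:02d}_mean", f"mfcc_{i:02d}_std"]
    for base in ("rms", "zcr", "onset_env", "spectral_bandwidth", "spectral_centroid"):
        names += [f"{base}_mean", f"{base}_std"]
    names.append("tempo_bpm")
    return tuple(names)


#: Fixed output schema of :func:`extract_acoustic_features`.
ACOUSTIC_FEATURE_NAMES: tuple[str, ...] = _names()


@dataclass(frozen=True)
class AcousticFeatureVector:
    """Per-recording acoustic aggregates in schema order."""

    features: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.features) != ACOUSTIC_FEATURE_NAMES:
            raise ValueError("acoustic features do not match the fixed schema")
        vals = np.array(list(self.features.values()))
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite acoustic features")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.features.values()), dtype=float)


# ---------------------------------------------------------------------------
# frame-level primitives

def frame_rms(frames: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(frames**2, axis=1))


def frame_zcr(
    frames: np.ndarray, frame_length_s: float, contiguous: bool = False
) -> np.ndarray:
    """Zero crossings per second in each frame (samples >= 0 count as
    positive, so digital silence has rate 0).

    With ``contiguous=True`` (frames tiling the signal without overlap) the
    crossing at each frame boundary is credited to the later frame, so the
    total count matches the whole-signal crossing count.
    """
    nonneg = frames >= 0
    crossings = np.sum(nonneg[:, 1:] != nonneg[:, :-1], axis=1).astype(float)
    if contiguous and frames.shape[0] > 1:
        crossings[1:] += nonneg[1:, 0] != nonneg[:-1, -1]
    return crossings / frame_length_s


def _stft_magnitude(fm: FrameMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed magnitude spectra (n_frames, n_bins) and bin
    frequencies in Hz."""
    window = np.hanning(fm.frames.shape[1])
    spec = np.abs(rfft(fm.frames * window, axis=1))
    freqs = rfftfreq(fm.frames.shape[1], d=1.0 / fm.sample_rate_hz)
    return spec, freqs


def spectral_centroid(spec: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Magnitude-weighted mean frequency per frame; 0 for empty spectra."""
    total = spec.sum(axis=1)
    out = np.zeros(spec.shape[0])
    nz = total > 0
    out[nz] = (spec[nz] * freqs).sum(axis=1) / total[nz]
    return out


def spectral_bandwidth(spec: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Magnitude-weighted std of frequency around the centroid per frame."""
    total = spec.sum(axis=1)
    cent = spectral_centroid(spec, freqs)
    out = np.zeros(spec.shape[0])
    nz = total > 0
    dev2 = (freqs[None, :] - cent[:, None]) ** 2
    out[nz] = np.sqrt((spec[nz] * dev2[nz]).sum(axis=1) / total[nz])
    return out


def _mel_filterbank(n_filters: int, n_bins: int, sample_rate: int) -> np.ndarray:
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    nyquist = sample_rate / 2
    mel_pts = np.linspace(0, hz_to_mel(nyquist), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = np.linspace(0, nyquist, n_bins)
    fb = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        left, center, right = hz_pts[i : i + 3]
        up = (freqs - left) / max(center - left, 1e-12)
        down = (right - freqs) / max(right - center, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0, None)
    return fb


def mfcc(spec: np.ndarray, sample_rate: int, n_coefs: int = N_MFCC) -> np.ndarray:
    """Mel-frequency cepstral coefficients per frame from magnitude spectra."""
    power = spec**2
    fb = _mel_filterbank(N_MEL_FILTERS, spec.shape[1], sample_rate)
    mel_energy = power @ fb.T
    log_mel = np.log(mel_energy + 1e-10)
    return dct(log_mel, type=2, axis=1, norm="ortho")[:, :n_coefs]


def chroma(spec: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """12-bin pitch-class energy profile per frame.

    Each FFT bin above 25 Hz is mapped to its equal-tempered pitch class
    (A440 reference) and magnitudes are summed per class.
    """
    out = np.zeros((spec.shape[0], N_CHROMA))
    valid = freqs > 25.0
    midi = 69.0 + 12.0 * np.log2(freqs[valid] / 440.0)
    classes = np.mod(np.round(midi).astype(int), 12)
    sub = spec[:, valid]
    for c in range(N_CHROMA):
        out[:, c] = sub[:, classes == c].sum(axis=1)
    return out


def onset_envelope(spec: np.ndarray) -> np.ndarray:
    """Spectral flux per frame: summed positive magnitude increase relative
    to the previous frame (first frame 0)."""
    flux = np.zeros(spec.shape[0])
    if spec.shape[0] > 1:
        diff = np.diff(spec, axis=0)
        flux[1:] = np.clip(diff, 0, None).sum(axis=1)
    return flux


def tempo_bpm(onset_env: np.ndarray, hop_s: float) -> float:
    """Dominant rhythmic rate from the onset-envelope autocorrelation.

    Searches lags corresponding to 30-300 beats/min and returns 0 for a
    flat envelope (no onsets).
    """
    env = onset_env - onset_env.mean()
    if not np.any(env):
        return 0.0
    ac = np.correlate(env, env, mode="full")[env.size - 1 :]
    lo = max(1, int(round(60.0 / _TEMPO_BPM_RANGE[1] / hop_s)))
    hi = min(ac.size - 1, int(round(60.0 / _TEMPO_BPM_RANGE[0] / hop_s)))
    if hi <= lo:
        return 0.0
    lag = lo + int(np.argmax(ac[lo : hi + 1]))
    return 60.0 / (lag * hop_s)


# ---------------------------------------------------------------------------
# public operations

def extract_acoustic_features(
    a: AudioSignal,
    frame_length_s: float = FRAME_LENGTH_S,
    hop_s: float | None = None,
) -> AcousticFeatureVector:
    """Compute the fixed 61-value acoustic feature vector for a recording."""
    fm = frame_audio(a, frame_length_s, hop_s)
    spec, freqs = _stft_magnitude(fm)

    per_frame: list[tuple[str, np.ndarray]] = []
    ch = chroma(spec, freqs)
    for i in range(N_CHROMA):
        per_frame.append((f"chroma_{i + 1:02d}", ch[:, i]))
    mf = mfcc(spec, fm.sample_rate_hz)
    for i in range(N_MFCC):
        per_frame.append((f"mfcc_{i + 1:02d}", mf[:, i]))
    env = onset_envelope(spec)
    per_frame += [
        ("rms", frame_rms(fm.frames)),
        ("zcr", frame_zcr(fm.frames, fm.frame_length_s,
                          contiguous=fm.hop_s == fm.frame_length_s)),
        ("onset_env", env),
        ("spectral_bandwidth", spectral_bandwidth(spec, freqs)),
        ("spectral_centroid", spectral_centroid(spec, freqs)),
    ]
    feats = {}
    for name, values in per_frame:
        feats[f"{name}_mean"] = float(values.mean())
        feats[f"{name}_std"] = float(values.std())
    feats["tempo_bpm"] = tempo_bpm(env, fm.hop_s)
    ordered = {k: feats[k] for k in ACOUSTIC_FEATURE_NAMES}
    return AcousticFeatureVector(ordered)


def silence_stats_from_audio(
    a: AudioSignal,
    rms_threshold: float = 0.02,
    min_silence_s: float = 0.25,
    frame_length_s: float = FRAME_LENGTH_S,
) -> SilenceStats:
    """Energy-based silence statistics.

    A silence is a maximal run of non-overlapping frames whose RMS falls
    below ``rms_threshold`` times the peak frame RMS, lasting at least
    ``min_silence_s``; statistics use the population standard deviation.
    A completely silent recording counts as one silence spanning it.

    Frames partially covered by speech at either edge of a gap are not
    silent, so a raw run undercounts the gap by about one frame; durations
    are therefore edge-corrected by one frame length (clamped to the
    recording duration), making them unbiased against timestamp-derived
    gap durations.
    """
    fm = frame_audio(a, frame_length_s, frame_length_s)
    rms = frame_rms(fm.frames)
    peak = rms.max()
    if peak == 0:
        return SilenceStats(a.duration_s, 0.0, 1)
    silent = rms < rms_threshold * peak
    durations = []
    run = 0
    for flag in silent:
        if flag:
            run += 1
        elif run:
            durations.append(min((run + 1) * frame_length_s, a.duration_s))
            run = 0
    if run:
        durations.append(min((run + 1) * frame_length_s, a.duration_s))
    durs = np.array([d for d in durations if d >= min_silence_s])
    if durs.size == 0:
        return SilenceStats(0.0, 0.0, 0)
    return SilenceStats(float(durs.mean()), float(durs.std()), int(durs.size))
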