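"""Audio container, WAV I/O, preprocessing and framing.

Recordings are peak-normalized (so volume differences between sessions do
not bias the features) and low-pass filtered with a zero-phase Butterworth
filter to attenuate high-frequency environmental noise, then segmented into
25 ms windows for frame-level feature computation.  All audio is resampled
to 16 kHz mono so feature dimensions are deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

#: Processing sample rate (Hz); all input audio is resampled to this.
DEFAULT_SAMPLE_RATE = 16_000

#: Analysis window length in seconds (25 ms).
FRAME_LENGTH_S = 0.025


class AudioError(ValueError):
    """Raised for invalid audio input."""


@dataclass(frozen=True)
class AudioSignal:
    """Mono audio samples in [-1, 1] with their sample rate."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float).ravel()
        if arr.size == 0:
            raise AudioError("empty audio signal")
        if not np.all(np.isfinite(arr)):
            raise AudioError("audio contains non-finite samples")
        object.__setattr__(self, "samples", arr)
        if self.sample_rate_hz <= 0:
            raise AudioError(f"sample rate must be positive, got {self.sample_rate_hz}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


@dataclass(frozen=True)
class FrameMatrix:
    """Fixed-length analysis windows cut from a signal."""

    frames: np.ndarray  # (n_frames, frame_length_samples)
    frame_length_s: float
    hop_s: float
    sample_rate_hz: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def read_wav(path, target_rate: int = DEFAULT_SAMPLE_RATE) -> AudioSignal:
    """Read a PCM/float WAV file, downmix to mono, scale to [-1, 1] and
    resample to ``target_rate``."""
    rate, raw = wavfile.read(path)
    data = np.asarray(raw, dtype=float)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        data = data / max(abs(info.min), info.max)
    if rate != target_rate:
        g = math.gcd(int(rate), int(target_rate))
        data = sps.resample_poly(data, target_rate // g, rate // g)
    return AudioSignal(np.clip(data, -1.0, 1.0), target_rate)


def write_wav(path, a: AudioSignal) -> None:
    wavfile.write(path, a.sample_rate_hz, a.samples.astype(np.float32))


def normalize_amplitude(a: AudioSignal) -> AudioSignal:
    """Scale so the peak absolute sample is 1; all-zero signals pass through."""
    peak = np.max(np.abs(a.samples))
    if peak == 0:
        return a
    return AudioSignal(a.samples / peak, a.sample_rate_hz)


def preprocess_audio(
    a: AudioSignal, cutoff_hz: float = 7000.0, order: int = 4
) -> AudioSignal:
    """Peak-normalize, then apply a zero-phase Butterworth low-pass filter.

    The filter is applied forward-backward (``sosfiltfilt``), so the
    effective magnitude response is the squared one-pass Butterworth
    response ``1 / (1 + (f/fc)^(2*order))``.  An all-zero signal is returned
    unchanged with a warning.
    """
    nyquist = a.sample_rate_hz / 2
    if not 0 < cutoff_hz < nyquist:
        raise AudioError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz "
            f"for sample rate {a.sample_rate_hz}"
        )
    if np.max(np.abs(a.samples)) == 0:
        warnings.warn("all-zero audio signal: skipping preprocessing", stacklevel=2)
        return a
    x = normalize_amplitude(a).samples
    sos = sps.butter(order, cutoff_hz, btype="low", fs=a.sample_rate_hz, output="sos")
    # tiny DC bias keeps the filter state out of the denormal range during
    # long silences (orders-of-magnitude slowdown otherwise); the bias is
    # below double-precision resolution of the unit-peak signal
    return AudioSignal(sps.sosfiltfilt(sos, x + 1e-20), a.sample_rate_hz)


def frame_audio(
    a: AudioSignal,
    frame_length_s: float = FRAME_LENGTH_S,
    hop_s: float | None = None,
) -> FrameMatrix:
    """Segment into fixed windows of ``frame_length_s`` seconds.

    The default hop equals the frame length (non-overlapping 25 ms
    windows); pass e.g. ``hop_s=0.010`` for overlapping analysis.  The final
    partial window is discarded; the frame count is
    ``floor((n_samples - frame_length) / hop) + 1``.
    """
    if hop_s is None:
        hop_s = frame_length_s
    frame_len = round(frame_length_s * a.sample_rate_hz)
    hop = round(hop_s * a.sample_rate_hz)
    if frame_len < 1 or hop < 1:
        raise AudioError("frame and hop must be at least one sample")
    n = a.samples.size
    if n < frame_len:
        raise AudioError(
            f"signal of {n} samples shorter than one frame "
            f"({frame_len} samples at {a.sample_rate_hz} Hz)"
        )
    n_frames = (n - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return FrameMatrix(a.samples[idx], frame_length_s, hop_s, a.sample_rate_hz)
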