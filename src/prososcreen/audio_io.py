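"""WAV input, channel selection, normalization and signal framing.

Recordings are expected as RIFF PCM WAV, mono or stereo, 8/16/24/32-bit
integer or 32/64-bit float, at any sample rate >= 8 kHz.  The two-microphone
recording setup places the patient on the left channel, so ``channel="left"``
is the default for stereo files.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile

__all__ = ["AudioSignal", "FrameSeries", "load_audio", "save_wav", "frame_signal"]

MIN_SAMPLE_RATE = 8000


@dataclass(frozen=True)
class AudioSignal:
    """A mono waveform with its sample rate; samples are float64 in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("AudioSignal requires a 1-D sample array")
        if samples.size == 0:
            raise ValueError("zero-length audio")
        if not np.all(np.isfinite(samples)):
            raise ValueError("audio contains non-finite samples")
        if self.sample_rate < MIN_SAMPLE_RATE:
            raise ValueError(
                f"sample rate {self.sample_rate} Hz below supported minimum "
                f"{MIN_SAMPLE_RATE} Hz"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def scaled(self, factor: float) -> "AudioSignal":
        return AudioSignal(self.samples * factor, self.sample_rate)


@dataclass(frozen=True)
class FrameSeries:
    """Uniformly hopped analysis frames; times mark frame centers."""

    frame_times: np.ndarray
    frames: np.ndarray  # (n_frames, frame_len) view
    window_s: float
    hop_s: float
    sample_rate: int


def _to_float(data: np.ndarray) -> np.ndarray:
    """Scale integer PCM by its full-scale constant; pass floats through."""
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        return (data.astype(np.float64) - 128.0) / 128.0
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:  # includes 24-bit PCM promoted by scipy
        return data.astype(np.float64) / 2147483648.0
    if data.dtype in (np.float32, np.float64):
        out = data.astype(np.float64)
        peak = np.max(np.abs(out)) if out.size else 0.0
        if peak > 1.0:  # peak-normalize out-of-range float input only
            out = out / peak
        return out
    raise ValueError(f"unsupported WAV sample encoding: {data.dtype}")


def load_audio(path, channel: str = "left") -> AudioSignal:
    """Read a PCM WAV file and return a mono :class:`AudioSignal`.

    Parameters
    ----------
    path:
        Path to a RIFF PCM WAV file.
    channel:
        For stereo input: ``"left"``, ``"right"``, or ``"mix"`` (average of
        the two channels).  Ignored for mono files.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    x = _to_float(np.asarray(data))
    if x.ndim == 2:
        if channel == "left":
            x = x[:, 0]
        elif channel == "right":
            x = x[:, 1]
        elif channel == "mix":
            x = x.mean(axis=1)
        else:
            raise ValueError(f"unknown channel selector: {channel!r}")
    return AudioSignal(x, int(rate))


def save_wav(signal: AudioSignal, path) -> None:
    """Write a signal as 16-bit PCM WAV (bit-exact round trip with load)."""
    x = np.clip(np.round(signal.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, signal.sample_rate, x)


def frame_signal(signal: AudioSignal, window_s: float, hop_s: float) -> FrameSeries:
    """Slice a signal into overlapping frames.

    Frame length is ``floor(window_s * rate)`` samples and the hop
    ``floor(hop_s * rate)``; the number of frames is
    ``floor((N - L) / H) + 1``.
    """
    if not 0 < hop_s <= window_s:
        raise ValueError("require 0 < hop_s <= window_s")
    fs = signal.sample_rate
    n = signal.samples.size
    length = int(np.floor(window_s * fs))
    hop = int(np.floor(hop_s * fs))
    if length < 1 or hop < 1:
        raise ValueError("window/hop shorter than one sample")
    if length > n:
        raise ValueError(f"window of {length} samples exceeds signal of {n}")
    frames = sliding_window_view(signal.samples, length)[::hop]
    times = (np.arange(frames.shape[0]) * hop + length / 2) / fs
    return FrameSeries(times, frames, window_s, hop_s, fs)
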