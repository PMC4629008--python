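"""Fundamental-frequency tracking and voicing.

A RAPT-family tracker: normalized cross-correlation (NCCF) candidate
generation followed by dynamic-programming candidate selection that
penalizes octave jumps and voicing transitions.  The tracker supplies the
vocal-activity limits used to clip syllable-nucleus boundaries and the
per-frame F0 behind the F0 dispersion features.

The signal is internally decimated to ~8 kHz for the correlation search
(the F0 band tops out at a few hundred Hz); frame times stay on the
original signal's clock.  The energy-envelope stage is unaffected and runs
at the full rate.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import List

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import resample_poly

from .audio_io import AudioSignal

__all__ = [
    "PitchTrack",
    "VoicedRegion",
    "track_pitch",
    "voiced_regions",
    "hz_to_semitones",
]

# DP weights: octave-jump penalty per octave, voicing-transition penalty,
# and a small short-lag preference that resolves period-multiple ambiguity
# in strongly periodic frames.
_OCTAVE_COST = 0.35
_TRANSITION_COST = 0.12
_LAG_BIAS = 0.05

_ANALYSIS_RATE = 8000.0
_CORR_WINDOW_S = 0.0075
_MAX_CANDIDATES = 4


@dataclass(frozen=True)
class PitchTrack:
    """Per-frame F0 (NaN where unvoiced) on a uniform time grid."""

    frame_times: np.ndarray
    f0_hz: np.ndarray
    voiced: np.ndarray
    hop_s: float

    def __len__(self) -> int:
        return self.frame_times.size

    @property
    def voiced_fraction(self) -> float:
        return float(np.mean(self.voiced)) if len(self) else 0.0

    def dump(self, path) -> None:
        """Two-column text dump (time_s, f0_hz; unvoiced written as NaN)."""
        with open(path, "w") as fh:
            fh.write("time_s\tf0_hz\n")
            for t, f, v in zip(self.frame_times, self.f0_hz, self.voiced):
                fh.write(f"{t:.6f}\t{f:.4f}\n" if v else f"{t:.6f}\tnan\n")


@dataclass(frozen=True)
class VoicedRegion:
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


def hz_to_semitones(f, f_ref: float = 100.0):
    """Convert frequency to semitones relative to ``f_ref``: 12*log2(f/f_ref)."""
    f = np.asarray(f, dtype=np.float64)
    if f_ref <= 0:
        raise ValueError("f_ref must be positive")
    if np.any(f <= 0):
        raise ValueError("frequency must be positive for semitone conversion")
    out = 12.0 * np.log2(f / f_ref)
    return float(out) if out.ndim == 0 else out


def _nccf_frames(x: np.ndarray, hop: int, win: int, lmax: int) -> np.ndarray:
    """Batched NCCF: rows = frames, columns = lags 0..lmax."""
    seg_len = win + lmax
    segs = sliding_window_view(x, seg_len)[::hop]
    n_frames = segs.shape[0]
    out = np.empty((n_frames, lmax + 1), dtype=np.float64)
    size = 1 << int(seg_len - 1).bit_length()
    if size < seg_len:
        size *= 2
    hi_idx = np.arange(lmax + 1) + win - 1
    tiny = 1e-30
    for a in range(0, n_frames, 4096):
        b = min(a + 4096, n_frames)
        seg = segs[a:b] - segs[a:b].mean(axis=1, keepdims=True)
        head = seg[:, :win]
        corr = np.fft.irfft(
            np.conj(np.fft.rfft(head, size)) * np.fft.rfft(seg, size), size
        )[:, : lmax + 1]
        cs = np.cumsum(seg * seg, axis=1)
        e_k = cs[:, hi_idx].copy()
        e_k[:, 1:] -= cs[:, :lmax]
        e_0 = cs[:, win - 1 : win]
        out[a:b] = corr / np.sqrt(e_0 * e_k + tiny)
    return out


def _frame_candidates(row: np.ndarray, lmin: int, lmax: int):
    """Local NCCF maxima in the lag search band, parabolic-refined."""
    c = row[lmin : lmax + 1]
    if c.size < 3:
        return np.empty(0), np.empty(0)
    interior = np.flatnonzero((c[1:-1] >= c[:-2]) & (c[1:-1] > c[2:])) + 1
    if interior.size == 0:
        return np.empty(0), np.empty(0)
    if interior.size > _MAX_CANDIDATES:
        keep = np.argpartition(c[interior], -_MAX_CANDIDATES)[-_MAX_CANDIDATES:]
        interior = interior[keep]
    lags = []
    vals = []
    for i in interior:
        k = i + lmin
        y0, y1, y2 = row[k - 1], row[k], row[k + 1] if k + 1 < row.size else row[k]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        lags.append(k + delta)
        vals.append(float(y1))
    order = np.argsort(lags)
    return np.asarray(lags)[order], np.asarray(vals)[order]


def track_pitch(
    signal: AudioSignal,
    f_min: float = 60.0,
    f_max: float = 400.0,
    hop_s: float = 0.005,
    voicing_threshold: float = 0.3,
) -> PitchTrack:
    """Estimate per-frame F0 and voicing.

    Frames whose best NCCF stays below ``voicing_threshold`` come out
    unvoiced (their ``f0_hz`` is NaN).  A silent signal yields an all-unvoiced
    track rather than an error.
    """
    fs = signal.sample_rate
    if not (20.0 <= f_min < f_max <= fs / 4.0):
        raise ValueError("require 20 <= f_min < f_max <= sample_rate/4")
    x = signal.samples
    if fs > 1.5 * _ANALYSIS_RATE:
        frac = Fraction(int(_ANALYSIS_RATE), int(fs)).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
        fa = fs * frac.numerator / frac.denominator
    else:
        fa = float(fs)
    hop = max(1, int(round(hop_s * fa)))
    win = max(8, int(round(_CORR_WINDOW_S * fa)))
    lmin = max(2, int(np.floor(fa / f_max)))
    lmax = int(np.ceil(fa / f_min))
    seg_len = win + lmax
    if x.size < seg_len + 1:
        return PitchTrack(np.empty(0), np.empty(0), np.empty(0, bool), hop_s)

    nccf = _nccf_frames(x, hop, win, lmax)
    n_frames = nccf.shape[0]
    cands: List[tuple] = [_frame_candidates(nccf[t], lmin, lmax) for t in range(n_frames)]

    # Dynamic program over (candidates + explicit unvoiced state) per frame.
    unvoiced_cost = 1.0 - voicing_threshold
    prev_cost = None
    prev_freq = None
    back: List[np.ndarray] = []
    for t in range(n_frames):
        lags, vals = cands[t]
        freqs = fa / lags if lags.size else np.empty(0)
        local = np.empty(freqs.size + 1)
        local[:-1] = 1.0 - vals + _LAG_BIAS * (lags / lmax)
        local[-1] = unvoiced_cost
        if prev_cost is None:
            cost = local
            back.append(np.full(local.size, -1, dtype=np.int64))
        else:
            n_prev_v = prev_freq.size
            trans = np.full((local.size, prev_cost.size), _TRANSITION_COST)
            if freqs.size and n_prev_v:
                trans[:-1, :n_prev_v] = _OCTAVE_COST * np.abs(
                    np.log2(freqs[:, None] / prev_freq[None, :])
                )
            trans[-1, -1] = 0.0  # unvoiced -> unvoiced
            total = prev_cost[None, :] + trans
            ptr = np.argmin(total, axis=1)
            cost = local + total[np.arange(local.size), ptr]
            back.append(ptr)
        prev_cost = cost
        prev_freq = freqs

    f0 = np.full(n_frames, np.nan)
    voiced = np.zeros(n_frames, dtype=bool)
    state = int(np.argmin(prev_cost))
    for t in range(n_frames - 1, -1, -1):
        lags, vals = cands[t]
        if state < lags.size:
            voiced[t] = True
            f0[t] = float(np.clip(fa / lags[state], f_min, f_max))
        state = int(back[t][state]) if t > 0 else -1
    f0 = _median_smooth_runs(f0, voiced, width=5)
    times = (np.arange(n_frames) * hop + win / 2.0) / fa
    return PitchTrack(times, f0, voiced, hop_s)


def _median_smooth_runs(f0: np.ndarray, voiced: np.ndarray, width: int = 5) -> np.ndarray:
    """Median-filter F0 within each voiced run; removes octave-spike frames."""
    out = f0.copy()
    half = width // 2
    n = f0.size
    i = 0
    while i < n:
        if not voiced[i]:
            i += 1
            continue
        j = i
        while j < n and voiced[j]:
            j += 1
        run = f0[i:j]
        if run.size >= 3:
            sm = np.empty_like(run)
            for k in range(run.size):
                a = max(0, k - half)
                b = min(run.size, k + half + 1)
                sm[k] = np.median(run[a:b])
            out[i:j] = sm
        i = j
    return out


def voiced_regions(track: PitchTrack, min_duration_s: float = 0.0) -> List[VoicedRegion]:
    """Maximal voiced runs as [start, end) intervals.

    A run of ``k`` consecutive voiced frames spans ``k * hop`` seconds
    (first frame time to one hop past the last).  Runs shorter than
    ``min_duration_s`` are discarded.
    """
    if len(track) == 0:
        raise ValueError("empty pitch track")
    v = np.asarray(track.voiced, dtype=bool)
    if not v.any():
        return []
    edges = np.diff(v.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if v[0]:
        starts.insert(0, 0)
    if v[-1]:
        ends.append(v.size)
    out = []
    for s, e in zip(starts, ends):
        t0 = float(track.frame_times[s])
        t1 = float(track.frame_times[e - 1] + track.hop_s)
        if t1 - t0 >= min_duration_s:
            out.append(VoicedRegion(t0, t1))
    return out
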