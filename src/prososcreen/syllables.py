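"""Syllable-nucleus detection from the energy envelope.

The detector follows an envelope/periodicity design: the waveform is
band-pass filtered to the vowel-energy band, a Hann-weighted RMS envelope is
computed at full signal rate with a 10 ms window and 5 ms hop (no
downsampling, to keep temporal resolution), nuclei are picked as prominent
envelope peaks under a relative threshold, and nucleus boundaries are the
nearest envelope minima clipped by the vocal-activity limits delivered by
the pitch tracker.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import AudioSignal, frame_signal
from .config import PipelineConfig
from .pitch import PitchTrack, VoicedRegion, track_pitch, voiced_regions

__all__ = [
    "Envelope",
    "SyllableNucleus",
    "compute_envelope",
    "detect_peaks",
    "estimate_boundaries",
    "annotate_f0",
    "detect_syllables",
]


@dataclass(frozen=True)
class Envelope:
    """Smoothed band-energy envelope on a uniform frame grid."""

    frame_times: np.ndarray
    values: np.ndarray
    window_s: float
    hop_s: float

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SyllableNucleus:
    """One detected nucleus: envelope peak plus estimated boundaries.

    ``f0_values`` holds the voiced-frame F0 samples inside [onset, offset);
    ``mean_f0_hz`` is their arithmetic mean, NaN (with ``voiced=False``)
    when no voiced frame falls inside the nucleus.
    """

    peak_time: float
    onset: float
    offset: float
    peak_value: float
    mean_f0_hz: float = float("nan")
    f0_values: Optional[np.ndarray] = None
    voiced: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def compute_envelope(
    signal: AudioSignal,
    window_s: float = 0.010,
    hop_s: float = 0.005,
    band: Sequence[float] = (300.0, 2500.0),
    smooth_frames: int = 3,
) -> Envelope:
    """Band-passed, Hann-weighted RMS energy envelope.

    The band-pass (4th-order Butterworth, zero-phase) isolates the
    vowel-energy band; per-frame weighted RMS then a short moving average
    give a smooth envelope whose peaks sit on syllable nuclei.
    """
    fs = signal.sample_rate
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    if not 0 < lo < hi:
        raise ValueError("invalid band edges")
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sosfiltfilt(sos, signal.samples)
    series = frame_signal(AudioSignal(np.ascontiguousarray(y), fs), window_s, hop_s)
    w = np.hanning(series.frames.shape[1])
    wsum = w.sum() if w.sum() > 0 else 1.0
    vals = np.sqrt(np.maximum((series.frames**2 * w).sum(axis=1) / wsum, 0.0))
    k = max(1, int(smooth_frames))
    if k > 1:
        vals = np.convolve(vals, np.ones(k) / k, mode="same")
    return Envelope(series.frame_times, vals, window_s, hop_s)


def detect_peaks(
    env: Envelope, rel_threshold: float = 0.3, min_gap_s: float = 0.06
) -> np.ndarray:
    """Pick nucleus peak times with a relative-prominence threshold.

    A local maximum qualifies when it exceeds ``floor + rel_threshold *
    (max - floor)`` (floor = 5th percentile of the envelope).  Maxima closer
    than ``min_gap_s`` merge keeping the larger; so do maxima separated only
    by a valley shallower than the threshold margin, so every surviving peak
    rises above its adjacent valleys (and the envelope edges) by the margin.
    """
    if len(env) == 0:
        raise ValueError("empty envelope")
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    if min_gap_s <= 0:
        raise ValueError("min_gap_s must be positive")
    v = env.values
    floor = float(np.percentile(v, 5))
    margin = rel_threshold * (float(v.max()) - floor)
    if margin <= 0:
        return np.empty(0)
    thr = floor + margin
    # local maxima: >= left neighbor, > right neighbor (plateau start wins)
    left_ok = np.r_[True, v[1:] >= v[:-1]]
    right_ok = np.r_[v[:-1] > v[1:], True]
    cand = [int(i) for i in np.flatnonzero(left_ok & right_ok & (v > thr))]
    if not cand:
        return np.empty(0)
    hop = env.hop_s
    merged: List[int] = []
    for i in cand:
        if merged and (i - merged[-1]) * hop < min_gap_s:
            if v[i] > v[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    # merge across shallow valleys until every inter-peak valley is deep
    changed = True
    while changed and len(merged) > 1:
        changed = False
        out = [merged[0]]
        for i in merged[1:]:
            valley = float(v[out[-1] : i + 1].min())
            if min(v[out[-1]], v[i]) - valley < margin:
                if v[i] > v[out[-1]]:
                    out[-1] = i
                changed = True
            else:
                out.append(i)
        merged = out
    # edge prominence: first/last peak must clear the envelope edge valley
    if merged and v[merged[0]] - v[: merged[0] + 1].min() < margin:
        merged = merged[1:]
    if merged and v[merged[-1]] - v[merged[-1] :].min() < margin:
        merged = merged[:-1]
    if not merged:
        return np.empty(0)
    return env.frame_times[np.asarray(merged, dtype=np.int64)]


def estimate_boundaries(
    peaks: Sequence[float],
    env: Envelope,
    regions: Sequence[VoicedRegion] = (),
) -> List[SyllableNucleus]:
    """Nucleus boundaries from envelope minima clipped by voicing limits.

    The candidate onset/offset of a peak are the bottoms of the envelope
    valleys toward its neighboring peaks (or the envelope edges); valley
    ties break toward the peak, and adjacent nuclei sharing a valley bottom
    split there.  The voiced region containing (or nearest to) the peak
    then tightens the boundaries to the vocal-activity limits.  A peak
    whose voiced region lies entirely to one side falls back to the
    envelope valleys alone; degenerate (zero-length) nuclei are dropped.
    """
    if len(env) == 0:
        raise ValueError("empty envelope")
    peaks = np.asarray(sorted(peaks), dtype=np.float64)
    if peaks.size == 0:
        return []
    t0, t1 = env.frame_times[0], env.frame_times[-1]
    if peaks[0] < t0 - env.hop_s or peaks[-1] > t1 + env.hop_s:
        raise ValueError("peak outside envelope span")
    v = env.values
    # actual frame spacing (floor(hop_s*rate)/rate), not the nominal hop_s
    dt = (t1 - t0) / (v.size - 1) if v.size > 1 else env.hop_s
    idxs = np.clip(np.round((peaks - t0) / dt).astype(int), 0, v.size - 1)
    starts = np.array([r.start for r in regions])
    ends = np.array([r.end for r in regions])
    out: List[SyllableNucleus] = []
    for k, pt in enumerate(peaks):
        ip = int(idxs[k])
        lo = int(idxs[k - 1]) if k > 0 else 0
        hi = int(idxs[k + 1]) if k + 1 < peaks.size else v.size - 1
        # valley bottoms; ties toward the peak (smaller nucleus)
        seg_l = v[lo : ip + 1]
        il = lo + (seg_l.size - 1 - int(np.argmin(seg_l[::-1])))
        seg_r = v[ip : hi + 1]
        ir = ip + int(np.argmin(seg_r))
        # first/last peak with no proper valley on the outward side: clip to
        # the signal extent
        if k == 0 and (il == 0 or il == ip):
            left = 0.0
        else:
            left = float(env.frame_times[il])
        if k == peaks.size - 1 and ir == ip:
            right = float(t1)
        else:
            right = float(env.frame_times[ir])
        onset, offset = left, right
        if len(regions):
            inside = np.flatnonzero((starts <= pt) & (pt < ends))
            if inside.size:
                r = inside[0]
            else:  # nearest region by edge distance, ties toward earlier
                d = np.minimum(np.abs(starts - pt), np.abs(ends - pt))
                r = int(np.argmin(d))
            ons = max(left, float(starts[r]))
            off = min(right, float(ends[r]))
            if ons <= pt <= off and off > ons:
                onset, offset = ons, off
        if offset <= onset:
            continue
        onset = max(onset, 0.0)
        out.append(
            SyllableNucleus(
                peak_time=float(pt),
                onset=float(onset),
                offset=float(offset),
                peak_value=float(v[ip]),
            )
        )
    # enforce disjointness at shared minima (half-open intervals)
    for i in range(1, len(out)):
        if out[i].onset < out[i - 1].offset:
            out[i] = replace(out[i], onset=min(out[i - 1].offset, out[i].peak_time))
    return [n for n in out if n.duration > 0]


def annotate_f0(
    nuclei: Sequence[SyllableNucleus],
    track: PitchTrack,
    edge_trim_s: float = 0.015,
) -> List[SyllableNucleus]:
    """Attach voiced-frame F0 samples and their mean to each nucleus.

    Frames within ``edge_trim_s`` of a nucleus boundary are excluded: their
    correlation windows straddle the onset/offset transition, where F0
    estimates are unreliable (the same reason nucleus edges, not syllable
    borders, delimit the usable F0 region).  If trimming would leave a
    short nucleus empty, the untrimmed voiced frames are used instead.
    """
    out = []
    t = track.frame_times
    for nuc in nuclei:
        mask = (
            track.voiced
            & (t >= nuc.onset + edge_trim_s)
            & (t < nuc.offset - edge_trim_s)
        )
        if not mask.any():
            mask = track.voiced & (t >= nuc.onset) & (t < nuc.offset)
        vals = np.asarray(track.f0_hz[mask], dtype=np.float64)
        if vals.size:
            out.append(
                replace(
                    nuc,
                    f0_values=vals,
                    mean_f0_hz=float(vals.mean()),
                    voiced=True,
                )
            )
        else:
            out.append(
                replace(nuc, f0_values=np.empty(0), mean_f0_hz=float("nan"), voiced=False)
            )
    return out


def detect_syllables(signal: AudioSignal, config: Optional[PipelineConfig] = None):
    """Full detection chain: envelope + pitch -> annotated nuclei.

    Returns ``(nuclei, track, envelope)``.
    """
    cfg = config or PipelineConfig()
    env = compute_envelope(
        signal,
        window_s=cfg.envelope.window_s,
        hop_s=cfg.envelope.hop_s,
        band=cfg.envelope.band,
        smooth_frames=cfg.envelope.smooth_frames,
    )
    track = track_pitch(
        signal,
        f_min=cfg.pitch.f_min,
        f_max=cfg.pitch.f_max,
        hop_s=cfg.pitch.hop_s,
        voicing_threshold=cfg.pitch.voicing_threshold,
    )
    regions = voiced_regions(track, cfg.pitch.min_voiced_s) if len(track) else []
    peaks = detect_peaks(env, cfg.envelope.rel_threshold, cfg.envelope.min_gap_s)
    nuclei = estimate_boundaries(peaks, env, regions)
    nuclei = annotate_f0(nuclei, track)
    return nuclei, track, env
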