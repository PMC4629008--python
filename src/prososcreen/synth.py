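"""Synthetic speech and cohort generators with exact ground truth.

Two emulation layers make every pipeline stage testable without clinical
recordings (none were ever released for this task):

* **Waveforms** — read-speech-like syllable trains: each syllable is a
  harmonic source (1/h spectral tilt) with a Hann amplitude envelope and a
  within-syllable F0 glide, separated by short gaps or longer pauses, plus
  additive white noise at a configurable SNR.  The ground truth (syllable
  onsets/offsets, per-syllable F0, all twelve features) is computed
  analytically from the generating timeline, never from the detector.

* **Feature cohorts** — two-group tables drawn per feature from truncated
  normals whose means/SDs/ranges reproduce the published descriptive
  statistics of the mild-dementia (MD) and control (non-MD) groups.
  Feature draws are independent across features (no covariance structure
  is published); see the methods note for what that does and does not
  exercise.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .audio_io import AudioSignal
from .features import (
    FEATURE_NAMES,
    ProsodicFeatureVector,
    compute_features,
    detect_pauses,
)
from .syllables import SyllableNucleus

__all__ = [
    "TABLE_STATS",
    "UtteranceSpec",
    "GroundTruth",
    "CohortSpec",
    "GroupProfile",
    "CohortRecording",
    "synth_timeline",
    "synth_utterance",
    "synth_feature_cohort",
    "synth_audio_cohort",
]

#: published per-group descriptive statistics: feature -> (mean, sd, low, high)
TABLE_STATS: Dict[str, Dict[str, Tuple[float, float, float, float]]] = {
    "MD": {
        "SPT": (156.4, 56.4, 75.0, 234.2),
        "NPU": (81.3, 38.2, 32.0, 132.0),
        "PPU": (54.7, 16.6, 30.1, 78.2),
        "PHT": (63.2, 13.4, 50.3, 90.1),
        "PPH": (45.2, 16.6, 21.7, 69.8),
        "SPR": (2.1, 0.8, 1.2, 3.8),
        "ARR": (4.8, 0.7, 3.6, 5.9),
        "NSY": (306.6, 67.6, 225.0, 449.0),
        "MSD": (0.1, 0.0, 0.0, 0.1),
        "SDF": (42.0, 13.5, 24.5, 68.6),
        "MVF": (279.3, 80.2, 143.0, 377.0),
        "MFF": (174.4, 40.6, 108.0, 219.9),
    },
    "non-MD": {
        "SPT": (127.9, 64.6, 59.2, 249.7),
        "NPU": (62.1, 33.7, 27.0, 124.0),
        "PPU": (52.2, 10.8, 30.7, 64.8),
        "PHT": (55.3, 16.9, 33.5, 107.2),
        "PPH": (47.7, 10.8, 35.1, 69.2),
        "SPR": (2.3, 0.5, 1.6, 3.6),
        "ARR": (4.8, 0.6, 4.3, 6.3),
        "NSY": (266.8, 75.1, 133.0, 401.0),
        "MSD": (0.1, 0.0, 0.0, 0.1),
        "SDF": (29.3, 8.7, 17.6, 46.6),
        "MVF": (232.9, 109.2, 99.0, 375.0),
        "MFF": (138.2, 27.7, 105.9, 192.3),
    },
}

_LN2_12 = np.log(2.0) / 12.0  # dF/F per semitone


def _truncnorm(rng: np.random.Generator, mean, sd, low, high, size=None):
    """Truncated-normal draw by rejection; sd == 0 degenerates to the mean."""
    if low > high:
        raise ValueError("truncation bounds inverted")
    if sd < 0:
        raise ValueError("negative SD")
    if sd == 0:
        val = np.clip(mean, low, high)
        return np.full(size, val) if size is not None else float(val)
    shape = (size,) if isinstance(size, int) else size
    n = int(np.prod(shape)) if shape is not None else 1
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 8))
        ok = draw[(draw >= low) & (draw <= high)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    if shape is None:
        return float(out[0])
    return out.reshape(shape)


@dataclass(frozen=True)
class UtteranceSpec:
    """Generating parameters for one synthetic read-speech utterance."""

    n_syllables: int = 20
    syllable_duration: Tuple[float, float] = (0.08, 0.18)  # uniform, s
    gap: Tuple[float, float] = (0.05, 0.15)  # inter-syllable gap, s
    pause_positions: Tuple[int, ...] = ()  # gap indices that become pauses
    pause_gap: Tuple[float, float] = (0.4, 1.0)  # pause length, s
    f0_base: float = 140.0  # Hz
    f0_jitter_st: float = 2.0  # per-syllable SD, semitones
    f0_glide_st: float = 2.0  # within-syllable glide span, semitones
    amplitude_jitter_db: float = 3.0
    snr_db: float = 30.0
    lead_s: float = 0.25  # leading/trailing silence
    sample_rate: int = 44100
    seed: int = 0

    def validate(self) -> None:
        if self.n_syllables < 1:
            raise ValueError("need at least one syllable")
        for lo, hi in (self.syllable_duration, self.gap, self.pause_gap):
            if not 0 < lo <= hi:
                raise ValueError("duration bounds must be positive and ordered")
        if any(p < 0 or p >= self.n_syllables - 1 for p in self.pause_positions):
            raise ValueError("pause position outside gap index range")
        if self.f0_base <= 0 or self.sample_rate < 8000:
            raise ValueError("invalid f0_base or sample_rate")


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-syllable timeline and the features it implies."""

    syllables: Tuple[Tuple[float, float, float], ...]  # (onset, offset, mean F0 Hz)
    f0_tracks: Tuple[np.ndarray, ...]  # per-syllable F0 contour at 5 ms
    features: ProsodicFeatureVector

    @property
    def nsy(self) -> int:
        return len(self.syllables)

    @property
    def npu(self) -> int:
        return self.features.npu

    def to_json(self, path) -> None:
        payload = {
            "syllables": [
                {"onset": o, "offset": f, "mean_f0_hz": m}
                for o, f, m in self.syllables
            ],
            "features": self.features.as_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _draw_timeline(spec: UtteranceSpec, rng: np.random.Generator):
    """Syllable (onset, dur, f0_base, glide_sign, amp) list plus gap lengths."""
    durs = rng.uniform(*spec.syllable_duration, spec.n_syllables)
    gaps = np.empty(max(spec.n_syllables - 1, 0))
    pauses = set(int(p) for p in spec.pause_positions)
    for g in range(gaps.size):
        gaps[g] = (
            rng.uniform(*spec.pause_gap) if g in pauses else rng.uniform(*spec.gap)
        )
    jit = np.clip(
        rng.normal(0.0, spec.f0_jitter_st, spec.n_syllables),
        -2.5 * spec.f0_jitter_st - 1e-12,
        2.5 * spec.f0_jitter_st + 1e-12,
    )
    f0s = np.clip(spec.f0_base * 2.0 ** (jit / 12.0), 70.0, 380.0)
    signs = rng.choice([-1.0, 1.0], spec.n_syllables)
    amps = 10.0 ** (rng.uniform(-spec.amplitude_jitter_db, 0.0, spec.n_syllables) / 20.0)
    onsets = np.empty(spec.n_syllables)
    t = spec.lead_s
    for i in range(spec.n_syllables):
        onsets[i] = t
        t += durs[i]
        if i < gaps.size:
            t += gaps[i]
    total = t + spec.lead_s
    return onsets, durs, gaps, f0s, signs, amps, total


def _syllable_f0_contour(f0: float, glide_st: float, sign: float, dur: float, step: float = 0.005):
    """F0 samples over the syllable: linear semitone glide around f0."""
    n = max(2, int(round(dur / step)))
    st = sign * glide_st * (np.linspace(0.0, 1.0, n) - 0.5)
    return f0 * 2.0 ** (st / 12.0)


def _truth_from_timeline(onsets, durs, f0s, signs, spec: UtteranceSpec) -> GroundTruth:
    sylls = []
    tracks = []
    nuclei = []
    for i in range(len(onsets)):
        contour = _syllable_f0_contour(f0s[i], spec.f0_glide_st, signs[i], durs[i])
        mean_f0 = float(contour.mean())
        onset = float(onsets[i])
        offset = float(onsets[i] + durs[i])
        sylls.append((onset, offset, mean_f0))
        tracks.append(contour)
        nuclei.append(
            SyllableNucleus(
                peak_time=0.5 * (onset + offset),
                onset=onset,
                offset=offset,
                peak_value=1.0,
                mean_f0_hz=mean_f0,
                f0_values=contour,
                voiced=True,
            )
        )
    pauses = detect_pauses(nuclei, 0.3)
    feats = compute_features(nuclei, pauses, f0_unit="hz")
    return GroundTruth(tuple(sylls), tuple(tracks), feats)


def synth_timeline(spec: UtteranceSpec) -> GroundTruth:
    """Ground truth only (no waveform) for a spec — cheap timeline draws."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    onsets, durs, gaps, f0s, signs, amps, total = _draw_timeline(spec, rng)
    return _truth_from_timeline(onsets, durs, f0s, signs, spec)


def synth_utterance(spec: UtteranceSpec) -> Tuple[AudioSignal, GroundTruth]:
    """Render the waveform for a spec and return it with its ground truth.

    Identical seeds give bit-identical waveforms.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    onsets, durs, gaps, f0s, signs, amps, total = _draw_timeline(spec, rng)
    fs = spec.sample_rate
    n_total = int(round(total * fs))
    x = np.zeros(n_total)
    f0_max = float(np.max(f0s)) * 2.0 ** (spec.f0_glide_st / 24.0)
    n_harm = max(3, int(min(4000.0, 0.45 * fs) / f0_max))
    for i in range(len(onsets)):
        a = int(round(onsets[i] * fs))
        n = int(round(durs[i] * fs))
        if n < 2 or a + n > n_total:
            n = min(n, n_total - a)
            if n < 2:
                continue
        st = signs[i] * spec.f0_glide_st * (np.linspace(0.0, 1.0, n) - 0.5)
        f_inst = f0s[i] * 2.0 ** (st / 12.0)
        phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
        syl = np.zeros(n)
        for h in range(1, n_harm + 1):
            syl += np.sin(h * phase) / h
        syl *= np.hanning(n) * amps[i]
        x[a : a + n] += syl
    speech = x[int(round(onsets[0] * fs)) : int(round((onsets[-1] + durs[-1]) * fs))]
    p_sig = float(np.mean(speech**2)) if speech.size else 1e-12
    p_noise = p_sig / 10.0 ** (spec.snr_db / 10.0)
    x = x + rng.normal(0.0, np.sqrt(p_noise), n_total)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    truth = _truth_from_timeline(onsets, durs, f0s, signs, spec)
    return AudioSignal(x, fs), truth


@dataclass(frozen=True)
class CohortSpec:
    """Two-group feature-table generator settings (defaults: published stats)."""

    n_per_group: int = 10
    seed: int = 0
    group_stats: Dict[str, Dict[str, Tuple[float, float, float, float]]] = field(
        default_factory=lambda: {g: dict(TABLE_STATS[g]) for g in TABLE_STATS}
    )

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        for stats in self.group_stats.values():
            for mean, sd, low, high in stats.values():
                if sd < 0 or low > high:
                    raise ValueError("inconsistent group stats")


def synth_feature_cohort(spec: Optional[CohortSpec] = None) -> pd.DataFrame:
    """Draw a labeled two-group feature table from truncated normals."""
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = []
    idx = 1
    for label, stats in spec.group_stats.items():
        for _ in range(spec.n_per_group):
            rec = {"subject_id": f"S{idx:03d}", "label": label}
            for name in FEATURE_NAMES:
                mean, sd, low, high = stats[name]
                rec[name] = _truncnorm(rng, mean, sd, low, high)
            records.append(rec)
            idx += 1
    return pd.DataFrame(records, columns=["subject_id", "label"] + FEATURE_NAMES)


@dataclass(frozen=True)
class GroupProfile:
    """Per-group audio-generation parameters derived from the published stats.

    ``nsy``/``npu``/``mff`` are (mean, sd, low, high) truncated normals per
    subject; ``f0_jitter_st`` sets the within-recording F0 spread so the
    recording-level F0 SD matches the published SDF/MFF ratio.  The MFF draw
    is bias-corrected for the lognormal factor exp((sigma_st*ln2/12)^2 / 2)
    introduced by semitone-domain jitter.
    """

    nsy: Tuple[float, float, float, float]
    npu: Tuple[float, float, float, float]
    mff: Tuple[float, float, float, float]
    f0_jitter_st: float
    syllable_duration: Tuple[float, float] = (0.08, 0.18)
    gap: Tuple[float, float] = (0.05, 0.15)
    pause_gap: Tuple[float, float] = (0.6, 1.5)


def _default_profile(label: str) -> GroupProfile:
    stats = TABLE_STATS[label]
    mff_mean, mff_sd, mff_lo, mff_hi = stats["MFF"]
    sdf_mean = stats["SDF"][0]
    jitter_st = 12.0 * np.log2(1.0 + sdf_mean / mff_mean)
    bias = float(np.exp(0.5 * (jitter_st * _LN2_12) ** 2))
    return GroupProfile(
        nsy=stats["NSY"],
        npu=stats["NPU"],
        mff=(mff_mean / bias, mff_sd / bias, mff_lo / bias, mff_hi / bias),
        f0_jitter_st=float(jitter_st),
    )


@dataclass(frozen=True)
class CohortRecording:
    subject_id: str
    label: str
    signal: AudioSignal
    truth: GroundTruth


def synth_audio_cohort(
    n_per_group: int = 10,
    seed: int = 0,
    sample_rate: int = 44100,
    length_scale: float = 1.0,
    snr_db: float = 30.0,
    md: Optional[GroupProfile] = None,
    control: Optional[GroupProfile] = None,
) -> List[CohortRecording]:
    """Generate a two-group audio cohort with per-recording ground truth.

    The MD group is longer, more pause-laden and more F0-dispersed than the
    control group, per the published group statistics.  ``length_scale``
    shrinks recording length (syllable and pause counts) proportionally for
    faster experiments without touching rates or dispersions.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    if not 0 < length_scale <= 1.0:
        raise ValueError("length_scale must be in (0, 1]")
    rng = np.random.default_rng(seed)
    profiles = {
        "MD": md or _default_profile("MD"),
        "non-MD": control or _default_profile("non-MD"),
    }
    out: List[CohortRecording] = []
    idx = 1
    for label, prof in profiles.items():
        for _ in range(n_per_group):
            nsy = max(5, int(round(length_scale * _truncnorm(rng, *prof.nsy))))
            npu = int(round(length_scale * _truncnorm(rng, *prof.npu)))
            npu = int(np.clip(npu, 0, nsy - 1))
            positions = tuple(
                sorted(int(p) for p in rng.choice(nsy - 1, size=npu, replace=False))
            ) if npu else ()
            f0_base = _truncnorm(rng, *prof.mff)
            child_seed = int(rng.integers(0, 2**31 - 1))
            spec = UtteranceSpec(
                n_syllables=nsy,
                syllable_duration=prof.syllable_duration,
                gap=prof.gap,
                pause_positions=positions,
                pause_gap=prof.pause_gap,
                f0_base=float(f0_base),
                f0_jitter_st=prof.f0_jitter_st,
                snr_db=snr_db,
                sample_rate=sample_rate,
                seed=child_seed,
            )
            signal, truth = synth_utterance(spec)
            out.append(CohortRecording(f"S{idx:03d}", label, signal, truth))
            idx += 1
    return out
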