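"""The twelve prosodic features computed from a recording's nuclei.

Timing features are measured on the nucleus timeline (speech time runs from
the first nucleus onset to the last nucleus offset; an inter-nucleus gap
strictly longer than 0.3 s counts as a pause).  F0 features are computed
from per-nucleus mean F0 (SDF, MFF) and from all voiced-frame F0 samples
inside nuclei (MVF), in Hz by default or in semitones re ``f_ref``.

Feature glossary
----------------
SPT  speech time, s             NPU  number of pauses
PPU  pause-time proportion, %   PHT  phonation time, s
PPH  phonation proportion, %    SPR  speech rate, syllables/s
ARR  articulation rate, syll/s  NSY  number of syllables
MSD  mean nucleus duration, s   SDF  SD of per-syllable F0
MVF  max F0 range               MFF  mean per-syllable F0
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .audio_io import AudioSignal
from .config import PipelineConfig
from .pitch import hz_to_semitones
from .syllables import SyllableNucleus, detect_syllables

__all__ = [
    "FEATURE_NAMES",
    "PauseSet",
    "ProsodicFeatureVector",
    "detect_pauses",
    "compute_features",
    "extract_features",
    "features_to_frame",
]

#: canonical feature/column order for tables and reports
FEATURE_NAMES = [
    "SPT", "NPU", "PPU", "PHT", "PPH", "SPR",
    "ARR", "NSY", "MSD", "SDF", "MVF", "MFF",
]


@dataclass(frozen=True)
class PauseSet:
    """Inter-nucleus gaps longer than the pause threshold."""

    gaps: Tuple[Tuple[float, float, float], ...]  # (start, end, length_s)
    pause_threshold_s: float
    total_pause_s: float

    @property
    def count(self) -> int:
        return len(self.gaps)


@dataclass(frozen=True)
class ProsodicFeatureVector:
    spt: float
    npu: int
    ppu: float
    pht: float
    pph: float
    spr: float
    arr: float
    nsy: int
    msd: float
    sdf: float
    mvf: float
    mff: float
    f0_unit: str = "hz"
    has_f0: bool = True

    def as_dict(self) -> dict:
        vals = [
            self.spt, self.npu, self.ppu, self.pht, self.pph, self.spr,
            self.arr, self.nsy, self.msd, self.sdf, self.mvf, self.mff,
        ]
        return dict(zip(FEATURE_NAMES, vals))


def detect_pauses(
    nuclei: Sequence[SyllableNucleus], threshold_s: float = 0.3
) -> PauseSet:
    """Find pauses: gaps between consecutive nuclei strictly over the threshold."""
    if len(nuclei) == 0:
        raise ValueError("no nuclei: cannot detect pauses")
    gaps = []
    for prev, nxt in zip(nuclei[:-1], nuclei[1:]):
        length = nxt.onset - prev.offset
        if length > threshold_s:
            gaps.append((prev.offset, nxt.onset, length))
    total = float(sum(g[2] for g in gaps))
    return PauseSet(tuple(gaps), threshold_s, total)


def _f0_in_unit(values: np.ndarray, unit: str, f_ref: float) -> np.ndarray:
    if unit == "hz":
        return values
    if unit == "st":
        return np.asarray(hz_to_semitones(values, f_ref))
    raise ValueError(f"unknown f0 unit: {unit!r}")


def compute_features(
    nuclei: Sequence[SyllableNucleus],
    pauses: Optional[PauseSet] = None,
    f0_unit: str = "hz",
    f_ref: float = 100.0,
) -> ProsodicFeatureVector:
    """Compute the twelve features from annotated nuclei.

    ``pauses`` defaults to :func:`detect_pauses` at the 0.3 s threshold.
    F0 features are NaN (with ``has_f0=False``) when no nucleus carries
    voiced frames.
    """
    if len(nuclei) == 0:
        raise ValueError("no nuclei: cannot compute features")
    if pauses is None:
        pauses = detect_pauses(nuclei)
    nsy = len(nuclei)
    spt = nuclei[-1].offset - nuclei[0].onset
    if spt <= 0:
        raise ValueError("degenerate recording: zero speech time")
    pht = spt - pauses.total_pause_s
    if pht <= 0:
        raise ValueError("degenerate recording: zero phonation time")
    ppu = 100.0 * pauses.total_pause_s / spt
    pph = 100.0 * pht / spt
    spr = nsy / spt
    arr = nsy / pht
    msd = float(np.mean([n.duration for n in nuclei]))

    per_nucleus = np.array(
        [n.mean_f0_hz for n in nuclei if n.voiced], dtype=np.float64
    )
    all_samples = (
        np.concatenate([n.f0_values for n in nuclei if n.voiced and n.f0_values is not None])
        if any(n.voiced for n in nuclei)
        else np.empty(0)
    )
    if per_nucleus.size == 0:
        sdf = mvf = mff = float("nan")
        has_f0 = False
    else:
        pn = _f0_in_unit(per_nucleus, f0_unit, f_ref)
        al = _f0_in_unit(all_samples, f0_unit, f_ref)
        mff = float(pn.mean())
        sdf = float(pn.std(ddof=1)) if pn.size >= 2 else 0.0
        mvf = float(al.max() - al.min()) if al.size else 0.0
        has_f0 = True
    return ProsodicFeatureVector(
        spt=float(spt), npu=pauses.count, ppu=float(ppu), pht=float(pht),
        pph=float(pph), spr=float(spr), arr=float(arr), nsy=nsy,
        msd=msd, sdf=sdf, mvf=mvf, mff=mff, f0_unit=f0_unit, has_f0=has_f0,
    )


def extract_features(
    signal: AudioSignal, config: Optional[PipelineConfig] = None
):
    """Run the full chain on one recording.

    Returns ``(vector, nuclei, track, envelope)``; ``vector`` is None when
    no nucleus was detected.
    """
    cfg = config or PipelineConfig()
    nuclei, track, env = detect_syllables(signal, cfg)
    if not nuclei:
        return None, nuclei, track, env
    pauses = detect_pauses(nuclei, cfg.features.pause_threshold_s)
    vec = compute_features(
        nuclei, pauses, f0_unit=cfg.features.f0_unit, f_ref=cfg.pitch.f_ref
    )
    return vec, nuclei, track, env


def features_to_frame(rows: Sequence[Tuple[str, str, ProsodicFeatureVector]]) -> pd.DataFrame:
    """Build the canonical feature table: subject_id, label, 12 features."""
    records = []
    for subject_id, label, vec in rows:
        rec = {"subject_id": subject_id, "label": label}
        rec.update(vec.as_dict())
        records.append(rec)
    return pd.DataFrame(records, columns=["subject_id", "label"] + FEATURE_NAMES)
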