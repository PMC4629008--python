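"""Pipeline configuration objects.

Every tunable of the analysis chain lives here so that a results file can
embed the exact settings it was produced with.  Defaults follow the study
protocol where one is stated (10 ms envelope window, 5 ms hop, 0.3 s pause
threshold, alpha 0.05) and this package's documented choices elsewhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import yaml


@dataclass
class EnvelopeConfig:
    """Energy-envelope front end for nucleus detection."""

    window_s: float = 0.010
    hop_s: float = 0.005
    band: Tuple[float, float] = (300.0, 2500.0)  # vowel-energy band, Hz
    rel_threshold: float = 0.3
    min_gap_s: float = 0.06
    smooth_frames: int = 3


@dataclass
class PitchConfig:
    """NCCF + dynamic-programming pitch tracker settings."""

    f_min: float = 60.0
    f_max: float = 400.0
    hop_s: float = 0.005
    voicing_threshold: float = 0.3
    f_ref: float = 100.0  # semitone reference
    min_voiced_s: float = 0.0


@dataclass
class FeatureConfig:
    pause_threshold_s: float = 0.3
    f0_unit: str = "hz"  # "hz" or "st"


@dataclass
class ClassifierConfig:
    kernel: str = "linear"
    C: float = 1.0
    gamma: str = "scale"
    convention: str = "standard"  # or "predictive_value"
    positive_label: str = "MD"


@dataclass
class PipelineConfig:
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    pitch: PitchConfig = field(default_factory=PitchConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    channel: str = "left"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["envelope"]["band"] = list(self.envelope.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for section, klass in (
            ("envelope", EnvelopeConfig),
            ("pitch", PitchConfig),
            ("features", FeatureConfig),
            ("classifier", ClassifierConfig),
        ):
            if section in d:
                payload = dict(d[section])
                if section == "envelope" and "band" in payload:
                    payload["band"] = tuple(payload["band"])
                setattr(cfg, section, klass(**payload))
        if "channel" in d:
            cfg.channel = d["channel"]
        if "seed" in d:
            cfg.seed = int(d["seed"])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
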