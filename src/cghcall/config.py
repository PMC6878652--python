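"""Run configuration: every numeric threshold of the pipeline in one place.

The defaults are the analysis constants the pipeline is built around
(detection score threshold 6, MALR > 0.30, DLRS gate 0.3, 80% overlap and
a 2-probe tolerance for database consistency, 5%/1% frequency bands).
Configs round-trip losslessly through YAML; unknown keys are errors, not
warnings, so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


def _strict(cls, data: dict, path: str) -> dict:
    """Kwargs for ``cls`` from ``data``, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) under {path!r}: {sorted(unknown)}")
    return {f.name: data[f.name] for f in fields(cls) if f.name in data}


@dataclass
class QCSection:
    dlrs_gate: float = 0.3
    gc_correction: bool = True


@dataclass
class SegmentationSection:
    threshold: float = 6.0
    visual_gain: float = 0.5
    visual_loss: float = -1.0
    visual_min_run: int = 2


@dataclass
class TriageSection:
    likely_gain: float = 0.5
    likely_loss: float = -1.0
    unlikely_malr: float = 0.35
    unlikely_two_probe_mean: float = 0.4


@dataclass
class CurationSection:
    malr_min: float = 0.30
    min_probes: int = 2
    max_gap_probes: int = 2
    oppose_ratio: float = 0.3
    trend_min: float = 0.15
    triage: TriageSection = field(default_factory=TriageSection)


@dataclass
class MatchingSection:
    overlap_min: float = 0.80
    max_probe_diff: int = 2
    compat_ratio: float = 0.3
    reciprocal: bool = False


@dataclass
class FrequencySection:
    common: float = 0.05
    rare: float = 0.01


@dataclass
class StatsSection:
    alpha: float = 0.05
    binomial_sided: str = "one"  # "one" | "two"


@dataclass
class RunConfig:
    seed: int = 0
    qc: QCSection = field(default_factory=QCSection)
    segmentation: SegmentationSection = field(default_factory=SegmentationSection)
    curation: CurationSection = field(default_factory=CurationSection)
    matching: MatchingSection = field(default_factory=MatchingSection)
    frequency: FrequencySection = field(default_factory=FrequencySection)
    stats: StatsSection = field(default_factory=StatsSection)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.matching.overlap_min <= 1:
            raise ValueError("matching.overlap_min must be in (0, 1]")
        for name, val in (("frequency.common", self.frequency.common),
                          ("frequency.rare", self.frequency.rare),
                          ("stats.alpha", self.stats.alpha)):
            if not 0 < val < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.frequency.rare >= self.frequency.common:
            raise ValueError("frequency.rare must be below frequency.common")
        for name, val in (("segmentation.threshold", self.segmentation.threshold),
                          ("curation.malr_min", self.curation.malr_min),
                          ("qc.dlrs_gate", self.qc.dlrs_gate)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.curation.min_probes < 1 or self.matching.max_probe_diff < 0:
            raise ValueError("probe-count thresholds out of range")
        if self.stats.binomial_sided not in ("one", "two"):
            raise ValueError("stats.binomial_sided must be 'one' or 'two'")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "qc": QCSection, "segmentation": SegmentationSection,
            "curation": CurationSection, "matching": MatchingSection,
            "frequency": FrequencySection, "stats": StatsSection,
        }
        kwargs = dict(_strict(cls, data, "config"))
        for name, section_cls in sections.items():
            if name in data:
                sub = dict(data[name])
                if name == "curation" and "triage" in sub:
                    sub["triage"] = TriageSection(
                        **_strict(TriageSection, sub["triage"], "curation.triage"))
                kwargs[name] = section_cls(**_strict(section_cls, sub, name))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
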