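"""Run configuration: defaults, YAML loading, and config hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ehgprop.features import SampEnParams
from ehgprop.velocity import XCorrParams


@dataclass
class ClassifyConfig:
    n_folds: int = 10
    n_reps: int = 30
    smote_mode: str = "pre"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smote_mode not in ("none", "pre", "in_folds"):
            raise ValueError(f"unknown smote_mode {self.smote_mode!r}")
        if self.n_folds < 2 or self.n_reps < 1:
            raise ValueError("n_folds must be >= 2 and n_reps >= 1")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the method's standard parameters."""

    bands: list[str] = field(default_factory=lambda: ["B0p", "Bb", "B1", "B2", "B3"])
    xcorr: XCorrParams = field(default_factory=XCorrParams)
    sampen: SampEnParams = field(default_factory=SampEnParams)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            bands=raw.get("bands", ["B0p", "Bb", "B1", "B2", "B3"]),
            xcorr=XCorrParams(**raw.get("xcorr", {})),
            sampen=SampEnParams(**raw.get("sampen", {})),
            classify=ClassifyConfig(**raw.get("classify", {})),
            seed=raw.get("seed", 0),
        )

    def to_dict(self) -> dict:
        return {
            "bands": self.bands,
            "xcorr": asdict(self.xcorr),
            "sampen": asdict(self.sampen),
            "classify": asdict(self.classify),
            "seed": self.seed,
        }

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]
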