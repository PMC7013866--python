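"""Nested pipeline configuration: YAML-loadable, strict, hashable.

Every stage reads its parameters from one section; unknown keys are
rejected rather than ignored, and the fully-resolved config (plus its
hash) is embedded in every output artifact for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class AudioSection:
    rate: int = 16_000
    frame_len: int = 512
    overlap_fraction: float = 0.5
    window: str = "hamming"


@dataclass
class DenoiseSection:
    enabled: bool = True
    low_hz: float = 300.0
    high_hz: float = 7500.0
    quantile: float = 0.1
    subtraction_factor: float = 1.0
    spectral_floor: float = 0.02


@dataclass
class DetectSection:
    threshold: float = 0.35
    min_duration_s: float = 0.03
    max_gap_s: float = 0.03
    smoothing_frames: int = 3
    use_energy: bool = False


@dataclass
class FeaturesSection:
    fmin_hz: float = 200.0
    fmax_hz: float = 4000.0
    lpc_order: int = 12


@dataclass
class ClassifySection:
    C: float = 1.0
    kernel: str = "polynomial"
    degree: int = 3
    gamma: float = 0.2
    coef0: float = 1.0
    max_iterations: int = 10_000
    tolerance: float = 1e-4
    k_folds: int = 5


@dataclass
class ThermalSection:
    thi_a: float = 0.8
    thi_b: float = 1.0
    thi_t_ref: float = 14.4
    thi_c: float = 46.4


@dataclass
class SynthSection:
    n_per_class: int = 100
    snr_db: float = 15.0
    clip_len_s: float = 10.0


@dataclass
class PipelineConfig:
    audio: AudioSection = field(default_factory=AudioSection)
    denoise: DenoiseSection = field(default_factory=DenoiseSection)
    detect: DetectSection = field(default_factory=DetectSection)
    features: FeaturesSection = field(default_factory=FeaturesSection)
    classify: ClassifySection = field(default_factory=ClassifySection)
    thermal: ThermalSection = field(default_factory=ThermalSection)
    synth: SynthSection = field(default_factory=SynthSection)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        sections = {f.name: f for f in fields(cls)}
        for key, value in data.items():
            if key not in sections:
                raise ValueError(f"unknown config section {key!r}")
            if key == "seed":
                cfg.seed = int(value)
                continue
            section = getattr(cfg, key)
            valid = {f.name for f in fields(section)}
            for k, v in value.items():
                if k not in valid:
                    raise ValueError(f"unknown config key {key}.{k}")
                setattr(section, k, type(getattr(section, k))(v))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def thi_coeffs(self) -> dict:
        t = self.thermal
        return {"a": t.thi_a, "b": t.thi_b, "t_ref": t.thi_t_ref, "c": t.thi_c}
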