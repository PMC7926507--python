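"""Run configuration with provenance hashing.

Defaults match the analysis protocol: 60-s windows, 10-fold CV, performance
curves over 1–10 predictors with 3 in the final model, sample entropy with
m = 2 and r = 0.3·SD, a two-level Daubechies-2 wavelet transform.
Precedence when loading: explicit CLI flag > config file > default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    window_s: float = 60.0
    k_folds: int = 10
    max_predictors: int = 10
    final_predictors: int = 3
    sampen_m: int = 2
    sampen_r: float = 0.3
    wavelet: str = "db2"
    wavelet_levels: int = 2
    seed: int = 0
    accel_dialect: str = "physics_toolbox"
    delimiter: str = ","

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.k_folds < 2 or self.max_predictors < 1:
            raise ValueError("invalid configuration")
        if not 1 <= self.final_predictors <= self.max_predictors:
            raise ValueError("final_predictors must be within 1..max_predictors")
        if self.wavelet_levels != 2:
            raise ValueError("feature naming is defined for a 2-level transform")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        """Short digest of the canonical config JSON, embedded in outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        """Build a config from an optional JSON/YAML file plus overrides.

        ``overrides`` with value ``None`` are ignored, so CLI options that
        were not set fall back to the file value and then the default.
        """
        values: dict = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text()) or {}
            unknown = set(loaded) - {f.name for f in dataclasses.fields(cls)}
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)
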