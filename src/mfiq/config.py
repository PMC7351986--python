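"""Pipeline configuration: schema, validation, YAML/JSON loading."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Configuration failed schema validation."""


@dataclass
class SyntheticConfig:
    """Cohort-generation settings (defaults are the analysed study conditions)."""

    n_severe: int = 10
    n_mild: int = 26
    n_recovered: int = 25
    slices_per_level: int = 3
    water_reference: float = 1000.0
    grid_rows: int = 64
    grid_cols: int = 128
    landmark_column: int = 64
    participant_sd: float = 3.0
    slope_sd: float = 0.8
    voxel_noise_sd: float = 30.0


@dataclass
class PipelineConfig:
    """Effective configuration of a pipeline run; serialized into every manifest."""

    mode: str = "synthetic"  # "synthetic" | "real"
    out_dir: str = "mfiq_out"
    seed: int = 0
    quartile_rule: str = "area"  # "area" | "width"
    bilateral: str = "pool"  # "pool" | "side-mean"
    alpha: float = 0.05
    adjust: str = "none"  # "none" | "bonferroni"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # real-mode inputs: per-participant fat/water/mask NIfTI paths + sidecar
    fat_paths: dict = field(default_factory=dict)
    water_paths: dict = field(default_factory=dict)
    mask_paths: dict = field(default_factory=dict)
    annotations_path: str = ""
    metadata_path: str = ""

    def validate(self) -> "PipelineConfig":
        if self.mode not in ("synthetic", "real"):
            raise ConfigError(f"mode must be 'synthetic' or 'real', got {self.mode!r}")
        if self.quartile_rule not in ("area", "width"):
            raise ConfigError(f"quartile_rule must be 'area' or 'width', got {self.quartile_rule!r}")
        if self.bilateral not in ("pool", "side-mean"):
            raise ConfigError(f"bilateral must be 'pool' or 'side-mean', got {self.bilateral!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.adjust not in ("none", "bonferroni"):
            raise ConfigError(f"adjust must be 'none' or 'bonferroni', got {self.adjust!r}")
        s = self.synthetic
        if min(s.n_severe, s.n_mild, s.n_recovered) < 0:
            raise ConfigError("group sizes must be >= 0")
        if s.slices_per_level < 3:
            raise ConfigError("slices_per_level must be >= 3")
        if s.water_reference <= 0:
            raise ConfigError("water_reference must be > 0")
        if self.mode == "real":
            for name in ("annotations_path", "metadata_path"):
                if not getattr(self, name):
                    raise ConfigError(f"real mode requires {name}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    synth = raw.pop("synthetic", {})
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "synthetic"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    unknown_s = set(synth) - set(SyntheticConfig.__dataclass_fields__)
    if unknown_s:
        raise ConfigError(f"unknown synthetic config keys: {sorted(unknown_s)}")
    cfg = PipelineConfig(synthetic=SyntheticConfig(**synth), **raw)
    return cfg.validate()


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")
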