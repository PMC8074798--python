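"""Structured configuration for the end-to-end pipeline.

A pipeline run is described by a small YAML file of key/value pairs; all
campaign constants (allometric coefficients, kerf width, density approach,
report rounding) are configuration keys with campaign-matching defaults,
and unknown keys are rejected rather than silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    """Normalized pipeline configuration."""

    data_dir: str = "."
    out_dir: str = "results"
    density_db: str | None = None
    qsm_file: str | None = None
    density_approach: str = "mass_weighted"
    allometric_coefficient: float = 0.0673
    allometric_exponent: float = 0.976
    cut_width_m: float = 0.0084
    extra_cuts: int = 0
    report_decimals: int = 1
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.density_approach not in ("mass_weighted", "stem",
                                         "literature", "all"):
            raise ConfigurationError(
                f"density_approach {self.density_approach!r} not one of "
                "mass_weighted/stem/literature/all")
        if not self.cut_width_m > 0:
            raise ConfigurationError("cut_width_m must be > 0")
        if not (self.allometric_coefficient > 0
                and self.allometric_exponent > 0):
            raise ConfigurationError("allometric constants must be > 0")
        if self.report_decimals < 0:
            raise ConfigurationError("report_decimals must be >= 0")
        return self


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> PipelineConfig:
    """Load, default-fill and validate a pipeline configuration.

    Unknown keys raise a :class:`ConfigurationError` listing the valid
    ones.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s) {unknown}; valid keys: "
            f"{sorted(valid)}")
    return PipelineConfig(**raw).validate()
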