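"""Pipeline configuration: flat, typed, validated before any stage runs.

All protocol constants that the analysis rules depend on (likelihood
gate 0.6, cue cut-off 0.9 with its 1-s minimum span, the R-squared
exclusion threshold 0.6, frame rate 15) are configuration defaults, not
hard-coded values, so sensitivity analyses are one key away.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    # paths
    bundle_dir: str = "bundle"
    out_dir: str = "out"
    # simulation scale
    n_per_cell: int = 2
    chambers_per_cell: int = 2
    phases: tuple[str, ...] = ("1a", "2", "3")
    pose_for: tuple[str, ...] = ()
    satiety_halflife_s: float | None = None
    # analysis thresholds
    likelihood_threshold: float = 0.6
    cue_threshold: float = 0.9
    cue_min_span_s: float = 1.0
    r2_exclusion_threshold: float = 0.6
    k_policy: str = "shared"
    k_value: float | None = None
    zero_policy: str = "drop"
    jitter_floor_px: float = 0.5
    fps: float = 15.0
    # randomness
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if not 0.0 <= self.likelihood_threshold <= 1.0:
            errors.append("likelihood_threshold must lie in [0, 1]")
        if not 0.0 <= self.cue_threshold <= 1.0:
            errors.append("cue_threshold must lie in [0, 1]")
        if self.cue_min_span_s <= 0:
            errors.append("cue_min_span_s must be positive")
        if not 0.0 <= self.r2_exclusion_threshold <= 1.0:
            errors.append("r2_exclusion_threshold must lie in [0, 1]")
        if self.k_policy not in ("shared", "fixed", "per_subject"):
            errors.append(f"unknown k_policy {self.k_policy!r}")
        if self.k_policy == "fixed" and self.k_value is None:
            errors.append("k_policy 'fixed' requires k_value")
        if self.zero_policy not in ("drop", "floor"):
            errors.append(f"unknown zero_policy {self.zero_policy!r}")
        if self.fps <= 0:
            errors.append("fps must be positive")
        if self.n_per_cell < 0 or self.chambers_per_cell < 1:
            errors.append("invalid simulation sizes")
        unknown = [p for p in self.phases if p not in ("1a", "1b", "2", "3")]
        if unknown:
            errors.append(f"unknown phases {unknown}")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load a YAML mapping of config keys; unknown keys are errors."""
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("phases", "pose_for"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
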