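"""Pipeline configuration: YAML file -> validated PipelineConfig.

Unknown keys are rejected with a closest-match suggestion; thresholds are
type- and sign-checked.  An empty (or absent) file yields the all-defaults
configuration, which runs in simulate-first mode on synthetic data.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "Paths", "Thresholds", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class Paths:
    counts: str | None = None
    metadata: str | None = None
    promoters: str | None = None
    pwm: str | None = None
    cohort: str | None = None
    peaks: str | None = None
    output_dir: str = "pipeline_out"


@dataclass
class Thresholds:
    slope_magnitude: float = 1.0
    r2: float = 0.6
    log2fc: float = 1.0
    q: float = 0.05
    e_value: float = 10.0
    promoter_bp: int = 10_000
    loh_similarity: float = 0.10

    def validate(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ConfigError(f"threshold {f.name!r} must be a number, got {v!r}")
            if v <= 0:
                raise ConfigError(f"threshold {f.name!r} must be positive, got {v}")
        if not 0 < self.r2 < 1:
            raise ConfigError("threshold 'r2' must be in (0, 1)")
        if not 0 < self.q < 1:
            raise ConfigError("threshold 'q' must be in (0, 1)")


@dataclass
class PipelineConfig:
    paths: Paths = field(default_factory=Paths)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    simulate_first: bool = True
    trend_scale: str = "log2"  # 'log2' or 'normalized'
    genotype_order: list[str] = field(default_factory=lambda: ["WT_WT", "WT_null", "WT_mut"])
    n_random_draws: int = 1
    n_perm: int = 1000

    def validate(self):
        self.thresholds.validate()
        if self.trend_scale not in ("log2", "normalized"):
            raise ConfigError("trend_scale must be 'log2' or 'normalized'")
        if len(self.genotype_order) != 3:
            raise ConfigError("genotype_order must list exactly three labels")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ConfigError("seed must be an integer")
        if self.n_random_draws < 1:
            raise ConfigError("n_random_draws must be >= 1")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")

    def echo(self) -> dict:
        return {
            "paths": vars(self.paths),
            "thresholds": vars(self.thresholds),
            "seed": self.seed,
            "simulate_first": self.simulate_first,
            "trend_scale": self.trend_scale,
            "genotype_order": list(self.genotype_order),
            "n_random_draws": self.n_random_draws,
            "n_perm": self.n_perm,
        }


def _reject_unknown(given: dict, allowed: list[str], context: str):
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1, cutoff=0.4)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {key!r} in {context}{suggestion}")


def validate_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load, default-fill and validate a pipeline configuration.

    ``path=None`` or an empty file produces the all-defaults simulate-mode
    configuration.  ``overrides`` (e.g. from CLI flags) are applied on top
    of the file's top-level keys.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        raw = loaded
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    cfg = PipelineConfig()
    top_allowed = [f.name for f in fields(PipelineConfig)]
    _reject_unknown(raw, top_allowed, "config")
    for key, val in raw.items():
        if key == "paths":
            if not isinstance(val, dict):
                raise ConfigError("'paths' must be a mapping")
            _reject_unknown(val, [f.name for f in fields(Paths)], "paths")
            for k, v in val.items():
                setattr(cfg.paths, k, v)
        elif key == "thresholds":
            if not isinstance(val, dict):
                raise ConfigError("'thresholds' must be a mapping")
            _reject_unknown(val, [f.name for f in fields(Thresholds)], "thresholds")
            for k, v in val.items():
                setattr(cfg.thresholds, k, v)
        else:
            setattr(cfg, key, val)
    cfg.validate()
    return cfg
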