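"""Run configuration and provenance manifests.

A run configuration is a YAML or JSON mapping with up to four
sections — ``cohort``, ``sampler``, ``priors``, ``analysis`` — each
optional and each validated against the corresponding dataclass.
Every pipeline stage writes a JSON manifest carrying the stage name,
the hash of the configuration it ran under, and its headline outputs,
so results are traceable to a config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .hierarchy import GroupHypers, HyperPriorConfig
from .lba_core import PARAM_NAMES
from .sampler import SamplerConfig
from .synthetic_data import CohortConfig


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the compare/correlate stages."""

    parameter: str = "v_c_face"
    min_rt: float = 0.150
    or_mode: str = "mean"  # "mean" (truncnorm means) or "plugin" (fresh draws)

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ConfigError(f"unknown parameter {self.parameter!r}")
        if self.min_rt < 0:
            raise ConfigError("min_rt must be >= 0")
        if self.or_mode not in ("mean", "plugin"):
            raise ConfigError(f"or_mode must be 'mean' or 'plugin'")


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    priors: HyperPriorConfig = field(default_factory=HyperPriorConfig.default)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "sampler": dataclasses.asdict(self.sampler),
            "priors": dataclasses.asdict(self.priors),
            "analysis": dataclasses.asdict(self.analysis),
        }


_SECTIONS = ("cohort", "sampler", "priors", "analysis")


def _build_cohort(raw: dict) -> CohortConfig:
    raw = dict(raw)
    if "true_hypers" in raw:
        hyp = {}
        for g, entry in raw["true_hypers"].items():
            try:
                hyp[g] = GroupHypers(g, dict(entry["mu"]), dict(entry["sigma"]))
            except (KeyError, TypeError) as e:
                raise ConfigError(f"bad true_hypers for group {g!r}: {e}")
        raw["true_hypers"] = hyp
    return _build(CohortConfig, raw, "cohort")


def _build(cls, raw: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
    try:
        return cls(**raw)
    except TypeError as e:
        raise ConfigError(f"bad [{section}] config: {e}")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration (defaults if None)."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        raise ConfigError(f"unparseable config {path}: {e}")
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    if "cohort" in raw:
        kwargs["cohort"] = _build_cohort(raw["cohort"] or {})
    if "sampler" in raw:
        try:
            kwargs["sampler"] = _build(SamplerConfig, raw["sampler"] or {},
                                       "sampler")
        except Exception as e:
            raise ConfigError(f"bad [sampler] config: {e}")
    if "priors" in raw:
        kwargs["priors"] = _build(HyperPriorConfig, raw["priors"] or {},
                                  "priors")
    if "analysis" in raw:
        kwargs["analysis"] = _build(AnalysisConfig, raw["analysis"] or {},
                                    "analysis")
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical JSON form of a configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir: str | Path, stage: str, config: RunConfig,
                   **extra) -> Path:
    path = Path(outdir) / f"manifest_{stage}.json"
    payload = {
        "stage": stage,
        "config_hash": config_hash(config),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config.to_dict(),
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
    return path


def read_manifest(outdir: str | Path, stage: str) -> dict:
    path = Path(outdir) / f"manifest_{stage}.json"
    if not path.exists():
        raise ConfigError(f"missing manifest for stage {stage!r} in {outdir}")
    with open(path) as fh:
        return json.load(fh)
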