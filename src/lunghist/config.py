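"""Structured-text (YAML) run configuration, validation and logging.

A run configuration gathers one section per model layer — smoking, tsce
(keyed by sex), progression, detection, cohort, estimation — plus a seed,
log level and output directory.  Sections map one-to-one onto the
parameter dataclasses of the corresponding modules; unknown keys are
rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from typing import Any, Dict

import yaml

from .detection import DetectionParams
from .estimation import FitOptions
from .population import CohortConfig
from .progression import ProgressionParams
from .smoking import SmokingConfig
from .tsce import PLACEHOLDER_RESPONSE, ResponseParams

__all__ = ["ConfigError", "RunConfig", "setup_logging"]

log = logging.getLogger("lunghist")


class ConfigError(ValueError):
    """A configuration section failed validation."""


def _build(cls, section: Dict[str, Any], name: str):
    try:
        obj = cls(**section)
    except TypeError as e:
        raise ConfigError(f"section '{name}': {e}") from None
    except ValueError as e:
        raise ConfigError(f"section '{name}': {e}") from None
    validate = getattr(obj, "validate", None)
    if validate is not None:
        try:
            validate()
        except ValueError as e:
            raise ConfigError(f"section '{name}': {e}") from None
    return obj


def _tuplify(d: Dict[str, Any], *keys) -> Dict[str, Any]:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


@dataclass
class RunConfig:
    """Full run configuration; every section has working defaults."""

    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "out"
    smoking: SmokingConfig = field(default_factory=SmokingConfig)
    tsce: Dict[str, ResponseParams] = field(
        default_factory=lambda: {
            "male": PLACEHOLDER_RESPONSE,
            "female": PLACEHOLDER_RESPONSE,
        }
    )
    progression: ProgressionParams = field(default_factory=ProgressionParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    estimation: FitOptions = field(default_factory=FitOptions)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "RunConfig":
        data = dict(data or {})
        known = {
            "seed",
            "log_level",
            "output_dir",
            "smoking",
            "tsce",
            "progression",
            "detection",
            "cohort",
            "estimation",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")
        cfg = cls(
            seed=int(data.get("seed", 0)),
            log_level=str(data.get("log_level", "INFO")),
            output_dir=str(data.get("output_dir", "out")),
        )
        if "smoking" in data:
            sect = _tuplify(data["smoking"], "init_age_bounds")
            cfg.smoking = _build(SmokingConfig, sect, "smoking")
        if "tsce" in data:
            tsce = {}
            for sex, sect in data["tsce"].items():
                if sex not in ("male", "female"):
                    raise ConfigError(f"tsce section keyed by unknown sex {sex!r}")
                tsce[sex] = _build(ResponseParams, sect, f"tsce.{sex}")
            for sex in ("male", "female"):
                tsce.setdefault(sex, PLACEHOLDER_RESPONSE)
            cfg.tsce = tsce
        if "progression" in data:
            sect = _tuplify(data["progression"], "met_growth_multipliers")
            cfg.progression = _build(ProgressionParams, sect, "progression")
        if "detection" in data:
            cfg.detection = _build(DetectionParams, data["detection"], "detection")
        if "cohort" in data:
            sect = _tuplify(data["cohort"], "window")
            if "births" in sect and sect["births"] is not None:
                sect["births"] = {int(k): int(v) for k, v in sect["births"].items()}
            cfg.cohort = _build(CohortConfig, sect, "cohort")
        if "estimation" in data:
            sect = _tuplify(data["estimation"], "onset_age_range")
            cfg.estimation = _build(FitOptions, sect, "estimation")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_dict(self) -> Dict[str, Any]:
        return {
            "seed": self.seed,
            "log_level": self.log_level,
            "output_dir": self.output_dir,
            "smoking": dataclasses.asdict(self.smoking),
            "tsce": {sex: dataclasses.asdict(rp) for sex, rp in self.tsce.items()},
            "progression": dataclasses.asdict(self.progression),
            "detection": dataclasses.asdict(self.detection),
            "cohort": {
                **dataclasses.asdict(self.cohort),
                "births": dict(self.cohort.births) if self.cohort.births else None,
            },
            "estimation": dataclasses.asdict(self.estimation),
        }

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Stable digest of the canonicalized configuration."""
        canon = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples/numpy scalars to YAML-friendly types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
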