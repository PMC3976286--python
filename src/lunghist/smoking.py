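"""Individual smoking trajectories and other-cause mortality.

This module emulates the output contract of the CISNET Smoking History
Generator (SHG): for every simulated person it produces whether and when
they started smoking, whether and when they quit, a lifetime-constant
intensity in packs per day (ppd), and an age at death from causes other
than lung cancer.  The downstream carcinogenesis model only consumes
these outputs, so any generator honoring the same contract can stand in
for the SHG itself.

All distributions are configurable through :class:`SmokingConfig`.  The
defaults describe a mid-20th-century U.S.-like population in round
numbers (sex-specific ever-smoking probability, normal initiation age
truncated to [10, 40], exponential time to cessation, lognormal
intensity, Gompertz other-cause mortality); they are deliberately not a
calibration to national survey data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SmokingHistory",
    "SmokingConfig",
    "sample_history",
    "status_at",
    "intensity_at",
    "sample_gompertz",
    "histories_to_frame",
    "frame_to_histories",
]

SEXES = ("male", "female")


class ConfigError(ValueError):
    """Invalid configuration (negative probability, unordered support, ...)."""


@dataclass(frozen=True)
class SmokingHistory:
    """One person's smoking trajectory and other-cause death age.

    ``init_age`` is absent (None) for never smokers; ``quit_age`` is
    absent for never and current smokers.  ``intensity`` is a single
    lifetime constant in packs per day while the person smokes.
    """

    sex: str
    birth_year: int
    init_age: Optional[float]
    quit_age: Optional[float]
    intensity: float
    other_cause_death_age: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.quit_age is not None:
            if self.init_age is None:
                raise ValueError("quit_age present without init_age")
            if not self.init_age < self.quit_age:
                raise ValueError("init_age must precede quit_age")
        if (self.intensity == 0.0) != (self.init_age is None):
            raise ValueError("intensity must be 0 iff never smoker")
        if self.intensity < 0.0:
            raise ValueError("intensity must be >= 0")
        if not self.other_cause_death_age > 0.0:
            raise ValueError("other_cause_death_age must be > 0")


@dataclass(frozen=True)
class SmokingConfig:
    """Distributional parameters for the smoking-history generator.

    initiation_prob      probability of ever initiating, by sex
    init_age_mean/sd     normal initiation age, truncated to init_age_bounds
    quit_rate            per-year exponential hazard of cessation after initiation
    intensity_median     median of the lognormal intensity distribution (ppd)
    intensity_sigma      log-scale sigma of the intensity distribution
    gompertz_b/c         other-cause mortality hazard b*exp(c*age)
    max_age              administrative upper bound on death age (years)
    vital_cutoff_year    optional calendar year after which vital status is
                         not observed (the SHG used 2000); None disables it
    """

    initiation_prob: dict = field(
        default_factory=lambda: {"male": 0.55, "female": 0.40}
    )
    init_age_mean: float = 18.0
    init_age_sd: float = 4.0
    init_age_bounds: tuple = (10.0, 40.0)
    quit_rate: float = 0.025
    intensity_median: float = 1.0
    intensity_sigma: float = 0.5
    gompertz_b: float = 8.0e-5
    gompertz_c: float = 0.085
    max_age: float = 110.0
    vital_cutoff_year: Optional[int] = None

    def validate(self) -> None:
        for sex in SEXES:
            p = self.initiation_prob.get(sex)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigError(f"initiation_prob[{sex!r}] must be in [0, 1]")
        lo, hi = self.init_age_bounds
        if not (0.0 <= lo < hi):
            raise ConfigError("init_age_bounds must satisfy 0 <= lo < hi")
        if self.init_age_sd <= 0.0:
            raise ConfigError("init_age_sd must be > 0")
        if self.quit_rate < 0.0:
            raise ConfigError("quit_rate must be >= 0")
        if self.intensity_median <= 0.0 or self.intensity_sigma < 0.0:
            raise ConfigError("intensity parameters must be positive")
        if self.gompertz_b <= 0.0 or self.gompertz_c <= 0.0:
            raise ConfigError("Gompertz parameters must be > 0")
        if self.max_age <= 0.0:
            raise ConfigError("max_age must be > 0")


def sample_gompertz(
    rng: np.random.Generator,
    b: float,
    c: float,
    size=None,
    min_age: float = 0.0,
    max_age: float = 110.0,
):
    """Sample death ages from a Gompertz hazard b*exp(c*t), conditioned on
    survival to ``min_age`` (scalar or array), truncated at ``max_age``."""
    e = rng.exponential(size=size)
    # Lambda(t) - Lambda(a) = e  =>  exp(c t) = exp(c a) + c e / b
    t = np.log(np.exp(c * np.asarray(min_age, dtype=float)) + c * e / b) / c
    return np.minimum(t, max_age)


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    """Rejection-sampled truncated normal; support is wide so this is cheap."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def sample_history(
    sex: str,
    birth_year: int,
    config: SmokingConfig,
    rng: np.random.Generator,
) -> SmokingHistory:
    """Draw one :class:`SmokingHistory` under ``config``.

    A person who would initiate after their other-cause death is recorded
    as a never smoker; a cessation falling after death is dropped (the
    person dies a current smoker).
    """
    config.validate()
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    oc_death = float(
        sample_gompertz(
            rng, config.gompertz_b, config.gompertz_c, max_age=config.max_age
        )
    )
    if config.vital_cutoff_year is not None:
        oc_death = min(oc_death, max(config.vital_cutoff_year - birth_year, 1e-6))

    init_age = quit_age = None
    intensity = 0.0
    if rng.random() < config.initiation_prob[sex]:
        lo, hi = config.init_age_bounds
        cand = _trunc_normal(rng, config.init_age_mean, config.init_age_sd, lo, hi)
        if cand < oc_death:
            init_age = cand
            intensity = float(
                rng.lognormal(math.log(config.intensity_median), config.intensity_sigma)
            )
            if config.quit_rate > 0.0:
                q = init_age + rng.exponential(1.0 / config.quit_rate)
                if q < oc_death:
                    quit_age = float(q)
    return SmokingHistory(
        sex=sex,
        birth_year=int(birth_year),
        init_age=init_age,
        quit_age=quit_age,
        intensity=intensity,
        other_cause_death_age=oc_death,
    )


def status_at(history: SmokingHistory, age: float) -> str:
    """Smoking status ('never' | 'current' | 'former') at a given age."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if history.init_age is None or age < history.init_age:
        return "never"
    if history.quit_age is not None and age >= history.quit_age:
        return "former"
    return "current"


def intensity_at(history: SmokingHistory, age: float) -> float:
    """Smoking intensity (ppd) at a given age: the lifetime constant while
    current, 0 otherwise."""
    return history.intensity if status_at(history, age) == "current" else 0.0


# ---------------------------------------------------------------------------
# Tabular serialization (columns: id, sex, birth_year, init_age, quit_age,
# intensity_ppd, oc_death_age; empty field = absent)
# ---------------------------------------------------------------------------

def histories_to_frame(histories):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id": i,
                "sex": h.sex,
                "birth_year": h.birth_year,
                "init_age": h.init_age,
                "quit_age": h.quit_age,
                "intensity_ppd": h.intensity,
                "oc_death_age": h.other_cause_death_age,
            }
            for i, h in enumerate(histories)
        ],
        columns=[
            "id",
            "sex",
            "birth_year",
            "init_age",
            "quit_age",
            "intensity_ppd",
            "oc_death_age",
        ],
    )


def frame_to_histories(frame):
    out = []
    for _, r in frame.iterrows():
        init = None if _isna(r["init_age"]) else float(r["init_age"])
        quit_ = None if _isna(r["quit_age"]) else float(r["quit_age"])
        out.append(
            SmokingHistory(
                sex=str(r["sex"]),
                birth_year=int(r["birth_year"]),
                init_age=init,
                quit_age=quit_,
                intensity=float(r["intensity_ppd"]),
                other_cause_death_age=float(r["oc_death_age"]),
            )
        )
    return out


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))
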