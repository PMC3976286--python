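"""Calendar-time birth-cohort simulation of the lung-cancer population.

Starting from a configurable yearly live-birth series (constant 2,877,000
births per year before 1909 by default), each cohort of simulated persons
receives a smoking history and other-cause death age, a TSCE tumor-onset
age, a tumor course (growth rate and metastasis times), and runs the
yearly detection cycle censored by other-cause death.  Detected cases
falling inside the observation window become case records — the SEER-like
surface the calibration and reporting layers consume — alongside yearly
alive-population counts.

No cancer-attributable death is applied before detection, and persons are
removed from the population only by other-cause mortality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .detection import DetectionParams, simulate_tumors
from .progression import ProgressionParams
from .smoking import SmokingConfig, sample_history
from .tsce import ResponseParams, sample_onset_age

__all__ = [
    "CohortConfig",
    "CASE_COLUMNS",
    "run",
    "summarize_observables",
    "summarize_unobservables",
]

PRE_1909_BIRTHS = 2_877_000

#: Column dictionary of the case listing (units embedded in the names).
CASE_COLUMNS = {
    "person_id": "simulation-wide person index",
    "diag_year": "calendar year of diagnosis",
    "age_at_diag": "age at diagnosis (years)",
    "sex": "male/female",
    "stage": "N0M0 | NxM0 | M1",
    "diameter_cm": "primary tumor diameter at diagnosis (cm)",
    "volume_cm3": "primary tumor volume at diagnosis (cm^3)",
    "smoking_status": "never/current/former at diagnosis",
    "mode": "detection route: primary | nodal | distant",
    "onset_age": "age at tumor onset (years)",
    "lam_per_yr": "tumor growth rate lambda (1/yr)",
    "t_nodal_yr": "onset-to-nodal-metastasis time (years; inf if none formed)",
    "t_distant_yr": "onset-to-distant-metastasis time (years; inf if none formed)",
    "det_time_yr": "onset-to-diagnosis time (years)",
    "vol_at_nodal_cm3": "primary volume when the nodal metastasis formed (cm^3)",
    "vol_at_distant_cm3": "primary volume when the distant metastasis formed (cm^3)",
}


@dataclass(frozen=True)
class CohortConfig:
    """Calendar simulation settings.

    births        mapping calendar year -> live births; years missing from
                  the mapping default to the pre-1909 constant 2,877,000
    scale         simulated persons per real birth (0 < scale <= 1)
    start_year / end_year   birth-cohort range simulated (inclusive)
    window        (first, last) diagnosis years kept as case records
    sex_split     probability a newborn is male
    """

    births: Optional[Mapping[int, int]] = None
    scale: float = 0.1
    start_year: int = 1890
    end_year: int = 1984
    window: Tuple[int, int] = (1988, 1999)
    sex_split: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.scale <= 1.0):
            raise ValueError("scale must be in (0, 1]")
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if not (0.0 <= self.sex_split <= 1.0):
            raise ValueError("sex_split must be in [0, 1]")
        if self.births is not None and any(v < 0 for v in self.births.values()):
            raise ValueError("birth counts must be >= 0")

    def births_in(self, year: int) -> int:
        if self.births is not None and year in self.births:
            return int(self.births[year])
        return PRE_1909_BIRTHS


def run(
    config: CohortConfig,
    response: Union[ResponseParams, Dict[str, ResponseParams]],
    pp: ProgressionParams,
    dp: DetectionParams,
    smoking: SmokingConfig,
    rng: np.random.Generator,
    grid_step: float = 0.1,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Run the calendar population simulation.

    ``response`` may be a single ResponseParams or a {'male':..., 'female':...}
    mapping.  Returns (case records DataFrame with :data:`CASE_COLUMNS`,
    yearly alive-population counts indexed by calendar year).
    """
    years = range(config.start_year, config.end_year + 1)
    total_births = sum(
        int(round(config.births_in(y) * config.scale)) for y in years
    )
    if total_births == 0:
        raise ValueError("birth series scales to an empty population")

    if isinstance(response, ResponseParams):
        response = {"male": response, "female": response}

    last_obs_year = config.window[1]
    pop_years = np.arange(config.start_year, last_obs_year + 1)
    pop_delta = np.zeros(pop_years.size + 1, dtype=np.int64)

    onset_rows = []  # (person_id, birth_year, onset_age, oc_death, sex, init, quit, intensity)
    person_id = 0
    for year in years:
        n = int(round(config.births_in(year) * config.scale))
        for _ in range(n):
            sex = "male" if rng.random() < config.sex_split else "female"
            h = sample_history(sex, year, smoking, rng)
            death_year = year + int(h.other_cause_death_age)
            i0 = year - config.start_year
            i1 = min(death_year, last_obs_year) + 1 - config.start_year
            if i1 > i0:
                pop_delta[i0] += 1
                pop_delta[i1] -= 1
            onset = sample_onset_age(
                h, response[sex], rng, max_age=smoking.max_age, grid_step=grid_step
            )
            if onset is not None:
                onset_rows.append(
                    (
                        person_id,
                        year,
                        onset,
                        h.other_cause_death_age,
                        sex,
                        h.init_age if h.init_age is not None else np.nan,
                        h.quit_age if h.quit_age is not None else np.nan,
                        h.intensity,
                    )
                )
            person_id += 1

    population = pd.Series(
        np.cumsum(pop_delta[:-1]), index=pop_years, name="alive"
    )

    if not onset_rows:
        return pd.DataFrame(columns=list(CASE_COLUMNS)), population

    cand = pd.DataFrame(
        onset_rows,
        columns=[
            "person_id",
            "birth_year",
            "onset_age",
            "oc_death",
            "sex",
            "init_age",
            "quit_age",
            "intensity",
        ],
    )
    onset_ages = cand["onset_age"].to_numpy()
    censor_ages = cand["oc_death"].to_numpy()
    sim = simulate_tumors(pp, dp, rng, onset_ages, censor_ages)

    det = sim["detected"].to_numpy()
    diag_age = sim["detection_age"].to_numpy()
    diag_year = cand["birth_year"].to_numpy() + np.floor(diag_age).astype("float")
    in_window = det & (diag_year >= config.window[0]) & (diag_year <= config.window[1])

    kept = cand[in_window].reset_index(drop=True)
    sims = sim[in_window].reset_index(drop=True)

    # smoking status at diagnosis
    age_d = sims["detection_age"].to_numpy()
    init = kept["init_age"].to_numpy()
    quit_ = kept["quit_age"].to_numpy()
    status = np.where(
        np.isnan(init) | (age_d < init),
        "never",
        np.where(~np.isnan(quit_) & (age_d >= quit_), "former", "current"),
    )

    lam = sims["lam"].to_numpy()
    records = pd.DataFrame(
        {
            "person_id": kept["person_id"],
            "diag_year": diag_year[in_window].astype(int),
            "age_at_diag": age_d,
            "sex": kept["sex"],
            "stage": sims["stage"],
            "diameter_cm": sims["diameter_cm"],
            "volume_cm3": sims["volume_cm3"],
            "smoking_status": status,
            "mode": sims["mode"],
            "onset_age": kept["onset_age"],
            "lam_per_yr": lam,
            "t_nodal_yr": sims["t_nodal"],
            "t_distant_yr": sims["t_distant"],
            "det_time_yr": sims["det_time"],
            "vol_at_nodal_cm3": pp.cell_volume * np.exp(lam * sims["t_nodal"].to_numpy()),
            "vol_at_distant_cm3": pp.cell_volume
            * np.exp(lam * sims["t_distant"].to_numpy()),
        }
    )
    return records, population


# ---------------------------------------------------------------------------
# Summaries of the detected-case population
# ---------------------------------------------------------------------------

def summarize_observables(records: pd.DataFrame) -> pd.DataFrame:
    """Clinically observable summary (sex, age, stage, size, smoking
    status), laid out as characteristic / value / percent rows."""
    if len(records) == 0:
        return pd.DataFrame(columns=["characteristic", "value", "percent"])
    n = len(records)
    rows = []
    for sex in ("male", "female"):
        c = int((records["sex"] == sex).sum())
        rows.append((f"sex: {sex}", c, 100.0 * c / n))
    age = records["age_at_diag"]
    rows.append(("age: mean", round(float(age.mean()), 2), np.nan))
    rows.append(("age: sd", round(float(age.std()), 2), np.nan))
    rows.append(("age: median", round(float(age.median()), 2), np.nan))
    for stage in ("N0M0", "NxM0", "M1"):
        c = int((records["stage"] == stage).sum())
        rows.append((f"stage: {stage}", c, 100.0 * c / n))
    size = records["diameter_cm"]
    rows.append(("tumor diameter cm: mean", round(float(size.mean()), 2), np.nan))
    rows.append(("tumor diameter cm: median", round(float(size.median()), 2), np.nan))
    rows.append(("tumor diameter cm: sd", round(float(size.std()), 2), np.nan))
    rows.append(("tumor diameter cm: variance", round(float(size.var()), 2), np.nan))
    for st in ("never", "former", "current"):
        c = int((records["smoking_status"] == st).sum())
        rows.append((f"smoking: {st}", c, 100.0 * c / n))
    return pd.DataFrame(rows, columns=["characteristic", "value", "percent"])


def _dist_row(name: str, x: pd.Series) -> tuple:
    x = x.dropna()
    if len(x) == 0:
        return (name, np.nan, np.nan, np.nan, np.nan, np.nan)
    return (
        name,
        float(x.mean()),
        float(x.std()),
        float(x.median()),
        float(x.quantile(0.25)),
        float(x.quantile(0.75)),
    )


def summarize_unobservables(records: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Latent-variable summary: onset-to-event times, primary size at
    metastasis, growth rate and doubling time by stage, and doubling time
    cross-tabbed by stage and detected-size bin."""
    cols = ["variable", "mean", "sd", "median", "q1", "q3"]
    if len(records) == 0:
        return {
            "durations": pd.DataFrame(columns=cols),
            "by_stage": pd.DataFrame(columns=cols),
            "doubling_by_stage_size": pd.DataFrame(),
        }
    det = records
    onset_to_nodal = det["t_nodal_yr"].where(det["t_nodal_yr"] <= det["det_time_yr"])
    onset_to_distant = det["t_distant_yr"].where(
        det["t_distant_yr"] <= det["det_time_yr"]
    )
    rows = [
        _dist_row("onset to nodal metastasis (yr)", onset_to_nodal),
        _dist_row("onset to distant metastasis (yr)", onset_to_distant),
        _dist_row("onset to diagnosis (yr)", det["det_time_yr"]),
        _dist_row(
            "primary volume at nodal met (cm3)",
            det["vol_at_nodal_cm3"].where(onset_to_nodal.notna()),
        ),
        _dist_row(
            "primary volume at distant met (cm3)",
            det["vol_at_distant_cm3"].where(onset_to_distant.notna()),
        ),
        _dist_row(
            "primary diameter at nodal met (cm)",
            (6.0 * det["vol_at_nodal_cm3"].where(onset_to_nodal.notna()) / np.pi)
            ** (1 / 3),
        ),
        _dist_row(
            "primary diameter at distant met (cm)",
            (6.0 * det["vol_at_distant_cm3"].where(onset_to_distant.notna()) / np.pi)
            ** (1 / 3),
        ),
    ]
    durations = pd.DataFrame(rows, columns=cols)

    by_stage_rows = []
    for stage in ("N0M0", "NxM0", "M1"):
        sub = det[det["stage"] == stage]
        lam = sub["lam_per_yr"]
        by_stage_rows.append(_dist_row(f"{stage}: growth rate (1/yr)", lam))
        by_stage_rows.append(
            _dist_row(f"{stage}: doubling time (days)", 365.0 * np.log(2.0) / lam)
        )
    by_stage = pd.DataFrame(by_stage_rows, columns=cols)

    size_bin = np.minimum(np.floor(det["diameter_cm"]), 19).astype(int)
    dt_days = 365.0 * np.log(2.0) / det["lam_per_yr"]
    cross = (
        pd.DataFrame({"stage": det["stage"], "size_bin_cm": size_bin, "dt": dt_days})
        .groupby(["stage", "size_bin_cm"], observed=True)["dt"]
        .agg(["count", "mean", "median"])
        .reset_index()
    )
    return {
        "durations": durations,
        "by_stage": by_stage,
        "doubling_by_stage_size": cross,
    }
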