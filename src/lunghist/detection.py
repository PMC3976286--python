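"""Competing-mode, size-linear detection on a yearly detection cycle.

A tumor can be found through three routes evaluated once per detection
cycle (default 1 year): its primary mass, its nodal metastases, or its
distant metastases.  The mode-specific hazards at primary size s are

    h_primary = eta s + w0,   h_nodal = w1 N,   h_distant = w2 M,

where N, M in {0, 1} indicate detectable nodal/distant metastases and the
total stage hazard z_NM is their sum (z00 = eta s + w0, z11 = eta s + w0 +
w1 + w2, ...).  In each cycle the stage indicators are updated first, the
tumor is then detected with probability 1 - exp(-z * cycle_years), and on
detection the mode is drawn multinomially in proportion to the three
hazards.  Stage at diagnosis follows from (N, M): M=1 -> M1, else N=1 ->
NxM0, else N0M0.

By default s is the primary volume in cm^3 (with the calibrated magnitudes
this puts localized detection on a multi-year scale and makes detection
near-immediate once metastases exist, w1, w2 >> w0); a cell-count size
unit is selectable.  An optional detectability lag delays the point at
which a formed metastasis counts toward stage and hazard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .progression import (
    ProgressionParams,
    TumorCourse,
    diameter_from_volume,
    sample_met_times,
)

__all__ = [
    "DetectionParams",
    "DetectedCase",
    "MODES",
    "STAGES",
    "stage_label",
    "mode_hazards",
    "cycle_detection",
    "simulate_tumors",
    "CohortDraws",
    "make_cohort_draws",
    "stage_probs_given_size",
]

MODES = ("primary", "nodal", "distant")
STAGES = ("N0M0", "NxM0", "M1")

_EXP_CAP = 46.0  # e^46 cells ~ 1e11 cm^3; hazards saturate far below this


@dataclass(frozen=True)
class DetectionParams:
    """Detection-model parameters.

    eta          efficiency of detection by tumor size (per size unit per year)
    w0, w1, w2   stage-dependent hazard offsets (per year) for the primary,
                 nodal and distant routes
    cycle_years  detection-evaluation interval (years)
    size_unit    'cm3' (default) or 'cells' — unit of s in eta*s
    met_detectability_lag_years  delay before a formed metastasis counts as
                 detectable/present (years)
    """

    eta: float = 1.0e-4
    w0: float = 0.065
    w1: float = 1.50e3
    w2: float = 7.00e4
    cycle_years: float = 1.0
    size_unit: str = "cm3"
    met_detectability_lag_years: float = 0.0

    def __post_init__(self) -> None:
        for name in ("eta", "w0", "w1", "w2"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        if self.cycle_years <= 0.0:
            raise ValueError("cycle_years must be > 0")
        if self.size_unit not in ("cm3", "cells"):
            raise ValueError("size_unit must be 'cm3' or 'cells'")
        if self.met_detectability_lag_years < 0.0:
            raise ValueError("met_detectability_lag_years must be >= 0")


@dataclass(frozen=True)
class DetectedCase:
    """A detected tumor: when, through which route, at what size/stage."""

    person_id: int
    detection_age: float
    mode: str
    primary_volume: float  # cm^3
    diameter: float  # cm
    N: int
    M: int
    stage: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "nodal" and self.N != 1:
            raise ValueError("nodal-mode detection requires N = 1")
        if self.mode == "distant" and self.M != 1:
            raise ValueError("distant-mode detection requires M = 1")
        if self.stage != stage_label(self.N, self.M):
            raise ValueError("stage label inconsistent with (N, M)")


def stage_label(N: int, M: int) -> str:
    """TNM-style stage from the metastasis indicators."""
    if M:
        return "M1"
    return "NxM0" if N else "N0M0"


def mode_hazards(s: float, N: int, M: int, dp: DetectionParams):
    """Mode-specific hazards (h_primary, h_nodal, h_distant) at primary
    size ``s`` (in ``dp.size_unit``) with stage indicators N, M."""
    if np.any(np.asarray(s) <= 0.0):
        raise ValueError("size must be > 0")
    h_p = dp.eta * s + dp.w0
    h_n = dp.w1 * (1 if N else 0)
    h_d = dp.w2 * (1 if M else 0)
    return h_p, h_n, h_d


def cycle_detection(
    course: TumorCourse,
    dp: DetectionParams,
    rng: np.random.Generator,
    censor_age: float,
    cell_volume: float = 1.0e-9,
) -> Optional[DetectedCase]:
    """Run the yearly detection cycle for a single tumor course.

    Advances in steps of ``cycle_years`` from onset; at each evaluation the
    stage indicators are updated from the metastasis times (plus the
    detectability lag), then detection is tested against the current total
    hazard.  Returns None if ``censor_age`` (death) is reached first.
    """
    if censor_age < course.onset_age:
        raise ValueError("censor_age must be >= onset_age")
    lag = dp.met_detectability_lag_years
    k = 0
    while True:
        k += 1
        t = k * dp.cycle_years
        if course.onset_age + t > censor_age:
            return None
        N = int(course.t_nodal is not None and course.t_nodal + lag <= t)
        M = int(course.t_distant is not None and course.t_distant + lag <= t)
        vol = cell_volume * np.exp(min(course.lam * t, _EXP_CAP))
        s = vol if dp.size_unit == "cm3" else vol / cell_volume
        h_p, h_n, h_d = mode_hazards(s, N, M, dp)
        z = h_p + h_n + h_d
        if rng.random() < -np.expm1(-z * dp.cycle_years):
            u = rng.random() * z
            mode = "primary" if u < h_p else ("nodal" if u < h_p + h_n else "distant")
            return DetectedCase(
                person_id=course.person_id,
                detection_age=course.onset_age + t,
                mode=mode,
                primary_volume=float(vol),
                diameter=float(diameter_from_volume(vol)),
                N=N,
                M=M,
                stage=stage_label(N, M),
            )


# ---------------------------------------------------------------------------
# Vectorized cohort pipeline (progression + detection for many tumors)
# ---------------------------------------------------------------------------

@dataclass
class CohortDraws:
    """Pre-drawn uniforms/exponentials so the pipeline can be re-evaluated
    at different parameters with common random numbers (required for a
    stable simulation-based objective)."""

    u_lambda: np.ndarray  # (n,) uniforms -> gamma growth rates via ppf
    e_nodal: np.ndarray  # (n,) standard exponentials
    e_distant: np.ndarray  # (n,)
    u_detect: np.ndarray  # (n, max_cycles) uniforms for per-cycle detection
    u_mode: np.ndarray  # (n,) uniforms for the mode draw


def make_cohort_draws(
    n: int, rng: np.random.Generator, max_cycles: int = 80
) -> CohortDraws:
    return CohortDraws(
        u_lambda=rng.random(n),
        e_nodal=rng.exponential(size=n),
        e_distant=rng.exponential(size=n),
        u_detect=rng.random((n, max_cycles)),
        u_mode=rng.random(n),
    )


def simulate_tumors(
    pp: ProgressionParams,
    dp: DetectionParams,
    rng: Optional[np.random.Generator],
    onset_ages: np.ndarray,
    censor_ages: np.ndarray,
    draws: Optional[CohortDraws] = None,
) -> pd.DataFrame:
    """Simulate the full natural history of ``len(onset_ages)`` tumors.

    Each tumor gets a gamma growth rate and conditionally independent
    nodal/distant metastasis times, then runs the yearly detection cycle
    until detection or censoring (death) at ``censor_ages``.

    Returns a DataFrame with one row per tumor: onset_age, lam, t_nodal,
    t_distant, detected, det_time (years from onset), detection_age, mode,
    volume_cm3, diameter_cm, N, M, stage (NaN/None where undetected).
    """
    onset_ages = np.asarray(onset_ages, dtype=float)
    censor_ages = np.asarray(censor_ages, dtype=float)
    n = onset_ages.size
    if censor_ages.size != n:
        raise ValueError("onset_ages and censor_ages must have equal length")

    if draws is not None:
        lam = gamma_dist.ppf(draws.u_lambda, pp.K, scale=pp.theta)
        e_n, e_m = draws.e_nodal, draws.e_distant
        t_n = np.log1p(e_n / (pp.mu_n * pp.xi)) / lam
        t_m = np.log1p(e_m / (pp.mu_m * pp.xi)) / lam
    else:
        if rng is None:
            raise ValueError("either rng or draws must be provided")
        lam = rng.gamma(pp.K, pp.theta, size=n)
        t_n, t_m = sample_met_times(lam, pp, rng)

    rel_censor = censor_ages - onset_ages
    cycle = dp.cycle_years
    lag = dp.met_detectability_lag_years
    max_cycles = int(np.ceil(max(rel_censor.max(), 0.0) / cycle)) if n else 0
    if draws is not None:
        max_cycles = min(max_cycles, draws.u_detect.shape[1])

    detected = np.zeros(n, dtype=bool)
    det_cycle = np.zeros(n, dtype=np.int64)
    det_N = np.zeros(n, dtype=np.int8)
    det_M = np.zeros(n, dtype=np.int8)
    det_mode = np.full(n, -1, dtype=np.int8)

    active = np.ones(n, dtype=bool)
    for k in range(1, max_cycles + 1):
        t_k = k * cycle
        active &= t_k <= rel_censor  # death censors before this evaluation
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        N_k = (t_n[idx] + lag) <= t_k
        M_k = (t_m[idx] + lag) <= t_k
        vol = 1.0 * np.exp(np.minimum(lam[idx] * t_k, _EXP_CAP)) * pp.cell_volume
        s = vol if dp.size_unit == "cm3" else vol / pp.cell_volume
        h_p = dp.eta * s + dp.w0
        h_n = dp.w1 * N_k
        h_d = dp.w2 * M_k
        z = h_p + h_n + h_d
        p_det = -np.expm1(-z * cycle)
        u = draws.u_detect[idx, k - 1] if draws is not None else rng.random(idx.size)
        hit = u < p_det
        if hit.any():
            didx = idx[hit]
            detected[didx] = True
            det_cycle[didx] = k
            det_N[didx] = N_k[hit]
            det_M[didx] = M_k[hit]
            um = (draws.u_mode[didx] if draws is not None else rng.random(didx.size)) * z[hit]
            mode = np.where(um < h_p[hit], 0, np.where(um < (h_p + h_n)[hit], 1, 2))
            det_mode[didx] = mode
            active[didx] = False

    det_time = np.where(detected, det_cycle * cycle, np.nan)
    with np.errstate(over="ignore", invalid="ignore"):
        vol_det = pp.cell_volume * np.exp(np.minimum(lam * det_time, _EXP_CAP))
    diam_det = np.where(detected, (6.0 * vol_det / np.pi) ** (1.0 / 3.0), np.nan)
    mode_labels = np.array(MODES, dtype=object)
    stage = np.where(
        detected,
        np.where(det_M == 1, "M1", np.where(det_N == 1, "NxM0", "N0M0")),
        None,
    )
    return pd.DataFrame(
        {
            "onset_age": onset_ages,
            "lam": lam,
            "t_nodal": t_n,
            "t_distant": t_m,
            "detected": detected,
            "det_time": det_time,
            "detection_age": onset_ages + det_time,
            "mode": np.where(detected, mode_labels[det_mode], None),
            "volume_cm3": np.where(detected, vol_det, np.nan),
            "diameter_cm": diam_det,
            "N": np.where(detected, det_N, -1),
            "M": np.where(detected, det_M, -1),
            "stage": stage,
        }
    )


def stage_probs_given_size(
    diameter_cm: float,
    pp: ProgressionParams,
    dp: DetectionParams,
    n: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    min_count: int = 100,
) -> Tuple[float, float, int]:
    """Estimate P(N=1) and P(M=1) among detected tumors whose primary
    diameter falls in the 1-cm bin containing ``diameter_cm``.

    Forward-simulates the progression + detection pipeline (onset ages
    uniform on 40-80 with Gompertz other-cause censoring, the package's
    desk-scale study condition) and conditions on the detected-size bin.
    Returns (P_N, P_M, achieved conditional count); raises if the bin
    collects fewer than ``min_count`` cases.
    """
    if diameter_cm <= 0.0:
        raise ValueError("diameter must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    from .smoking import sample_gompertz

    onset = rng.uniform(40.0, 80.0, size=n)
    censor = sample_gompertz(rng, 8.0e-5, 0.085, size=n, min_age=onset)
    df = simulate_tumors(pp, dp, rng, onset, censor)
    det = df[df["detected"]]
    lo = np.floor(diameter_cm)
    bin_lo = min(lo, 19.0)
    sel = det[
        (det["diameter_cm"] >= bin_lo)
        & ((det["diameter_cm"] < bin_lo + 1.0) | (bin_lo >= 19.0))
    ]
    count = len(sel)
    if count < min_count:
        raise RuntimeError(
            f"only {count} detected cases in the {bin_lo:.0f}-{bin_lo + 1:.0f} cm "
            f"bin (need {min_count}); increase n"
        )
    return (
        float((sel["N"] == 1).mean()),
        float((sel["M"] == 1).mean()),
        count,
    )
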