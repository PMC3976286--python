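"""Simulation-based least-squares calibration of the nine progression and
detection parameters.

The fitting target is the joint distribution of tumor size (1-cm diameter
bins, 0-20 cm, with >20 cm lumped into the top bin) and stage (N0M0 /
NxM0 / M1) among detected cases.  The objective is the plain sum of
squared differences

    L = sum_i sum_j (p_sim[i][j] - p_obs[i][j])^2

between the simulated and observed joint proportion tables, minimized by
Nelder-Mead over the nine parameters (xi, mu_n, mu_m, K, theta, eta, w0,
w1, w2).  The search runs on log-transformed coordinates for positivity,
with the ordering mu_n >= mu_m enforced by parameterizing mu_m =
mu_n * r, r in (0, 1).  Each objective evaluation re-simulates a cohort
with common random numbers, so the objective is deterministic given
(parameters, seed) — without that, Nelder-Mead chases Monte-Carlo noise.

Note on identifiability: the metastasis c.d.f. depends on (xi, mu_n,
mu_m) only through the products xi*mu_n and xi*mu_m, and xi enters the
detection stage nowhere else, so xi is a flat direction of the objective;
only the products are determined by a size-stage table.  Confidence
intervals come from a percentile bootstrap over multinomial resamples of
the observed table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .detection import (
    DetectionParams,
    STAGES,
    make_cohort_draws,
    simulate_tumors,
)
from .progression import ProgressionParams
from .smoking import sample_gompertz

__all__ = [
    "N_BINS",
    "SizeStageTable",
    "FitOptions",
    "FitResult",
    "histogram_cases",
    "least_squares",
    "simulate_size_stage_table",
    "fit",
    "bootstrap_ci",
]

N_BINS = 20  # 1-cm diameter bins [0,1) ... [19,20]; >20 cm lumped into the last


@dataclass(frozen=True)
class SizeStageTable:
    """Normalized joint distribution over stage x diameter bin.

    ``probs`` has shape (3, 20): rows follow :data:`~lunghist.detection.STAGES`
    (N0M0, NxM0, M1), columns are left-closed 1-cm diameter bins with the
    final bin absorbing everything >= 19 cm.  ``n_cases`` records the
    underlying case count (used by the bootstrap).
    """

    probs: np.ndarray
    n_cases: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(STAGES), N_BINS):
            raise ValueError(f"probs must have shape (3, {N_BINS}), got {p.shape}")
        if np.any(p < 0.0):
            raise ValueError("proportions must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {p.sum():.12f}")
        object.__setattr__(self, "probs", p)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{j}-{j + 1}" for j in range(N_BINS - 1)] + ["19-20+"]
        return pd.DataFrame(self.probs, index=list(STAGES), columns=cols)


def size_bin(diameter_cm) -> np.ndarray:
    """1-cm bin index of a diameter, top bin lumped."""
    return np.minimum(np.floor(np.asarray(diameter_cm, dtype=float)), N_BINS - 1).astype(
        int
    )


def histogram_cases(records: pd.DataFrame) -> SizeStageTable:
    """Bin detected cases (columns ``stage`` and a diameter column) into a
    normalized :class:`SizeStageTable`."""
    if len(records) == 0:
        raise ValueError("no records to histogram")
    diam_col = "diameter_cm" if "diameter_cm" in records else "diameter"
    stages = records["stage"].to_numpy()
    bins = size_bin(records[diam_col].to_numpy())
    counts = np.zeros((len(STAGES), N_BINS), dtype=float)
    for i, stage in enumerate(STAGES):
        sel = bins[stages == stage]
        np.add.at(counts[i], sel, 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("records contain no staged cases")
    return SizeStageTable(probs=counts / total, n_cases=int(total))


def least_squares(sim: SizeStageTable, obs: SizeStageTable) -> float:
    """Sum of squared cellwise differences between two tables."""
    if sim.probs.shape != obs.probs.shape:
        raise ValueError("tables have mismatched bin structure")
    d = sim.probs - obs.probs
    return float(np.sum(d * d))


# ---------------------------------------------------------------------------
# Simulation harness used by the objective (and fixtures)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit`.

    n_onsets        simulated tumor onsets per objective evaluation
    seed            seed for the common-random-numbers draws
    maxiter         Nelder-Mead iteration budget
    xatol / fatol   simplex convergence tolerances (log-parameter space / loss)
    onset_age_range ages at onset drawn uniformly over this interval
    gompertz_b/c    other-cause mortality used for censoring
    max_cycles      detection cycles provisioned in the CRN draw matrix
    """

    n_onsets: int = 120_000
    seed: int = 0
    maxiter: int = 300
    xatol: float = 1e-3
    fatol: float = 1e-8
    onset_age_range: Tuple[float, float] = (40.0, 80.0)
    gompertz_b: float = 8.0e-5
    gompertz_c: float = 0.085
    max_cycles: int = 80


@dataclass
class FitResult:
    progression: ProgressionParams
    detection: DetectionParams
    loss: float
    x: np.ndarray
    trace: List[float] = field(default_factory=list)
    n_eval: int = 0
    converged: bool = False
    seed: int = 0
    ci: Optional[Dict[str, Tuple[float, float]]] = None


PARAM_NAMES = ("xi", "mu_n", "mu_m", "K", "theta", "eta", "w0", "w1", "w2")


def _params_to_x(pp: ProgressionParams, dp: DetectionParams) -> np.ndarray:
    r = pp.mu_m / pp.mu_n
    r = min(r, 1.0 - 1e-12)
    return np.array(
        [
            np.log(pp.xi),
            np.log(pp.mu_n),
            logit(r),
            np.log(pp.K),
            np.log(pp.theta),
            np.log(dp.eta),
            np.log(dp.w0),
            np.log(dp.w1),
            np.log(dp.w2),
        ]
    )


def _x_to_params(
    x: np.ndarray, dp_template: DetectionParams
) -> Tuple[ProgressionParams, DetectionParams]:
    xi = min(float(np.exp(x[0])), 1.0)
    mu_n = float(np.exp(x[1]))
    mu_m = mu_n * float(expit(x[2]))
    pp = ProgressionParams(
        xi=xi, mu_n=mu_n, mu_m=mu_m, K=float(np.exp(x[3])), theta=float(np.exp(x[4]))
    )
    dp = replace(
        dp_template,
        eta=float(np.exp(x[5])),
        w0=float(np.exp(x[6])),
        w1=float(np.exp(x[7])),
        w2=float(np.exp(x[8])),
    )
    return pp, dp


def simulate_size_stage_table(
    pp: ProgressionParams,
    dp: DetectionParams,
    options: FitOptions,
    draws=None,
    onset_ages: Optional[np.ndarray] = None,
    censor_ages: Optional[np.ndarray] = None,
) -> Optional[SizeStageTable]:
    """Simulate a cohort under (pp, dp) and histogram the detected cases.

    With ``draws``/``onset_ages``/``censor_ages`` supplied the evaluation is
    fully deterministic (common random numbers).  Returns None when no
    tumor is detected.
    """
    rng = np.random.default_rng(options.seed)
    n = options.n_onsets
    if onset_ages is None:
        lo, hi = options.onset_age_range
        onset_ages = rng.uniform(lo, hi, size=n)
        censor_ages = sample_gompertz(
            rng, options.gompertz_b, options.gompertz_c, size=n, min_age=onset_ages
        )
    if draws is None:
        draws = make_cohort_draws(n, rng, max_cycles=options.max_cycles)
    df = simulate_tumors(pp, dp, None, onset_ages, censor_ages, draws=draws)
    det = df[df["detected"]]
    if len(det) == 0:
        return None
    return histogram_cases(det)


def fit(
    obs: SizeStageTable,
    init: Tuple[ProgressionParams, DetectionParams],
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Calibrate the nine progression/detection parameters to ``obs``.

    ``init`` provides the starting point; ``options`` controls the
    simulated cohort size per evaluation, the CRN seed, and the
    Nelder-Mead budget.  Returns the best parameters found, flagging
    non-convergence within the budget rather than raising.
    """
    options = options or FitOptions()
    pp0, dp0 = init
    x0 = _params_to_x(pp0, dp0)

    rng = np.random.default_rng(options.seed)
    lo, hi = options.onset_age_range
    onset_ages = rng.uniform(lo, hi, size=options.n_onsets)
    censor_ages = sample_gompertz(
        rng, options.gompertz_b, options.gompertz_c,
        size=options.n_onsets, min_age=onset_ages,
    )
    draws = make_cohort_draws(options.n_onsets, rng, max_cycles=options.max_cycles)

    trace: List[float] = []

    def objective(x: np.ndarray) -> float:
        try:
            pp, dp = _x_to_params(x, dp0)
        except ValueError:
            return 4.0  # outside the admissible region; L is bounded by 2
        table = simulate_size_stage_table(
            pp, dp, options, draws=draws,
            onset_ages=onset_ages, censor_ages=censor_ages,
        )
        if table is None:
            return 4.0
        loss = least_squares(table, obs)
        trace.append(loss)
        return loss

    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": options.maxiter,
            "xatol": options.xatol,
            "fatol": options.fatol,
            "adaptive": True,
        },
    )
    pp, dp = _x_to_params(res.x, dp0)
    return FitResult(
        progression=pp,
        detection=dp,
        loss=float(res.fun),
        x=np.asarray(res.x),
        trace=trace,
        n_eval=int(res.nfev),
        converged=bool(res.success),
        seed=options.seed,
    )


def _result_param_vector(r: FitResult) -> Dict[str, float]:
    pp, dp = r.progression, r.detection
    return {
        "xi": pp.xi,
        "mu_n": pp.mu_n,
        "mu_m": pp.mu_m,
        "K": pp.K,
        "theta": pp.theta,
        "eta": dp.eta,
        "w0": dp.w0,
        "w1": dp.w1,
        "w2": dp.w2,
    }


def bootstrap_ci(
    obs: SizeStageTable,
    fit_result: FitResult,
    B: int,
    options: Optional[FitOptions] = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> Dict[str, Tuple[float, float]]:
    """Percentile bootstrap intervals from refits to B multinomial
    resamples of the observed table (the package's substitute for
    asymptotic intervals; the resampling respects the case count).

    Small B yields degenerate, purely indicative intervals; a warning is
    emitted for B < 20.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if B < 20:
        import warnings

        warnings.warn(
            f"B={B} gives degenerate percentile intervals; use B >= 20",
            stacklevel=2,
        )
    options = options or FitOptions()
    rng = np.random.default_rng(seed)
    flat = obs.probs.ravel()
    draws: Dict[str, List[float]] = {name: [] for name in PARAM_NAMES}
    for b in range(B):
        counts = rng.multinomial(obs.n_cases, flat / flat.sum())
        p = counts.astype(float) / counts.sum()
        table = SizeStageTable(probs=p.reshape(obs.probs.shape), n_cases=obs.n_cases)
        opts_b = replace(options, seed=options.seed + 1 + b)
        r = fit(table, (fit_result.progression, fit_result.detection), opts_b)
        for name, val in _result_param_vector(r).items():
            draws[name].append(val)
    out: Dict[str, Tuple[float, float]] = {}
    for name, vals in draws.items():
        lo = float(np.quantile(vals, alpha / 2))
        hi = float(np.quantile(vals, 1 - alpha / 2))
        out[name] = (lo, hi)
    return out
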