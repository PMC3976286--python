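"""Smoking-dependent two-stage clonal expansion (TSCE) model of tumor onset.

The TSCE model of carcinogenesis: normal cells are initiated at aggregate
rate nu (Poisson in time); each initiated cell founds a clone that divides
at rate alpha, dies at rate beta, and converts to a malignant cell at rate
mu2.  Tumor onset is the appearance of the first malignant cell; the model
yields the survival function of the onset age T in closed form on any
interval where the rates are constant.

Smoking enters through response functions that map intensity d (packs per
day) to the TSCE rates via the identifiable parameterization
(nu, alpha, gamma) with gamma = alpha - beta - mu2 the net clonal
proliferation rate:

    linear form:   nu(d) = nu0 (1 + a1 d),  gamma(d) = gamma0 (1 + a2 d)
    exp form:      nu(d) = nu0 (1 + a1 (1 - e^{-d})),  similarly for gamma

with alpha(d) = alpha0 and beta recovered as alpha - gamma - mu2.  A
person's never/current/former segments give piecewise-constant rates; the
survival function is assembled by integrating the clone-extinction Riccati
equation backward through the segments (closed form per segment).

Derivation used throughout: let u(s) be the probability that a clone
founded by a single initiated cell produces no malignant cell within the
next s years.  Then u' = alpha u^2 - (alpha+beta+mu2) u + beta with
u(0) = 1, whose closed-form solution involves the roots a < 1 < b of
alpha r^2 - (alpha+beta+mu2) r + beta = 0, and

    P(T > t) = exp( - \int_0^t nu(tau) (1 - u(t - tau; tau)) dtau ).

The integral is available in closed form on constant-rate segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .smoking import SmokingHistory

__all__ = [
    "TSCEParams",
    "ResponseParams",
    "PLACEHOLDER_RESPONSE",
    "dose_response",
    "onset_survival",
    "sample_onset_age",
]

RESPONSE_FORMS = ("linear", "exp")


@dataclass(frozen=True)
class TSCEParams:
    """Constant TSCE rates (per year): initiation nu, clone division alpha,
    clone death beta, malignant conversion mu2."""

    nu: float
    alpha: float
    beta: float
    mu2: float

    def __post_init__(self) -> None:
        for name in ("nu", "alpha", "beta", "mu2"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"TSCE rate {name} must be >= 0")


@dataclass(frozen=True)
class ResponseParams:
    """Dose-response parameters linking smoking intensity to TSCE rates.

    nu0, alpha0, gamma0 are the never-smoker baseline initiation, division
    and net-proliferation rates (per year); a1 and a2 scale the initiation
    and proliferation response to dose (per ppd under the linear form);
    mu2 is the malignant conversion rate, taken dose-independent.  ``form``
    selects the functional form ('linear' or 'exp' saturation).
    """

    nu0: float
    alpha0: float
    gamma0: float
    a1: float
    a2: float
    mu2: float = 1.0e-7
    form: str = "linear"

    def __post_init__(self) -> None:
        for name in ("nu0", "alpha0", "gamma0", "mu2"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        if self.form not in RESPONSE_FORMS:
            raise ValueError(f"form must be one of {RESPONSE_FORMS}")


#: Documented placeholder baseline (the published sex-specific response
#: parameters are supplied by the user through configuration; these defaults
#: give roughly 1% never-smoker, 7% 1-ppd and 20% 2-ppd lifetime onset risk,
#: with hazard rising steeply after midlife as the clonal-expansion transient
#: plays out).
PLACEHOLDER_RESPONSE = ResponseParams(
    nu0=0.008, alpha0=3.0, gamma0=0.13, a1=2.0, a2=1.0, mu2=1.0e-5, form="linear"
)


def dose_response(rp: ResponseParams, d: float) -> TSCEParams:
    """TSCE rates at smoking intensity ``d`` (packs per day)."""
    if d < 0.0:
        raise ValueError("dose must be >= 0")
    if rp.form == "linear":
        g = d
    else:  # exponential saturation in dose
        g = -np.expm1(-d)
    nu = rp.nu0 * (1.0 + rp.a1 * g)
    gamma = rp.gamma0 * (1.0 + rp.a2 * g)
    beta = rp.alpha0 - gamma - rp.mu2
    if beta < 0.0:
        raise ValueError(
            "parameters imply a negative clone death rate "
            f"(alpha0={rp.alpha0}, gamma={gamma}, mu2={rp.mu2})"
        )
    return TSCEParams(nu=nu, alpha=rp.alpha0, beta=beta, mu2=rp.mu2)


def _propagate(u_end, dur, p: TSCEParams):
    """Advance the clone no-malignancy probability backward over one
    constant-rate segment of length ``dur`` with terminal value ``u_end``,
    returning (u at segment start, cumulative-hazard contribution).

    Vectorized over ``u_end`` and ``dur`` (broadcast)."""
    u_end = np.asarray(u_end, dtype=float)
    dur = np.asarray(dur, dtype=float)
    shape = np.broadcast_shapes(u_end.shape, dur.shape)
    u_end = np.broadcast_to(u_end, shape).astype(float)
    dur = np.broadcast_to(dur, shape).astype(float)

    if p.mu2 == 0.0 and np.all(u_end == 1.0):
        return np.ones(shape), np.zeros(shape)

    if p.alpha == 0.0:
        tot = p.beta + p.mu2
        if tot == 0.0:
            return u_end.copy(), p.nu * (1.0 - u_end) * dur
        ustar = p.beta / tot
        decay = np.exp(-tot * dur)
        u0 = ustar + (u_end - ustar) * decay
        lam = p.nu * ((1.0 - ustar) * dur - (u_end - ustar) * (1.0 - decay) / tot)
        return u0, lam

    s = p.alpha + p.beta + p.mu2
    disc = s * s - 4.0 * p.alpha * p.beta  # = gamma^2 + mu2^2 + 2 mu2 (alpha+beta) > 0
    sq = np.sqrt(disc)
    a = (s - sq) / (2.0 * p.alpha)
    b = (s + sq) / (2.0 * p.alpha)
    # u_end in (a, 1]; u_end - b < 0 so R0 <= 0 and all logs below are real.
    R0 = (u_end - a) / (u_end - b)
    R = R0 * np.exp(-sq * dur)  # c = alpha (b - a) = sq
    u0 = (a - b * R) / (1.0 - R)
    lam = p.nu * ((1.0 - a) * dur + ((b - a) / sq) * np.log((1.0 - R) / (1.0 - R0)))
    return u0, lam


def _person_pieces(history: SmokingHistory, rp: ResponseParams):
    """Edges and per-piece TSCE rates for one person's never/current/former
    smoking segments, from birth onward."""
    if history.init_age is None:
        edges = [0.0]
        doses = [0.0]
    elif history.quit_age is None:
        edges = [0.0, history.init_age]
        doses = [0.0, history.intensity]
    else:
        edges = [0.0, history.init_age, history.quit_age]
        doses = [0.0, history.intensity, 0.0]
    params = [dose_response(rp, d) for d in doses]
    return edges, params


def onset_survival(history: SmokingHistory, rp: ResponseParams, t):
    """P(no malignant cell by age t) for one person.

    ``t`` may be a scalar or array of ages; returns the matching shape.
    The survival function is 1 at t = 0, nonincreasing, and continuous
    across smoking-segment boundaries.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0.0):
        raise ValueError("age must be >= 0")
    edges, params = _person_pieces(history, rp)
    edges = edges + [np.inf]
    out = np.ones_like(t_arr)
    for j in range(len(params)):
        lo, hi = edges[j], edges[j + 1]
        m = (t_arr > lo) & (t_arr <= hi) if j > 0 else (t_arr >= lo) & (t_arr <= hi)
        if not m.any():
            continue
        u, lam = _propagate(1.0, t_arr[m] - lo, params[j])
        for k in range(j - 1, -1, -1):
            u, dlam = _propagate(u, edges[k + 1] - edges[k], params[k])
            lam = lam + dlam
        out[m] = np.exp(-lam)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def sample_onset_age(
    history: SmokingHistory,
    rp: ResponseParams,
    rng: np.random.Generator,
    max_age: float = 110.0,
    grid_step: float = 0.1,
) -> Optional[float]:
    """Inverse-c.d.f. sample of the onset age T, or None if no onset occurs
    by min(max_age, other_cause_death_age).

    The survival function is tabulated on a uniform age grid (default
    0.1-year steps) and inverted by linear interpolation.
    """
    if max_age <= 0.0:
        raise ValueError("max_age must be > 0")
    horizon = min(max_age, history.other_cause_death_age)
    grid = np.append(np.arange(0.0, horizon, grid_step), horizon)
    surv = onset_survival(history, rp, grid)
    u = rng.random()
    if u <= surv[-1]:
        return None
    # surv is nonincreasing in age; invert on the reversed (increasing) axis
    t = float(np.interp(u, surv[::-1], grid[::-1]))
    return t
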