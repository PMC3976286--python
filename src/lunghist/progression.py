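"""Primary tumor growth and detachment-driven metastasis hazards.

Model: the primary tumor grows exponentially from a single cell of volume
``cell_volume`` (default 1e-9 cm^3), with per-year growth rate lambda drawn
once at onset from a gamma distribution (shape K, scale theta) and held
constant thereafter.  Cells continuously detach from the primary in
proportion to its growth; the cumulative number of detached cells by time
t after onset is xi (e^{lambda t} - 1) with xi in (0, 1] so the detached
pool never exceeds the tumor itself.  Detached cells seed nodal and
distant metastases after transfer and deposition at rates mu_n >= mu_m
(nodal sites are at least as accessible as distant ones), giving, for a
tumor of known growth rate, the metastasis-time hazard and c.d.f.

    h(t) = mu xi lambda e^{lambda t},
    F(t | lambda) = 1 - exp(-mu xi (e^{lambda t} - 1)).

Marginal (population-level) metastasis-time densities mix the conditional
density over the gamma growth-rate law by quadrature.  Tumors are spheres
for the volume <-> diameter conversion; metastasis deposits grow 3x
(nodal) and 4x (distant) faster than the primary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import integrate, optimize
from scipy.stats import gamma as gamma_dist

__all__ = [
    "ProgressionParams",
    "TumorCourse",
    "cells_at",
    "volume_at",
    "doubling_time_days",
    "diameter_from_volume",
    "volume_from_diameter",
    "detached_cells",
    "met_hazard",
    "met_cdf",
    "sample_growth_rate",
    "sample_met_times",
    "marginal_met_pdf",
    "marginal_met_mode",
    "nodal_only_pdf",
]

SITES = ("nodal", "distant")

#: Exponent cap for e^{lambda t}: beyond this the tumor is ~1e11 cm^3 and
#: every downstream hazard has long since saturated; keeps float math finite.
_EXP_CAP = 46.0


@dataclass(frozen=True)
class ProgressionParams:
    """Growth and metastasis parameters.

    xi      dimensionless detachment fraction in (0, 1]
    mu_n    transfer/deposition rate of detached cells to nodal sites (1/yr)
    mu_m    same for distant sites (1/yr); mu_n >= mu_m > 0
    K       gamma shape of the growth-rate distribution
    theta   gamma scale of the growth-rate distribution (1/yr)
    cell_volume            volume of a single cell (cm^3)
    met_growth_multipliers (nodal, distant) growth-rate multipliers of
                           metastasis deposits relative to the primary
    """

    xi: float = 0.01
    mu_n: float = 8.05e-9
    mu_m: float = 2.78e-9
    K: float = 3.80
    theta: float = 1.15
    cell_volume: float = 1.0e-9
    met_growth_multipliers: Tuple[float, float] = (3.0, 4.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.xi <= 1.0):
            raise ValueError("xi must be in (0, 1]")
        if not (self.mu_n >= self.mu_m > 0.0):
            raise ValueError("rates must satisfy mu_n >= mu_m > 0")
        if self.K <= 0.0 or self.theta <= 0.0:
            raise ValueError("gamma parameters K, theta must be > 0")
        if self.cell_volume <= 0.0:
            raise ValueError("cell_volume must be > 0")

    def mu(self, site: str) -> float:
        if site not in SITES:
            raise ValueError(f"site must be one of {SITES}")
        return self.mu_n if site == "nodal" else self.mu_m


@dataclass(frozen=True)
class TumorCourse:
    """One tumor's latent natural history: onset age, growth rate, and
    times (years from onset) at which nodal/distant metastases form."""

    person_id: int
    onset_age: float
    lam: float
    t_nodal: Optional[float] = None
    t_distant: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lam <= 0.0:
            raise ValueError("growth rate lambda must be > 0")
        for t in (self.t_nodal, self.t_distant):
            if t is not None and t <= 0.0:
                raise ValueError("metastasis times must be > 0")


# ---------------------------------------------------------------------------
# Deterministic growth
# ---------------------------------------------------------------------------

def cells_at(lam: float, t) -> float:
    """Cell count e^{lambda t} of a tumor started from one cell."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("t must be >= 0")
    return np.exp(lam * t)


def volume_at(lam: float, t, cell_volume: float = 1.0e-9):
    """Tumor volume (cm^3) at time t after onset."""
    return cells_at(lam, t) * cell_volume


def doubling_time_days(lam: float) -> float:
    """Volume doubling time in days, 365 ln2 / lambda (lambda per year)."""
    if np.any(np.asarray(lam) <= 0.0):
        raise ValueError("lambda must be > 0")
    return 365.0 * math.log(2.0) / lam


def diameter_from_volume(v):
    """Sphere diameter (cm) of a tumor of volume v (cm^3)."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0.0):
        raise ValueError("volume must be > 0")
    return (6.0 * v / math.pi) ** (1.0 / 3.0)


def volume_from_diameter(d):
    """Sphere volume (cm^3) of a tumor of diameter d (cm)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0.0):
        raise ValueError("diameter must be > 0")
    return math.pi * d**3 / 6.0


# ---------------------------------------------------------------------------
# Detachment and metastasis
# ---------------------------------------------------------------------------

def detached_cells(lam: float, xi: float, t):
    """Cumulative number of cells detached from the primary by time t:
    xi (e^{lambda t} - 1); never exceeds the cell count when xi <= 1."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("t must be >= 0")
    return xi * np.expm1(lam * t)


def met_hazard(lam: float, xi: float, mu: float, t):
    """Metastasis hazard mu xi lambda e^{lambda t} for a tumor of growth
    rate lambda."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("t must be >= 0")
    return mu * xi * lam * np.exp(lam * t)


def met_cdf(lam: float, xi: float, mu: float, t):
    """Conditional metastasis-time c.d.f. 1 - exp(-mu xi (e^{lambda t}-1))."""
    if mu <= 0.0:
        raise ValueError("mu must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("t must be >= 0")
    with np.errstate(over="ignore"):
        return -np.expm1(-mu * xi * np.expm1(lam * t))


def sample_growth_rate(pp: ProgressionParams, rng: np.random.Generator, size=None):
    """Draw growth rates lambda ~ Gamma(K, scale=theta)."""
    return rng.gamma(pp.K, pp.theta, size=size)


def sample_met_times(lam, pp: ProgressionParams, rng: np.random.Generator):
    """Sample (t_nodal, t_distant) by inverting the conditional c.d.f.:
    t = ln(1 + E / (mu xi)) / lambda with E standard exponential.  The two
    sites are conditionally independent given lambda.  Vectorized over
    ``lam``; returns arrays matching its shape."""
    lam = np.asarray(lam, dtype=float)
    e_n = rng.exponential(size=lam.shape)
    e_m = rng.exponential(size=lam.shape)
    t_n = np.log1p(e_n / (pp.mu_n * pp.xi)) / lam
    t_m = np.log1p(e_m / (pp.mu_m * pp.xi)) / lam
    return t_n, t_m


# ---------------------------------------------------------------------------
# Gamma-mixed marginal metastasis-time densities
# ---------------------------------------------------------------------------

def _gamma_mass_points(pp: ProgressionParams, lam_max: float):
    """Breakpoints marking where the gamma growth-rate law carries its
    mass, so adaptive quadrature cannot step over a concentrated spike."""
    lo = gamma_dist.ppf(1e-6, pp.K, scale=pp.theta)
    hi = gamma_dist.ppf(1.0 - 1e-6, pp.K, scale=pp.theta)
    pts = [lo, pp.K * pp.theta, hi]
    return [p for p in pts if 0.0 < p < lam_max]


def _log_conditional_pdf(t, lam, muxi):
    """log of mu xi lambda e^{lambda t} exp(-mu xi (e^{lambda t} - 1))."""
    lt = lam * t
    with np.errstate(over="ignore"):
        tail = muxi * np.expm1(lt)
    return np.log(muxi * lam) + lt - tail


def marginal_met_pdf(
    pp: ProgressionParams, t, site: str = "nodal", lam_max: float = 30.0
):
    """Marginal metastasis-time density, mixing the conditional density
    over lambda ~ Gamma(K, theta) by adaptive quadrature on (0, lam_max]."""
    mu = pp.mu(site)
    muxi = mu * pp.xi

    def one(tv: float) -> float:
        if tv <= 0.0:
            return 0.0

        def integrand(lam):
            logf = gamma_dist.logpdf(lam, pp.K, scale=pp.theta) + _log_conditional_pdf(
                tv, lam, muxi
            )
            with np.errstate(over="ignore", under="ignore", invalid="ignore"):
                val = np.exp(logf)
            return np.where(np.isfinite(val), val, 0.0)

        val, err = integrate.quad(
            integrand, 0.0, lam_max, limit=200, points=_gamma_mass_points(pp, lam_max)
        )
        if not np.isfinite(val):
            raise ArithmeticError(
                f"marginal density quadrature failed at t={tv} (value {val}, err {err})"
            )
        return val

    t_arr = np.asarray(t, dtype=float)
    if t_arr.ndim == 0:
        return one(float(t_arr))
    return np.array([one(tv) for tv in t_arr])


def marginal_met_mode(
    pp: ProgressionParams,
    site: str = "nodal",
    bounds: Tuple[float, float] = (0.01, 30.0),
) -> float:
    """Mode (years) of the marginal metastasis-time density, by bounded
    scalar search."""
    res = optimize.minimize_scalar(
        lambda t: -marginal_met_pdf(pp, t, site=site),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-3},
    )
    if not res.success:
        raise ArithmeticError(f"mode search did not converge: {res.message}")
    return float(res.x)


def nodal_only_pdf(pp: ProgressionParams, t, lam_max: float = 30.0):
    """Density of nodal-metastasis times among tumors with no distant
    metastasis by the same time: the conditional nodal density times the
    distant survival factor, mixed over the growth-rate law.  Bounded above
    by the marginal nodal density."""
    muxi_n = pp.mu_n * pp.xi
    muxi_m = pp.mu_m * pp.xi

    def one(tv: float) -> float:
        if tv <= 0.0:
            return 0.0

        def integrand(lam):
            with np.errstate(over="ignore", under="ignore", invalid="ignore"):
                logf = (
                    gamma_dist.logpdf(lam, pp.K, scale=pp.theta)
                    + _log_conditional_pdf(tv, lam, muxi_n)
                    - muxi_m * np.expm1(lam * tv)
                )
                val = np.exp(logf)
            return np.where(np.isfinite(val), val, 0.0)

        val, err = integrate.quad(
            integrand, 0.0, lam_max, limit=200, points=_gamma_mass_points(pp, lam_max)
        )
        if not np.isfinite(val):
            raise ArithmeticError(
                f"nodal-only quadrature failed at t={tv} (value {val}, err {err})"
            )
        return val

    t_arr = np.asarray(t, dtype=float)
    if t_arr.ndim == 0:
        return one(float(t_arr))
    return np.array([one(tv) for tv in t_arr])
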