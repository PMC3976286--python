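"""Independent oracles used by the test suite.

These deliberately avoid the package's own closed forms: the two-stage
onset survival is checked against a direct Gillespie simulation of the
branching process, and the metastasis-time c.d.f. against a thinned
inhomogeneous-Poisson first-event simulation.
"""

from __future__ import annotations

import numpy as np


def branching_survival_mc(
    nu: float,
    alpha: float,
    beta: float,
    mu2: float,
    t: float,
    n_rep: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo estimate of P(no malignant cell by time t) for the
    two-stage process, by vectorized Gillespie simulation across replicates.

    State per replicate: number of live initiated cells.  Events:
    initiation (rate nu), division (n*alpha), death (n*beta), malignant
    conversion (n*mu2, absorbing failure).
    """
    n_cells = np.zeros(n_rep, dtype=np.int64)
    clock = np.zeros(n_rep)
    alive = np.ones(n_rep, dtype=bool)  # not yet failed
    active = np.ones(n_rep, dtype=bool)  # still needs simulating
    while active.any():
        idx = np.flatnonzero(active)
        n = n_cells[idx].astype(float)
        total = nu + n * (alpha + beta + mu2)
        dt = rng.exponential(1.0 / total)
        clock[idx] += dt
        done = clock[idx] >= t
        active[idx[done]] = False
        idx = idx[~done]
        if idx.size == 0:
            continue
        n = n_cells[idx].astype(float)
        total = nu + n * (alpha + beta + mu2)
        u = rng.random(idx.size) * total
        init_ev = u < nu
        div_ev = (~init_ev) & (u < nu + n * alpha)
        death_ev = (~init_ev) & (~div_ev) & (u < nu + n * (alpha + beta))
        mal_ev = (~init_ev) & (~div_ev) & (~death_ev)
        n_cells[idx[init_ev]] += 1
        n_cells[idx[div_ev]] += 1
        n_cells[idx[death_ev]] -= 1
        failed = idx[mal_ev]
        alive[failed] = False
        active[failed] = False
    return float(alive.mean())


def met_time_mc(
    lam: float,
    xi: float,
    mu: float,
    n_rep: int,
    rng: np.random.Generator,
    t_max: float = 12.0,
    dt: float = 0.002,
) -> np.ndarray:
    """First-event times of an inhomogeneous Poisson process with rate
    mu*xi*lam*e^{lam t}, by per-step Bernoulli thinning on a fine time
    grid (independent of the package's inverse-c.d.f. sampler).  Each step
    [t, t+dt) fires with probability 1 - exp(-dH), dH the step's exact
    cumulative intensity; censored replicates return +inf.
    """
    first = np.full(n_rep, np.inf)
    undecided = np.ones(n_rep, dtype=bool)
    t = 0.0
    while t < t_max and undecided.any():
        with np.errstate(over="ignore"):
            dH = mu * xi * (np.exp(lam * (t + dt)) - np.exp(lam * t))
        p = -np.expm1(-min(dH, 700.0))
        hit = rng.random(n_rep) < p
        newly = undecided & hit
        first[newly] = t + dt * rng.random(int(newly.sum()))
        undecided &= ~hit
        t += dt
    return first
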