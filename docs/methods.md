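# Methods

`lunghist` chains four model layers into an individual-level natural-history
and detection model of lung cancer, plus a calibration layer that fits the
progression/detection parameters to registry-style data. This note records
the model, the numerical choices, and the limits of what the tests
demonstrate.

## 1. Smoking histories and other-cause mortality

Each simulated person carries a smoking trajectory — initiation age, optional
cessation age, and a lifetime-constant intensity in packs per day (ppd) — and
an age at death from causes other than lung cancer. The generator emulates
the output contract of the CISNET Smoking History Generator with configurable
parametric distributions:

| quantity | default law | default values |
|---|---|---|
| ever-initiation | Bernoulli by sex | male 0.55, female 0.40 |
| initiation age | normal truncated to [10, 40] yr | mean 18, sd 4 |
| time to cessation | exponential after initiation | rate 0.025 /yr |
| intensity | lognormal (constant for life) | median 1.0 ppd, sigma 0.5 |
| other-cause death | Gompertz hazard b·e^(c·age) | b = 8e-5, c = 0.085 (median ~83 yr) |

These defaults are round numbers giving a mid-20th-century U.S.-like
population; they are deliberately not a calibration to national survey data.
A person initiating after their death age is recorded as a never smoker; a
cessation after death is dropped (they die a current smoker). An optional
calendar cut-off year can truncate vital-status observation (the original
generator stopped at 2000); by default no cut-off is applied and the
configured mortality law extrapolates.

## 2. Two-stage clonal expansion (TSCE) onset

Tumor onset is the appearance of the first malignant cell in the two-stage
clonal expansion model: normal cells are initiated at aggregate rate ν
(Poisson in time); each initiated cell founds a clone dividing at α, dying at
β, and converting to malignant at μ₂. Smoking enters through response
functions on the identifiable parameterization (ν, α, γ), γ = α − β − μ₂:

    linear (default):  ν(d) = ν₀(1 + a₁d),  γ(d) = γ₀(1 + a₂d)
    exp saturation:    ν(d) = ν₀(1 + a₁(1 − e^(−d))), likewise for γ

with α(d) = α₀ and β recovered as α − γ − μ₂ (validation rejects β < 0).
μ₂ is held dose-independent. The response parameterization names
(ν₀, α₀, γ₀, a₁, a₂) follow the published convention; the published values
themselves are not reproduced here (they live in supplementary material that
is user-supplied through configuration, separately by sex). The packaged
placeholder baseline (ν₀ = 0.008, α₀ = 3, γ₀ = 0.13, a₁ = 2, a₂ = 1,
μ₂ = 1e-5, all per year, doses in ppd) was chosen so lifetime onset risk is
roughly 1% for never smokers, 7% at 1 ppd and 20% at 2 ppd, with the steep
after-midlife hazard rise that the near-critical clonal expansion produces.
No calibration target depends on these placeholders.

Survival of the onset age is computed exactly on piecewise-constant
never/current/former segments. Writing u(s) for the probability that a clone
founded by one initiated cell produces no malignant cell within s years,
u solves the Riccati equation u' = αu² − (α+β+μ₂)u + β, u(0) = 1, with
closed-form solution through the roots a < 1 < b of
αr² − (α+β+μ₂)r + β = 0, and

    P(T > t) = exp(−∫₀ᵗ ν(τ)(1 − u(t−τ; τ)) dτ),

where the integral is available in closed form per segment and u is
propagated backward across segment boundaries (so a clone initiated while
smoking correctly lives out its later life under post-cessation rates). The
closed form is verified against direct ODE integration (1e-9 agreement) and
against a Gillespie branching-process simulation in the tests. α = 0
degenerates to a linear ODE, handled analytically; μ₂ = 0 gives survival 1.

Onset ages are sampled by inverse c.d.f. on a uniform age grid (0.1-yr steps
to 110 by default, linear interpolation), censored at the other-cause death
age.

## 3. Tumor growth and metastasis

The primary tumor grows exponentially from a single cell of volume
1e-9 cm³; the growth rate λ (per year of log-volume; volume doubling time
365·ln2/λ days) is drawn once at onset from a gamma law with shape K = 3.80
and scale θ = 1.15 /yr (calibrated defaults), so E[λ] = 4.37 /yr, a doubling
time of ~58 days. Tumors are spheres for the volume/diameter conversion.

Cells detach from the primary in proportion to its growth: the cumulative
detached count by time t is ξ(e^{λt} − 1), ξ ∈ (0, 1] so the detached pool
cannot exceed the tumor. Detached cells seed nodal and distant metastases
after transfer/deposition at rates μ_n ≥ μ_m, giving the conditional hazard
and c.d.f.

    h(t|λ) = μξλe^{λt},    F(t|λ) = 1 − exp(−μξ(e^{λt} − 1)).

This hazard family is a reconstruction from the stated model assumptions
(the source equations are not machine-readable); it is the package's
canonical model. Nodal and distant processes are conditionally independent
given λ (both marginals are specified, no coupling is). Deposits grow at 3λ
(nodal) and 4λ (distant); secondary metastasis from metastases is out of
scope. Defaults: ξ = 0.01, μ_n = 8.05e-9, μ_m = 2.78e-9 (calibrated
estimates).

Population-level metastasis-time densities mix the conditional density over
the gamma growth-rate law by adaptive quadrature on λ ∈ (0, 30], with
breakpoints at the gamma quantiles so a concentrated growth-rate law cannot
be stepped over; modes are located by bounded scalar search with 1e-3-yr
tolerance. The densities normalize to 1 within 1e-3 (tested); the mode
structure under the defaults is ~4.1 yr (nodal) and ~4.3 yr (distant), with
the nodal/distant spacing set by ln(μ_n/μ_m)/λ as expected.

**Known discrepancy with the published record.** The publication this model
family follows prints marginal-mode values of 6.4/6.8 yr, a latent median
primary volume at nodal metastasis of 0.06 cm³, and the parameter estimates
above — but these three anchors imply mutually incompatible values of the
product ξμ_n (about e^−35, e^−17.9 and e^−23.2 respectively). No single
scale reconciles them, so the package follows the printed parameter
estimates and reports what they imply. The acceptance tests assert the
printed anchors at their stated tolerances and fail with diagnostics where
the inconsistency bites; this is intentional.

## 4. Competing-mode detection

Detection is evaluated on a yearly cycle (configurable `cycle_years`). At
each evaluation, stage indicators N, M (nodal/distant metastasis present)
are updated first — a metastasis formed earlier in the same cycle counts,
matching the yearly visit discretization — then the tumor is detected with
probability 1 − exp(−z·Δ), where the total hazard z at primary size s
decomposes into competing mode-specific routes:

    h_primary = η·s + w₀,   h_nodal = w₁·N,   h_distant = w₂·M,

and the detection mode is drawn in proportion to the three hazards. Stage at
diagnosis follows (N, M): M1 if M = 1, else NxM0 if N = 1, else N0M0.
Defaults (calibrated): η = 1e-4 per cm³·yr, w₀ = 0.065 /yr, w₁ = 1.5e3 /yr,
w₂ = 7e4 /yr. The size unit of s defaults to cm³ — with these magnitudes,
localized disease is detected on a multi-year scale while metastatic disease
is detected at essentially the next cycle (w₁, w₂ ≫ w₀) — and a cell-count
unit is selectable since the published unit is unstated. An optional
detectability lag delays when a formed metastasis counts toward stage and
hazard (default 0: formed = detectable). The additive decomposition of the
stage hazards z_NM into per-route hazards is the natural competing-risks
reading of the model assumptions and is likewise a documented
reconstruction.

With the defaults, the model implies a selection effect at detection: slow-
growing tumors accumulate more metastasis-free yearly evaluations and are
therefore over-represented among localized (N0M0) diagnoses, while fast
growers convert more within-cycle time into metastatic spread. (The source
publication reports the opposite ordering of growth rates by stage; under
the reconstructed hazards its ordering is not reproducible, consistent with
the scale inconsistency noted above.)

## 5. Population simulation

The calendar simulation adds a birth cohort each year (live-birth counts are
configuration; missing years default to the stated pre-1909 constant
2,877,000, scaled by a simulated-persons-per-birth factor), assigns each
person a smoking history, death age and (possibly) a TSCE onset age, runs
progression + detection censored by other-cause death, and emits case
records for diagnoses inside the observation window plus yearly
alive-population counts. No cancer-attributable mortality is applied before
detection; stage "missing" is not simulated, so stage percentages compare to
staged-only registry columns. Smoking status at diagnosis is the trajectory
status at the diagnosis age.

## 6. Calibration

The fitting target is a `SizeStageTable`: the joint distribution of detected
cases over stage (N0M0/NxM0/M1) and 1-cm diameter bins [0,1)…[19,20], with
diameters ≥ 19 cm lumped in the top bin. The objective is the plain sum of
squared cell-wise differences between simulated and observed tables,
minimized by Nelder–Mead over log-transformed parameters, with μ_m = r·μ_n
(r ∈ (0,1) via a logistic link) enforcing the ordering. Each evaluation
re-simulates a cohort with common random numbers (fixed uniforms mapped
through quantile functions), making the objective deterministic given
(parameters, seed); without this the simplex chases Monte-Carlo noise.
Defaults: 1.2e5 simulated onsets per evaluation, onset ages uniform on
40–80, Gompertz censoring as above, simplex tolerances 1e-3 (log-space) /
1e-8 (loss), 300-iteration budget; non-convergence returns best-so-far with
a flag.

**Identifiability.** The metastasis law depends on (ξ, μ_n, μ_m) only
through the products ξμ_n and ξμ_m, and ξ enters detection nowhere else, so
ξ is a flat direction of the objective: only the products are estimable from
a size-stage table. The cycle discretization also saturates w₁ and w₂ (any
value ≫ 1/cycle gives next-cycle detection), and a near-degenerate ridge
couples K, θ, η and the μ products: distinct parameter vectors reach the
observed-table noise floor. In recovery experiments from a 2e5-case
synthetic table the identifiable products come back within ~10% while the
individual factors along the ridge can drift several-fold. Confidence
intervals are percentile bootstrap over multinomial resamples of the
observed table (the package's substitute for unspecified asymptotic
intervals); with the ridge present they should be read as uncertainty on the
identifiable functionals.

## 7. What the synthetic data do and do not show

The synthetic generator reproduces the structural features the model needs —
sex-specific smoking prevalence, age-increasing mortality and onset hazard,
gamma growth-rate heterogeneity, competing size/stage detection — with
round-number defaults rather than fitted national data. Passing tests
demonstrate internal correctness (closed forms vs independent simulations,
inversion samplers vs c.d.f.s, objective vs brute force, round-tripping
formats) and faithful reproduction of the calibrated-parameter model; they
do not demonstrate that the defaults describe any real population, nor can
they resolve the publication-internal inconsistencies documented above.

## 8. Problem sizes

Desk-scale runs use 1e5–2e5 simulated tumors for population summaries
(Monte-Carlo error on stage shares ~0.3 points), 2.5e4–4e4 replicates for
branching-process comparisons, and a 2e5-case observed table with 1.2e5
onsets per objective evaluation for recovery experiments — the package's
standard sizes for its own verification.
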