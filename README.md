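# lunghist

Individual-level natural history and detection of lung cancer.

Most lung cancers present at an advanced stage, and the registry data a
modeler can see — tumor size, nodal/distant stage, age, sex at diagnosis —
are the output of two entangled processes: how tumors arise and progress,
and how (and when) they get found. `lunghist` implements a mechanistic
framework that disentangles them, for epidemiological modelers who want to
trace a person from birth through smoking exposure, tumor onset, growth,
metastasis and eventual diagnosis, and to ask counterfactuals about
detection.

The chain has four layers:

1. **Smoking histories** — per-person initiation/cessation/intensity
   trajectories and other-cause death ages from configurable distributions
   (an emulator of the CISNET Smoking History Generator's output contract).
2. **Tumor onset** — the two-stage clonal expansion (TSCE) model: normal
   cells initiated at rate ν, clones expanding with division α and death β,
   malignant conversion at μ₂; smoking intensity d (packs/day) enters via
   response functions ν(d) = ν₀(1+a₁d), γ(d) = γ₀(1+a₂d) on the net
   proliferation γ = α−β−μ₂. Onset-age survival is exact (closed-form
   Riccati solution, composed backward across never/current/former
   segments).
3. **Growth and metastasis** — exponential growth from one cell with
   per-tumor rate λ ~ Gamma(K, θ); cells detach in proportion to growth
   (cumulative ξ(e^{λt}−1)) and seed nodal/distant metastases at deposition
   rates μ_n ≥ μ_m, giving metastasis-time c.d.f. 1 − exp(−μξ(e^{λt}−1))
   conditional on λ and gamma-mixed marginals at the population level.
4. **Detection** — a yearly competing-risks cycle: at primary size s the
   route hazards are η·s + w₀ (primary), w₁N (nodal), w₂M (distant); the
   first success determines diagnosis time, mode, size and TNM-style stage
   (N0M0 / NxM0 / M1).

A calendar population simulation (birth cohorts from 1890 onward) combines
the layers into a SEER-like case listing, and a calibration layer fits the
nine progression/detection parameters (ξ, μ_n, μ_m, K, θ, η, w₀, w₁, w₂) to
an observed joint tumor-size × stage table by simulation-based least squares
(Nelder–Mead with common random numbers).

See `docs/methods.md` for the full model description, numerical choices,
identifiability analysis, and documented discrepancies between the model's
published anchor values.

## Worked example

```python
import numpy as np
from lunghist import (ProgressionParams, DetectionParams, marginal_met_mode,
                      simulate_tumors, doubling_time_days)
from lunghist.smoking import sample_gompertz

pp, dp = ProgressionParams(), DetectionParams()   # calibrated defaults
print("mean growth rate      :", round(pp.K * pp.theta, 2), "per year")
print("mean doubling time    :", round(doubling_time_days(pp.K * pp.theta), 1), "days")
print("nodal met-time mode   :", round(marginal_met_mode(pp, "nodal"), 2), "years")

rng = np.random.default_rng(1)
n = 100_000
onset = rng.uniform(40.0, 80.0, n)                       # ages at tumor onset
censor = sample_gompertz(rng, 8e-5, 0.085, size=n, min_age=onset)
det = simulate_tumors(pp, dp, rng, onset, censor).query("detected")
print(f"mean onset-to-diagnosis: {det['det_time'].mean():.2f} years")
shares = det["stage"].value_counts(normalize=True)
print(f"stage mix             : N0M0 {100*shares['N0M0']:.1f}%  "
      f"NxM0 {100*shares['NxM0']:.1f}%  M1 {100*shares['M1']:.1f}%")
print(f"median diameter       : {det['diameter_cm'].median():.2f} cm")
```

prints

```
mean growth rate      : 4.37 per year
mean doubling time    : 57.9 days
nodal met-time mode   : 4.09 years
mean onset-to-diagnosis: 5.30 years
stage mix             : N0M0 33.1%  NxM0 20.7%  M1 46.2%
median diameter       : 2.93 cm
```

Read: the average tumor doubles every ~58 days; nodal spread most often
arrives ~4 years after the first malignant cell; under yearly detection with
the calibrated hazards, tumors are diagnosed on average ~5.3 years after
onset at a median diameter of ~3 cm, with roughly half already metastatic —
the familiar registry picture in which localized diagnoses are the minority.

## Command line

```bash
lunghist simulate --config run.yaml --seed 1 --out cases.csv
lunghist fit --observed table.csv --config run.yaml --out fit.yaml
lunghist predict --config run.yaml --out-dir out/
lunghist report --cases cases.csv --out-dir out/ --plots
```

All subcommands honor `--config` (YAML, one section per model layer) and
`--seed`; validation failures exit nonzero.

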