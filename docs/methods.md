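# Methods

This document records the model definitions, parameter choices, numerical
methods, and known limitations of the `qstox` package.

## 1. Myelosuppression ODE model

### 1.1 Equations

Five compartments: proliferating progenitors `Prol`, three transit
(maturation) compartments `T1..T3`, circulating cells `Circ`. All first-order
rates share `k = (n_transit + 1) / MTT`:

```
dProl/dt = k · Prol · (Circ0 / Circ)^γ  −  k · Prol
dTi/dt   = k · (T(i−1) − Ti),   T0 ≡ Prol
dCirc/dt = k · (T3 − Circ)
```

The feedback `(Circ0/Circ)^γ` stimulates proliferation when circulating
counts fall below baseline. The homeostatic equilibrium has every compartment
equal to `Circ0` (equal rates force equal levels along the chain; the
feedback term is then exactly 1).

### 1.2 Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| `circ0` | 5.05 | 10⁹ cells/L | typical baseline neutrophil concentration |
| `mtt` | 125 | h | typical maturation time estimate for this model class |
| `gamma` | 0.17 | – | published population estimate; 0.3 and 0.5 exercised as sensitivity values |
| `n_transit` | 3 | – | standard chain length; `k = 4/125 ≈ 0.032 h⁻¹` |

Treatment is an instantaneous fractional kill of the proliferating pool:
`Prol → (1 − f)·Prol`. Multiple events compose multiplicatively. Default
study schedule: `f = 0.95`, single dose or repeated every 21 days (q21d).

### 1.3 Numerical integration

`scipy.integrate.solve_ivp` with LSODA (`rtol = 1e-8`, `atol = 1e-10`),
integrated piecewise between event times so each dose is applied exactly, with
dense output evaluated on a fixed reporting grid (default 1 h). At an event
grid point the post-dose state is recorded. Inside the feedback term only,
`Circ` is floored at `1e-12·Circ0` to keep the right-hand side finite in
pathological states; activations are logged. Negative values from integrator
round-off are clamped to zero and logged.

### 1.4 Neutropenia grading

CTCAE-style concentration cut-offs `(1.5, 1.0, 0.5, 0.25) × 10⁹/L` for grades
1–4; a value equal to a cut-off takes the more severe grade. With the default
parameters a single 95% kill at γ = 0.17 reaches a nadir of 0.538 × 10⁹/L —
grade 2, just above the grade-3 cut-off — while repeated q21d dosing at
γ ≥ 0.3 drives nadirs into grades 3–4.

### 1.5 Recovery definitions — a deliberate duality

Recovery is measured against the band `|Circ − Circ0| ≤ tol·Circ0` (default
`tol = 0.02`) after the last dose, and the summary reports **two** times:

* **`first_in_band_time`** — the first re-entry into the band after leaving
  it: the moment counts first climb back to baseline. For a single 95% kill
  this is 506 h (γ = 0.17) and 364 h (γ = 0.3) — both under a month, matching
  the qualitative description of these regimes.
* **`recovery_time`** (sustained) — the first time from which the count
  *stays* in the band for the rest of the horizon. Because the dominant
  eigenvalue decays with half-lives of 160 h (γ = 0.17), 282 h (γ = 0.3) and
  1,320 h (γ = 0.5), rebound oscillations keep re-exiting a ±2% band long
  after the first return: sustained times are 1,262 h, ~2,100 h, and beyond
  4,000 h respectively.

The duality is intrinsic to damped oscillatory recovery, not a numerical
artifact: "recovered in under a month" is a first-return statement, "requires
months to recover the basal value" is a sustained-band statement. Tests and
the CLI report both.

### 1.6 Repeated dosing (q21d) regimes

The regime comparison across γ is inherently qualitative, so it is
operationalized on per-cycle nadirs with thresholds frozen from the computed
dynamics *before* the tests were written:

* γ ∈ {0.17, 0.3}: per-cycle nadirs from cycle 2 onward lie within ±20% of
  their mean (measured maximal deviations 0.2% and 9.9%) — consistent
  per-cycle toxicity.
* γ = 0.5: the eigenperiod (≈496 h) nearly resonates with the 504 h dosing
  interval; nadirs deviate by up to 35% and pre-dose counts wander far above
  baseline — the irregular regime. The circulating count also never holds a
  ±2% band for 24 h between doses ("no return to homeostatic values between
  treatments"), which the CLI flags.

## 2. Linear stability analysis

The Jacobian at equilibrium is bidiagonal (chain) plus one feedback entry
`∂Prol'/∂Circ = −kγ`; the proliferating diagonal term vanishes because
production and exit cancel at equilibrium. Its characteristic relation,

```
μ (μ + 1)^(n+1) = −γ,     μ = λ / k,
```

is dimensionless, so stability depends only on γ and the chain length; `MTT`
and `Circ0` only set the time scale. On the Hopf locus (`μ = iω`):

```
ω  = tan( π / (2(n+1)) )
γ* = ω (1 + ω²)^((n+1)/2)
```

For `n = 3`: γ\* = 0.5685424949…

Two independent computational routes are kept and cross-checked in tests:
`numpy.linalg.eigvals` on the Jacobian, and `numpy` polynomial roots of the
characteristic polynomial (agreement to 1e-8 relative over randomized draws).
The bifurcation locator brackets the zero crossing of max Re λ in γ and
solves with Brent's method (`xtol = 1e-6`), cross-checked against the closed
form.

Two structural facts worth noting:

* At γ = 0 the feedback decouples and the Jacobian has an exact zero
  eigenvalue (a line of equilibria in `Prol`); scans flag this row as
  degenerate.
* max Re λ is **not** globally monotone in γ: for small γ the dominant
  eigenvalue is the real root μ ≈ −γ, which *decreases*; the complex pair
  becomes dominant near γ ≈ 0.1 and from there max Re λ increases monotonely
  through the Hopf point. Tests assert monotonicity on the oscillatory
  branch only.

## 3. Crypt–villus agent-based model

### 3.1 Structure and rules

Cylindrical lattice, 16 columns × 30 rows. Rows 0–4: stem cells (mean cycle
24 h). Rows 5–20: transit-amplifying (TA) progenitors (mean cycle 21.5 h).
Rows 21–29: differentiated cells. Cycle times are drawn per cell, uniform
±20% around the mean (asynchrony); initial clocks are uniform over the cycle
(the stationary residual-time distribution).

Per time step (`dt = 0.5 h`):

1. Clocks of cycling cells advance; due divisions execute one at a time in
   seeded random order. A division puts the daughter at the mother's site and
   pushes the column above up by one; the push stops at the first vacancy,
   otherwise the top-row cell transfers to the villus. Cells pushed above a
   band boundary change identity (stem → TA → differentiated, one-way);
   both daughter and mother restart their cycles.
2. Arrested cells age; any reaching the 72 h senescence lifetime are removed,
   the column above collapsing down by one (leaving a transient top vacancy
   that the next division push in that column refills).
3. The villus — a well-mixed count — sheds `shed_rate · dt` cells.

Injury: at a specified time, each proliferative cell in a positional band is
arrested independently with probability `arrest_fraction` (default 0.85;
an exact-count variant exists). Arrest is irreversible; arrested cells keep
their sites, are pushed passively, and never divide. Stem cells are never
targeted. Study bands: rows 5–12 (low half of the TA band) and rows 13–20
(high half).

### 3.2 Calibration and villus sizing

The villus shed rate is set to the **measured** homeostatic division influx
rather than the naive estimate `sites / cycle time ≈ 15.2 cells/h`. The naive
estimate is wrong because cells pushed across the TA top differentiate
mid-cycle, losing the remainder of their cycle; the emergent influx is
≈10.7 cells/h. The calibration window is 720 h: a short (48 h) window has a
±4% rate error whose accumulated villus drift (±120 cells over a 264 h run)
would swamp the injury signal itself (60–200 cells). With the long window the
uninjured villus drifts by ~1% over a full run.

Default villus size is `shed_rate × 72 h ≈ 775 cells`, i.e. a villus whose
turnover time equals the ~3-day absorptive-cell residence that also motivates
the 72 h senescence lifetime. (A much larger villus fed by a single crypt
would imply a multi-week residence, inconsistent with that lifespan; a fixed
`villus_init` remains available as a config override.)

Every scenario runs a 24 h recorded homeostatic lead-in before the injury;
recovery is measured against the pre-injury mean of this stretch.

### 3.3 Recovery metric and measured behavior

Per replicate, recovery time is the first time after injury at which the TA
proliferative count is within 10% of its pre-injury mean and stays there for
12 h; replicates that never recover within the horizon report `None` and are
reported distinctly.

Measured with defaults (10–30 seeds):

* low-band (rows 5–12) mean recovery ≈ 45 h (sd ≈ 1.5 h) — the arrested
  cells sit at the bottom of the band and must be pushed its full height by
  stem/early-TA divisions, whose ~24 h cycle sets the washout velocity;
* high-band (rows 13–20) mean recovery ≈ 14 h — arrested cells are close to
  the top and clear quickly;
* villus nadir: ≈78% of baseline (low band) versus ≈92% (high band). Only
  the low-band injury pushes the villus below 90%; the comparison is made on
  replicate means because individual high-band seeds can graze the 90% line
  through binomial variability in the arrest pattern.

Two honest caveats, visible in the acceptance test results:

1. The low-band mean recovery (≈45 h) sits on the stated "more than two
   days" timescale but about 6% *under* a literal 48 h bound. This follows
   from the fixed division kinetics above; no parameter was adjusted to move
   it.
2. Crypt occupancy is *almost* always constant (divisions replace arrested
   cells before senescence), but in roughly 2 of 20 low-band replicates a few
   arrested cells starting at the very bottom of the band need more than 72 h
   to exit and are removed by senescence, producing a transient ≤0.6% dip in
   total crypt count before the next divisions refill the columns. The model
   reports this faithfully rather than forcing exact constancy.

### 3.4 Determinism and bookkeeping

All randomness flows from a single `numpy` PCG64 generator seeded by
`config.seed`; identical configs reproduce bit-identical trajectories. Per
step, `villus(t+dt) = villus(t) + influx − shed` holds exactly (asserted in
tests). Time series record crypt count, villus count, TA proliferative count,
and the per-row proliferative fraction profile.

## 4. Scenarios and synthetic observations

`qstox.scenarios` freezes the canonical conditions: three feedback exponents
{0.17, 0.3, 0.5} × {single 95% kill, 95% q21d × 6}, and the two crypt injury
bands with seeds 1–10. Bundles serialize to YAML (config) + JSON
(schedule/injury) and round-trip losslessly. `noisy_observations` applies
mean-preserving multiplicative lognormal noise (`σ² = ln(1 + cv²)`,
`μ = −σ²/2`) for property tests only — no acceptance value depends on noise.

## 5. Limitations

* The ODE model has no pharmacokinetics: treatment is an instantaneous
  fractional kill, not a concentration-driven drug effect.
* No inter-individual variability or virtual populations; parameters are
  point estimates.
* The crypt model is a single idealized cylindrical crypt with a well-mixed
  villus; no spatial villus structure, no crowding-dependent cycle
  regulation, and the quantitative recovery times inherit the assumed cycle
  times directly (see §3.3).
* Regime thresholds for "consistent" versus "irregular" repeated-dosing
  nadirs (±20%, cycles 2+) are operational choices documented here; the
  qualitative orderings they encode are robust to the exact threshold.
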