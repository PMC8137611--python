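# qstox

Quantitative systems toxicology simulators for drug-induced injury in two
renewing tissues:

1. **Hematopoiesis** (`qstox.hematopoiesis`, `qstox.stability`) — the
   classical transit-compartment ODE model of chemotherapy-induced
   myelosuppression: a proliferating progenitor pool, three maturation
   (transit) compartments, and a circulating pool, coupled by the feedback
   term `(Circ0/Circ)^γ` that stimulates proliferation when circulating
   counts fall. The package simulates fractional-kill treatment schedules,
   grades the resulting neutropenia on CTCAE-style thresholds, summarizes
   nadir/recovery, and analyzes the linear stability of the homeostatic
   equilibrium — including the Hopf bifurcation in the feedback exponent at
   γ\* ≈ 0.5685.
2. **Intestinal crypt–villus unit** (`qstox.crypt`) — a stochastic
   agent-based model of a cylindrical crypt lattice (stem niche, transit-
   amplifying band, differentiated zone) feeding a well-mixed villus. It
   quantifies how the *position* of an irreversible cycle-arrest injury
   within the transit-amplifying band determines how long the proliferative
   compartment takes to recover and whether villus integrity is compromised.

`qstox.scenarios` packages the canonical study conditions as serializable
bundles, and `qstox.cli` exposes everything as the `qstox` command with
reproducible, manifest-stamped runs.

## Model summary

### Myelosuppression ODE

State `(Prol, T1, T2, T3, Circ)`, common rate constant `k = (n+1)/MTT`
(defaults: `n = 3` transit compartments, `MTT = 125 h`, `Circ0 = 5.05 ×
10⁹/L`):

```
Prol' = k·Prol·(Circ0/Circ)^γ − k·Prol
Ti'   = k·(T(i−1) − Ti)
Circ' = k·(T3 − Circ)
```

Treatment events multiply the proliferating pool by `1 − kill_fraction`
instantaneously. The equilibrium (all compartments at `Circ0`) has the
characteristic relation `μ(μ+1)⁴ = −γ` with `μ = λ/k`, giving the closed-form
Hopf threshold `γ* = ω(1+ω²)²` with `ω = tan(π/8)`, i.e. **γ\* = 0.5685** —
independent of `Circ0` and `MTT`. Below γ\* insults heal (monotonically or
through damped oscillations); above it, blood counts oscillate without
settling.

### Crypt–villus agent-based model

A 16-column × 30-row cylindrical lattice: stem cells in rows 0–4 (24 h
cycle), transit-amplifying (TA) progenitors in rows 5–20 (21.5 h cycle),
differentiated cells above. A division places the daughter at the mother's
site and pushes the column up; the cell leaving the top row joins the villus,
which sheds cells at a constant rate calibrated to the measured homeostatic
influx. Injury irreversibly arrests a fraction of proliferative cells in a
positional band; arrested cells are pushed passively and removed by
senescence after 72 h. Recovery is emergent — divisions below the injured
band push arrested cells up and out.

## Worked example

```python
from qstox import (ModelParams, TreatmentSchedule, simulate,
                   recovery_summary, hopf_gamma)

params = ModelParams(gamma=0.17)                     # published estimate
sched = TreatmentSchedule.single_dose(0.95)          # 95% progenitor kill
traj = simulate(params, sched, horizon=2160.0)       # 90 days, hourly output

rs = recovery_summary(traj, tolerance_fraction=0.02)
print(f"nadir {rs.nadir_value:.3f} x 10^9/L at {rs.nadir_time:.0f} h")
print(f"first return to +/-2% of baseline at {rs.first_in_band_time:.0f} h")
print(f"gamma* = {hopf_gamma(n_transit=3):.4f}")
```

prints

```
nadir 0.538 x 10^9/L at 266 h
first return to +/-2% of baseline at 506 h
gamma* = 0.5685
```

Crypt injury comparison:

```python
import dataclasses, numpy as np
from qstox import CryptConfig, InjurySpec, run_scenario, recovery_time

def mean_recovery(band, seeds=range(1, 11)):
    times = []
    for s in seeds:
        cfg = dataclasses.replace(CryptConfig(), seed=s)
        series = run_scenario(cfg, InjurySpec(0.85, band), horizon=240.0)
        times.append(recovery_time(series))
    return np.mean(times)

print(f"low band (rows 5-12):   {mean_recovery((5, 12)):.0f} h")
print(f"high band (rows 13-20): {mean_recovery((13, 20)):.0f} h")
```

prints (values are seed-dependent; ~±2 h across seed sets)

```
low band (rows 5-12):   46 h
high band (rows 13-20): 14 h
```

An injury low in the TA band takes roughly three times longer to clear —
arrested cells must be pushed the full height of the band — and it is the
only scenario whose villus dips below 90% of its pre-injury size (to ~78% on
average, versus ~92% for the high-band injury).

## Command line

```bash
qstox generate-scenarios --outdir bundles            # canonical scenarios
qstox bifurcation-scan --outdir scan                 # gamma scan + gamma*
qstox simulate-hematology \
    --schedule bundles/single_dose_gamma_0.17.schedule.json --outdir run1
qstox simulate-crypt \
    --injury bundles/arrest_low_band.injury.json \
    --seed 1 --replicates 10 --outdir crypt_low
```

Every run writes a `manifest.json` (command, resolved config, seeds, outputs,
package version, timestamps). Exit codes: 0 success, 2 validation error,
3 numerical failure.

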