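# twinjoint

Estimators for the effect of a longitudinal biomarker on a **left-truncated,
twin-pair-clustered** time-to-event outcome, under a shared gamma frailty —
with a simulation engine and Monte-Carlo harness to compare them.

## The problem

In twin cohorts (and other paired designs: eyes, hips, sibling studies) the
natural time scale for aging-related outcomes is *age*, and participants
enroll at different ages.  A subject is only observed if still event-free at
enrollment, so the survival outcome is left-truncated; and the two members
of a pair share unmeasured genetic and environmental factors, so their event
times are dependent.  Standard joint longitudinal–survival software handles
either the clustering or the delayed entry, not both with a time-varying
marker.  This package implements the combination.

## Model

For twin *j* of pair *i*, the marker follows a twin-structured linear mixed
model and the conditional hazard is Weibull proportional-hazards with a
pair-shared gamma frailty:

```
y_ijk = M_ij(t_k) + ε_ijk,   M_ij(t) = β₀ + β₁ t + b_ij0 (+ b_ij1 t) + u_i
h_ij(t | v_i) = λρ t^{ρ-1} · v_i · exp{ γ'x_ij + α M_ij(t) }
```

with subject effects `b_ij ~ N(0, Σ_b)`, pair effect `u_i ~ N(0, σ_u²)`,
measurement error `ε ~ N(0, σ_e²)` and frailty `v_i ~ Gamma(mean 1, var θ)`.
The target of inference is α, the marker effect on the hazard, together
with the frailty variance θ.

Delayed entry is handled by the **updated gamma frailty distribution**:
conditioning on both twins surviving to their entry ages keeps the frailty
gamma, with the rate increased by the entry-age cumulative hazards.  All
pair-level marginal likelihoods are available in closed form over the
frailty, so fits are fast.

Four estimators of α are provided:

| method | marker value used in the hazard |
|---|---|
| `naive` | last observation carried forward; frailty *not* updated at entry |
| `locf`  | last observation carried forward; updated frailty |
| `orc`   | BLUP predictions on a dense age grid from one mixed model fit to all data |
| `rrc`   | BLUP predictions from mixed-model refits on the risk set at each event age |
| `jm`    | two-stage joint model: subject BLUPs plugged in, pair effect `u_i` shared between marker and hazard and integrated numerically |

## Worked example

```python
from twinjoint import (SimulationConfig, simulate_dataset,
                       build_locf_startstop, fit_frailty)

config = SimulationConfig(n_pairs=2000, alpha=1.0, seed=11)
dataset = simulate_dataset(config)          # delayed entry, complete pairs
table = build_locf_startstop(dataset)       # counting-process format
fit = fit_frailty(table, truncation_adjust=True)
```

Running `python examples/02_locf_fit.py` (the same computation) prints:

```
1640 pairs, 561 events, 12914 start-stop rows

truncation-adjusted LOCF fit (truth in brackets):
  alpha = 0.971 (se 0.309)   [1.0]
  theta = 0.258 (se 0.162)   [0.5]
  lambda= 0.00123, rho = 1.883   [0.001, 2.0]
naive fit (population frailty at entry): alpha = 0.970, theta = 0.269
```

Of 2000 simulated pairs, 1640 survive the truncation filter; the
truncation-adjusted LOCF fit recovers the generating marker effect
(α̂ = 0.97, truth 1.0) and frailty variance within sampling error.  The
`examples/` directory has one short script per capability: simulation,
LOCF, regression calibration, the two-stage joint model, and the
Monte-Carlo harness.

A thin CLI mirrors the library:

```
twinjoint simulate --out data/ --seed 1
twinjoint fit --method locf --data data/ --out fit.json
twinjoint mc --scenario src/twinjoint/scenarios/table1_a1.yaml --reps 200 --out results/
twinjoint summarize --result results/ --layout table1
```

## Scope

Complete pairs only (the likelihood conditions on both twins entering);
gamma frailty and parametric Weibull baseline; no competing risks, recurrent
events, or spline baselines.  See `docs/methods.md` for the estimation
details, numerical choices, and known limitations.
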