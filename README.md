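# spnma — shared-parameter network meta-analysis for competing risks and mixed data summaries

Aggregate-data (network) meta-analysis of binary outcomes routinely has to
combine trials that summarize the *same* outcomes in *different* ways:

* **format 1** — only each patient's **first** event is reported, after
  which the patient is censored (the outcomes are competing risks),
* **format 2** — the number of patients with **at least one** event of each
  outcome (a patient can count toward several outcomes, once each),
* **format 3** — the **total** number of events of each outcome, repeat
  events included.

The common shortcut is to feed every count into a binomial/logit
fixed-effect NMA with the number randomized as denominator, ignoring both
the format and the competing-risk structure.  `spnma` implements that
simple odds-ratio model alongside a **shared-parameter hazard-ratio model**
that gives each format its own likelihood while all formats inform one set
of underlying event hazards — plus the simulation, constructed-data and
asymptotic machinery needed to establish *when the two disagree* (roughly:
once any underlying event rate approaches 0.2 events per person-year).

## The models

For study *i*, arm *k*, outcome *m*, with treatment *t<sub>ik</sub>*,
*n<sub>ik</sub>* patients, person-years at risk *E<sub>ik</sub>* and mean
follow-up *T̄<sub>ik</sub> = E<sub>ik</sub>/n<sub>ik</sub>*:

**Shared-parameter model** — one hazard per cell, on the log scale

> log λ<sub>ikm</sub> = ω<sub>im</sub> + h<sub>t<sub>ik</sub>m</sub> − h<sub>t<sub>i1</sub>m</sub>,  h<sub>1m</sub> = 0

with format-specific likelihoods sharing the λ's:

| format | likelihood |
|---|---|
| 1 | R<sub>ik</sub> = Σ<sub>m</sub> r<sub>ikm</sub> ~ Poisson(E<sub>ik</sub> Σ<sub>m</sub> λ<sub>ikm</sub>), (r<sub>ik1</sub>…r<sub>ikM</sub>) ~ Multinomial(λ/Σλ, R<sub>ik</sub>) |
| 2 | r<sub>ikm</sub> ~ Bin(p<sub>ikm</sub>, n<sub>ik</sub>) with cloglog(p<sub>ikm</sub>) = log T̄<sub>ik</sub> + log λ<sub>ikm</sub>; a designated mortality outcome uses r ~ Poisson(E λ) |
| 3 | r<sub>ikm</sub> ~ Poisson(E<sub>ik</sub> λ<sub>ikm</sub>) |

Priors are mean-zero normals parameterized by precision: 0.5 (sd ≈ 1.41)
for both the study baselines ω<sub>im</sub> and the log hazard ratios
h<sub>tm</sub>, with a vaguer precision-0.05 variant (sd ≈ 4.47) available.
Exponentiated effects are hazard ratios versus treatment 1.

**Simple model** — r<sub>ikm</sub> ~ Bin(p<sub>ikm</sub>, n<sub>ik</sub>)
with logit(p<sub>ikm</sub>) = μ<sub>im</sub> + d<sub>t<sub>ik</sub>m</sub> −
d<sub>t<sub>i1</sub>m</sub> for every format alike, vague N(0, precision
10⁻⁴) priors; exponentiated effects are odds ratios.

Posteriors are sampled exactly with an in-package MCMC engine
(Laplace-preconditioned independence Metropolis by default, a
random-walk kernel as cross-check), with Brooks–Gelman–Rubin convergence
statistics for every parameter, and — crucial for simulation studies —
batched execution of hundreds of replicate fits in one vectorized run.

## Worked example

Simulate one replicate of the built-in 10-trial, 3-treatment, 2-outcome
network (all three formats, true log hazard ratios ±0.25, average event
rate 0.2) and fit both models:

```python
import numpy as np
from spnma import ScenarioSpec, simulate_dataset, fit, MCMCConfig, report_comparison

scenario = ScenarioSpec(target_rates=(0.2, 0.2))
dataset = simulate_dataset(scenario, np.random.default_rng(7))

shared = fit(dataset, model="shared", config=MCMCConfig(seed=1))
simple = fit(dataset, model="simple", config=MCMCConfig(seed=2))

table = report_comparison(shared, simple, truth=scenario)
```

which prints (model *a* = shared-parameter hazard ratios, model *b* =
simple odds ratios):

```
 treatment  outcome  hr_mean_a  hr_q2.5_a  hr_q97.5_a  hr_mean_b  hr_q2.5_b  hr_q97.5_b  true_ratio
         2        1      0.776      0.567       1.018      0.787      0.565       1.066       0.779
         2        2      1.019      0.752       1.320      1.123      0.802       1.544       1.284
         3        1      1.303      0.968       1.748      1.523      1.075       2.085       1.284
         3        2      0.784      0.575       1.041      0.800      0.568       1.086       0.779
```

At an event rate of 0.2 the two models already drift apart: the simple
model's odds ratios overshoot the true hazard ratios away from 1 (e.g.
1.523 vs truth 1.284 for treatment 3 on outcome 1) because an odds ratio
only approximates a hazard ratio when events are rare, and formats 1/3
counts are not really "patients out of n".  The shared-parameter estimates
stay close to the truth.  `max rhat` for the fit above was 1.004.

The same comparison on real data, a rate scan, count inflation and full
simulation cells are available from the command line:

```sh
spnma fit --data trials.csv --model shared --config config.yaml --out summary.csv
spnma inflate --data trials.csv --factor 10 --out inflated.csv
spnma check --grid 0.01:0.4:0.01 --effect -0.25 --out thresholds.csv
spnma simulate --rates 0.4,0.4 --nsim 300 --seed 1 --out results/
```

Every run writes a JSON manifest (config hash, seeds, versions) so any
number in any output is reproducible from its manifest.

## Layout

| module | contents |
|---|---|
| `spnma.data` | domain types, validation, long-format CSV I/O |
| `spnma.likelihoods` | exact log-densities for both models, priors |
| `spnma.inference` | MCMC fitting, diagnostics, effect summaries; `SharedParameterNMA` / `SimpleORNMA` |
| `spnma.simulation` | scenario design, synthetic trial generator, bias/coverage study |
| `spnma.constructed` | count-inflation stressor and average event rates |
| `spnma.equivalence` | rare-event equivalence checks between likelihoods and scales |
| `spnma.reporting`, `spnma.cli` | comparison tables, manifests, `spnma` CLI |

See `docs/methods.md` for the modelling and numerical details.
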