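# causalbind

Bayesian causal inference (BCI) modeling of audiovisual spatial
localization, for psychophysicists who measure the brain's *binding
tendency* — the prior probability that a sound and a flash presented
together came from one source — and ask whether it changes between
sessions (e.g., before and after an exposure manipulation).

The package provides, as importable modules and a command-line pipeline:

- the generative BCI observer model (8 free parameters, 3 decision
  strategies) with analytic posteriors and a fast vectorized simulator;
- simulation-based maximum-likelihood fitting of per-subject,
  per-session trial data, with strategy selection and goodness of fit;
- a synthetic-cohort generator that emulates the standard 35-condition
  localization design with known ground truth;
- the group analysis: per-subject binding-tendency difference scores,
  Cook's-distance outlier exclusion, and percentile-bootstrap confidence
  intervals within and between experiments.

## The model

On each bisensory trial the observer receives internal measurements

x_V ~ N(s_V + Δx_V·K, σ_V + |Δσ_V·K|),  x_A ~ N(s_A + Δx_A·K, σ_A),

where K ∈ {−2…2} indexes the five speaker azimuths (−13°, −6.5°, 0°,
6.5°, 13°). With a Gaussian spatial prior p(s) = N(μ_p, σ_p) the
observer computes the posterior probability that both signals share a
common cause,

p(C=1 | x_A, x_V) = p_c·p(x_A,x_V|C=1) / [p_c·p(x_A,x_V|C=1) + (1−p_c)·p(x_A,x_V|C=2)],

where p_c is the binding tendency. The common-cause estimate is the
precision-weighted fusion of x_A, x_V and the prior; the
independent-cause estimates shrink each measurement toward the prior
alone. A decision strategy maps the posterior to the reported location:
**model averaging** (posterior-weighted mix), **model selection**
(threshold at 0.5), or **probability matching** (threshold at a fresh
uniform draw each trial). The 8 free parameters are
(p_c, μ_p, σ_p, σ_V, Δσ_V, Δx_V, σ_A, Δx_A).

Fitting maximizes a simulated likelihood: 10,000 trials per condition
are simulated (2,000 in the reduced test configuration), binned at 1°
over ±45°, floor-smoothed, and each observed response scores the log
mass of its bin; a bounded Nelder-Mead simplex (sinusoidal
reparameterization, multiple restarts, common random numbers) does the
search. See `docs/methods.md` for every numerical choice.

## Worked example

```python
import numpy as np
from causalbind import (
    ModelParameters, DecisionStrategy, StimulusCondition,
    posterior_common, simulate_responses,
)
from causalbind.model import TrialLatents

observer = ModelParameters(
    p_common=0.35, mu_prior=0.0, sigma_prior=25.0,
    sigma_v=2.0, delta_sigma_v=0.3, delta_x_v=0.0,
    sigma_a=8.0, delta_x_a=0.0,
)

# one maximally discrepant trial: sound at +13, flash at -13
lat = TrialLatents(x_a=10.2, x_v=-12.8, xi=0.5)
print("p(C=1 | x_A=10.2, x_V=-12.8) =",
      round(posterior_common(lat, observer, k_v=-2), 4))

rng = np.random.default_rng(0)
cond = StimulusCondition(s_a=13.0, s_v=-13.0)
resp_a, resp_v = simulate_responses(
    observer, DecisionStrategy.MODEL_AVERAGING, cond, 10_000, rng)
print("mean auditory response:", round(resp_a.mean(), 2))
print("mean visual response:  ", round(resp_v.mean(), 2))

stronger = ModelParameters(**{**observer.to_dict(), "p_common": 0.75})
resp_a2, _ = simulate_responses(
    stronger, DecisionStrategy.MODEL_AVERAGING, cond, 10_000,
    np.random.default_rng(0))
print("mean auditory response at p_common=0.75:", round(resp_a2.mean(), 2))
```

prints

```
p(C=1 | x_A=10.2, x_V=-12.8) = 0.043
mean auditory response: 10.86
mean visual response:   -12.75
mean auditory response at p_common=0.75: 8.74
```

With 26° of audiovisual discrepancy the causal posterior collapses to
0.04 — the observer segregates. Raising the binding tendency from 0.35
to 0.75 pulls the mean auditory localization from 10.9° to 8.7° toward
the discrepant flash (the ventriloquist pull), while the visual response
barely moves because vision is far more precise.

## Command-line pipeline

```bash
causalbind simulate --seed 1 --n-subjects 5 --label exp5 --delta-p-common 0.15 --out cohort/
causalbind fit cohort/trials_*.csv --seed 1 --out fits/
causalbind analyze fits/fit_*.json --seed 1 --control exp1 --out analysis/
causalbind oracle-check
```

`simulate` writes per-subject trial tables plus a ground-truth table;
`fit` writes one JSON per subject/session (skips existing outputs unless
`--force`); `analyze` writes the experiment-summary table and an audit
JSON with every seed, exclusion, and Cook's distance.

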