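# Methods

## Observer model

The generative model treats each trial of an audiovisual localization
task as Bayesian causal inference. True source azimuths s_A, s_V come
from five speaker positions (−13°, −6.5°, 0°, 6.5°, 13°; eccentricity
code K = azimuth/6.5 ∈ {−2…2}). The observer's internal measurements
are corrupted by Gaussian sensory noise with eccentricity-dependent
terms:

- x_V ~ N(s_V + Δx_V·K_V, σ_V + |Δσ_V·K_V|)
- x_A ~ N(s_A + Δx_A·K_A, σ_A)

Negative Δx values model central (foveal/medial) bias, positive values
peripheral bias; Δσ_V lets visual precision degrade away from fixation.
A Gaussian spatial prior p(s) = N(μ_p, σ_p) is shared by every causal
branch and both modalities. The binding tendency p_c = p(C=1) is the
prior probability that the two signals share one cause.

Conditional on the causal structure, the location posteriors are
conjugate-Gaussian and their MAP estimates are precision-weighted
means: fusion of x_V, x_A and the prior under C=1, and per-modality
shrinkage toward the prior under C=2 (the C=2 form also models the
unisensory trials). The causal posterior combines the two marginal
likelihoods, which have closed forms (a bivariate Gaussian in
(x_A, x_V) for C=1, a product of two univariate Gaussians for C=2).
All densities are evaluated in log space; the posterior is computed on
the log-odds scale, so discrepancies large enough to underflow both
densities still yield a well-defined posterior.

Three read-out strategies map the posterior to reported locations:
model averaging (posterior-weighted mix of the conditional estimates),
model selection (common-cause branch iff p(C=1|x) > 0.5; ties
segregate), and probability matching (common-cause branch iff
p(C=1|x) > ξ, with ξ uniform on [0, 1) re-drawn each trial; the strict
comparison means certainty always integrates).

Two modeling asymmetries deserve emphasis because they are easy to get
wrong. First, the Δx/Δσ eccentricity terms act only on the *sampling*
of measurements; the observer's inference treats its measurement as an
unbiased Gaussian observation (the internal model does not know about
its own bias). Second, the inference uses the visual noise σ_V'
evaluated at the trial's true K_V — the only eccentricity available per
trial. No motor or report noise is added anywhere; all response
variability is sensory.

## Free parameters

| parameter | meaning | units | bounds | neutral start |
|---|---|---|---|---|
| p_common | binding tendency p(C=1) | — | [0, 1] | 0.5 |
| mu_prior | spatial-prior mean | deg | [−20, 20] | 0 |
| sigma_prior | spatial-prior s.d. | deg | [0.1, 45] | 20 |
| sigma_v | visual noise at center | deg | [0.1, 45] | 3 |
| delta_sigma_v | visual-noise slope per K | deg | [0, 10] | 0 |
| delta_x_v | visual bias slope per K | deg | [−5, 5] | 0 |
| sigma_a | auditory noise | deg | [0.1, 45] | 8 |
| delta_x_a | auditory bias slope per K | deg | [−5, 5] | 0 |

## Simulated likelihood and optimization

The response densities have no closed form once a decision strategy is
applied, so the likelihood is built by simulation. For each stimulus
condition present in the data, n_sim trials are simulated (default
10,000; the test and acceptance harnesses use 2,000 and record it),
responses are binned at 1° over [−45°, 45°], 10⁻⁵ mass is added to
every bin before renormalizing (so no observed response scores −∞), and
each observed response contributes the log mass of its bin; bisensory
trials contribute both modalities. Observed responses outside ±45° are
clipped into the edge bins with a warning.

The standard-normal and uniform draws behind the simulation are frozen
per condition at the start of a fit (common random numbers), making the
objective a deterministic function of the parameters — without this,
simplex search stalls on objective noise. Optimization is Nelder-Mead
under box bounds via the sinusoidal reparameterization
x = lb + (ub − lb)(sin u + 1)/2, so every candidate satisfies the
bounds exactly. Two numerical details matter: an explicit initial
simplex with 0.25-radian per-coordinate steps (the default perturbation
is ~10⁻⁴ for zero coordinates, which would freeze the neutral start's
p_common and bias terms), and multiple restarts — one neutral point and
the rest uniform within bounds — because the surface has genuine local
optima (the restarts are cheap insurance and demonstrably rescue fits).
Defaults: 3 restarts, tolerance 10⁻³ on parameters and objective, at
most 2,000 evaluations per restart (the harnesses use 300 and record
it). Each subject and session is fit independently; the three
strategies have equal parameter counts, so the best strategy is the raw
maximum-likelihood one.

Fit quality is summarized by R², the squared Pearson correlation
between observed and predicted binned response frequencies concatenated
over all conditions and modalities. R² uses 5° bins, deliberately
coarser than the likelihood's 1° bins: with 15 trials per condition the
observed frequencies of ninety 1° bins are dominated by multinomial
sampling noise, which caps the statistic near 0.5 *at the generating
parameters*; at 5° the same comparison reaches ≈ 0.86 at truth, so the
statistic measures fit rather than bin-level shot noise. The definition
is recorded in every output as `r2_binned_5deg`.

## Synthetic cohorts

The generator emulates the study design: 5 unisensory auditory + 5
unisensory visual + 25 bisensory conditions, 15 trials each (525 trials
per session), shuffled into pseudorandom order, two sessions (pre,
post) per subject. Ground-truth parameters are drawn per subject from
population distributions chosen to put the observer in the regime the
model assumes — auditory noise well above visual, weak central prior:
p_c ~ Beta(2, 4); σ_A ~ logN(ln 8, 0.4); σ_V ~ logN(ln 2, 0.4);
σ_p ~ logN(ln 25, 0.3); μ_p ~ N(0, 2); Δx_V, Δx_A ~ N(0, 0.5);
Δσ_V ~ |N(0, 0.5)|; all draws clipped to the fitting bounds. A cohort's
pre→post manipulation is an injected additive shift of p_c (clipped to
[0, 1]); every other parameter is held fixed across sessions, and each
subject keeps one decision strategy throughout. The generator does not
model the exposure phase, learning dynamics, response order, breaks, or
lapses — so passing tests show that the pipeline recovers what this
generative model produces, not that the model is true of human data.

Randomness everywhere derives from named substreams of a single master
seed (per subject, session, and purpose), so any artifact can be
regenerated in isolation; seeds are echoed into every output file.

## Group analysis

The unit of group inference is the per-subject difference score,
fitted p_c(post) − p_c(pre). Before bootstrapping, a single-pass
outlier screen fits OLS of post-test on pre-test binding tendency and
drops subjects whose Cook's distance exceeds 4× the experiment's mean
Cook's distance (an intercept-only variant is available when the
regression is degenerate; a perfect fit yields all-zero distances and
no exclusions). The within-experiment analysis draws 10,000 resamples
of the scores with replacement and reports the mean of resample means
with the percentile 95% CI (2.5th/97.5th percentiles of the stored
bootstrap distribution). The between-experiment analysis resamples the
two experiments' scores independently on each of 10,000 iterations and
records the difference of resample means. The categorical call for an
experiment is "none" unless its within-CI excludes zero; the
versus-control CI then grades the call, with "marginal" when the CI
endpoint nearest zero lies within ±0.01 of it (a reporting convention,
recorded in the audit output).

## Evaluation harnesses and problem sizes

The recovery study draws subjects from the population priors, simulates
one 525-trial session each, and refits with the generating strategy
supplied, at n_sim = 2,000, 3 restarts, 300 evaluations per restart.
At 20 subjects the median absolute error of the fitted binding tendency
is ≈ 0.07–0.13 (seed-dependent), and quadrupling trials per condition
(15 → 60) shrinks it — the per-subject error is dominated by the
genuine flatness of the likelihood when σ_A is large, not by the
optimizer, which we verified by comparing the simulated likelihood at
truth versus at the fitted point.

The group-pipeline calibration runs on score level: emulated fitted
binding tendencies equal to truth plus Gaussian fit noise with s.d.
0.12 per session (set from the recovery harness's error spread),
clipped to [0, 1]. Null cohorts (n = 25) produce a within-experiment CI
excluding zero in ≈ 5–8% of 200 replicates; a +0.15 shift at n = 29 is
detected in ≈ 100%. The six-experiment suite injects the shift only in
"exp5" and runs the full pipeline (exclusion + both bootstraps); the
expected output calls an increase for exp5 and none elsewhere, with the
calibrated ≈ 5% false-positive rate per null experiment.

## Known limitations

- The simulated likelihood at n_sim = 2,000 carries enough histogram
  noise that individual fits can miss p_c by ~0.2 when auditory noise
  is high; medians over subjects are the reliable summary at that
  budget, and n_sim = 10,000 (the default) tightens individual fits.
- Sessions are fit fully independently; no parameter sharing or
  hierarchical pooling across subjects or sessions.
- The azimuth axis is linear with no wrap-around, appropriate only for
  the ±13° stimulus range (responses are histogrammed over ±45°).
- Strategy identification is intrinsically soft — the three strategies
  mimic each other over much of parameter space — so the package
  selects the max-likelihood strategy but makes no claim of strategy
  recovery guarantees.
- The exposure manipulation that would cause a binding-tendency change
  is represented only as an injected parameter shift, never modeled
  mechanistically.
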