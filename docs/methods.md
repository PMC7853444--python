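# Methods

`copefr` analyses small-arena predation trials in which a single cyclopoid
copepod (*Macrocyclops albidus* or *Megacyclops viridis*) is offered
newly-hatched *Aedes albopictus* larvae for a fixed period, with
predator-absent control dishes run alongside. Two designs are supported: a
functional-response arm (a gradient of initial densities) and a
predation-efficiency arm (a constant density near the saturation plateau).

## The depletion model and its likelihood

Prey are not replaced during a trial, so the functional response must be
integrated through the prey-depletion ODE

    dN/dt = - b N^(1+q) / (1 + b h N^(1+q)) P - m N

with

| symbol | meaning | units | default / range |
|---|---|---|---|
| `b` | attack coefficient | arena · predator⁻¹ · h⁻¹ | estimated; start 1.0 |
| `h` | handling time (time lost from searching per prey) | h · prey⁻¹ | estimated; start 1/max feeding rate |
| `q` | shape exponent, type II (0) vs type III (1) | — | fixed by the classifier, never estimated |
| `m` | background per-capita prey mortality | h⁻¹ | estimated from controls; start 0.01 |
| `P` | predators per arena | count | 0 or 1 |
| `T` | trial duration | h | 6 |

The observation model is binomial: with `N(T)` the ODE solution from
`N(0) = N0`, the count of prey missing at the end of a trial is
`Binomial(N0, 1 - N(T)/N0)`. Missing prey count as eaten in treatments and
dead in controls; the split between the predation and mortality hazards is
carried entirely by the ODE. Two likelihood variants exist:

- **with mortality** — treatments and controls pooled in one likelihood
  with `m` free. Used whenever control deaths occurred. Controls (`P = 0`)
  depend only on `m` and identify it.
- **no mortality** — treatment dishes only, `m = 0`. Used when no control
  deaths occurred, or when the with-mortality fit's Wald test of `m`
  (two-sided, from the finite-difference observed information) is
  insignificant at 0.05.

For `q = 0`, `m = 0` the model has the Rogers random-predator closed form:
remaining prey `= W0(b h N0 exp(b h N0 - b P T)) / (b h)` with the
principal Lambert-W branch. For `q = 0`, `m > 0` the ODE is separable and
is solved *exactly* through its implicit partial-fraction solution with a
bracketed vectorized Newton iteration; no discretization error enters the
likelihood. Only the `q = 1` branch integrates numerically (fixed-step
RK4, 400 steps over 6 h). The stand-alone predictor `predict_remaining`
uses adaptive integration (rtol 1e-10, atol 1e-14, tight enough that
survivor fractions below 1e-5 retain six significant figures) and is
pinned against the closed forms in the test suite.

Optimization is Nelder-Mead on log-transformed parameters (positivity
without constraints, robustness to the flat likelihood surfaces these
designs produce) with three jittered restarts from the conventional
starting values. Predicted loss probabilities are clamped to
`[1e-12, 1 - 1e-12]` with a warning before entering the binomial.

### Profile confidence intervals

95% intervals for `b` and `h` are profile-deviance intervals: the bound is
where the profiled NLL (nuisance parameters re-optimized, warm-started)
rises by `chi2(1, 0.95)/2 = 1.9207` above the minimum. Bounds are located
by geometric bracketing then Brent root-finding on the log scale; because
the profile is itself the result of an inner optimization it carries
~1e-6 noise, so an endpoint already sitting on the threshold is accepted
as the bound. If the profile never crosses the threshold within
`estimate x 1e4` on a side, that side is reported unbounded — the
behaviour a weakly identified attack coefficient produces. Cross-group
differences are called significant only when two intervals are disjoint;
unbounded intervals conservatively overlap everything.

## Response-type classification

Type is read off logit-link binomial polynomial regressions of prey
killed against initial density (predator-present trials only), fitted by
IRLS. The quadratic model is fitted first; a positive significant
first-order term demands a negative significant second-order term for a
type III call, otherwise the linear model's negative significant
first-order term makes the type II call; anything else — including
non-convergence or logit-scale coefficients beyond ±20, which indicate
separation — is inconclusive. Significance level defaults to 0.05. The
fallback order when quadratic and linear fits disagree is a documented
package choice; with fewer than four distinct densities only the linear
call is available.

## Predation efficiency

Abbott's formula corrects predation for background mortality:
`efficiency = 100 (alive_control - alive_treatment) / alive_control`,
computed per matched treatment-control pair at the same temperature. With
8 controls serving 16 treatments per temperature, the assignment is a
seeded random balanced allocation (each control serves two treatments) —
the mapping is not recoverable from the design, so it is explicit and
reproducible. Negative efficiencies (treatment outliving control) are
legitimate values, not errors.

Six OLS models explain efficiency: species and mass each alone, with
temperature, and with a first-order temperature interaction. Categorical
coding is treatment contrasts with *M. albidus* and 15 °C as references.
AIC uses the full Gaussian log-likelihood with the error variance counted
as a parameter, so nested differences equal
`n log(RSS_small/RSS_big) - 2 dk` exactly; a model is preferred only with
a lead of at least 2. Distribution summaries use moment skewness and
plain (non-excess) kurtosis, so a normal population scores 3.

## Body-size analysis

Lengths (mm) convert to mass by the crustacean allometric law
`mass = 0.055 length^2.73` (mg). Species comparisons are gated on
Shapiro-Wilk normality of each sample at alpha 0.05: Welch's t when both
pass, Wilcoxon rank-sum (midranks, tie-corrected variance, continuity
correction) otherwise. Cross-arm comparison pairs individuals across
species uniformly at random without replacement, dropping surplus
individuals of the larger group at random — surplus handling is explicit
because real datasets lose the odd record — and differences
(viridis - albidus, mg) from both arms are compared by rank-sum.

## Synthetic data

The generator reproduces the study conditions: densities 1, 2, 4, 8, 16,
24, 32 in 20 mL arenas, four predator replicates and one control per
density for each of six species x temperature combinations (2,610 larvae,
168 predators), and per temperature 8 + 8 treatment and 8 control dishes
of 24 larvae in the efficiency arm (1,728 larvae). Group-level background
mortality defaults to the observed control mortality fractions (3/5/13%
for *M. albidus* and 2/3/0% for *M. viridis* at 15/20/25 °C over 6 h)
converted to hourly rates; attack and handling default to b = 1.0,
h = 0.5 h. Copepod lengths are truncated normals inside the published
adult ranges (albidus 1.3–2.5 mm, viridis 1.2–3.0 mm) with means 1.7 and
2.1 mm and SDs 0.2 and 0.25 mm — the means/SDs are synthetic conventions
(no within-group variance is published), chosen only to respect the
ranges and the observed species size ordering. Efficiency-arm truth is a
linear predictor of expected Abbott efficiency (default intercept 9.72%,
mass slope 34.44 %/mg, no temperature effect) realized through binomial
survivor draws; control mortality defaults to 5/11/3% at 15/20/25 °C.

Two stochastic modes: *binomial* draws missing prey as
`Binomial(N0, 1 - N(T)/N0)` — identical in distribution to the fitted
likelihood, making parameter recovery a proper self-consistency check —
and *gillespie* simulates the continuous-time Markov chain whose
mean-field limit is the ODE, one prey removed per event with total hazard
`P b N^(1+q)/(1 + b h N^(1+q)) + m N`. The Gillespie mode treats the
response as an instantaneous hazard with no explicit busy-predator state;
that is the same mean-field idealization the fitted model makes, so it
probes demographic stochasticity, not model misspecification. What the
generator does **not** emulate: overdispersion between dishes, predator
individual variation in b/h, size-dependent attack rates, and
arena-geometry effects — passing recovery tests therefore demonstrates
internal consistency of the estimation machinery, not robustness to every
feature of real data.

## Validation strategy and problem sizes

Every closed form is pinned against an independent route (adaptive ODE vs
Lambert-W vs implicit solution vs brute-force RK4 at step 1e-4), the
rank-sum test against exact enumeration at n = 4 + 4, Welch against the
hand formulas, and the Gillespie pure-death limit against its analytic
binomial by chi-square at 10,000 replicates. Simulation studies use one
35-dish group per replicate: 200 replicates for parameter recovery and
profile-CI coverage (median b and h within 15% of truth; coverage >= 85%
at nominal 95%), 100 for response-type power, 100 + 100 for
mortality-variant power and size, and 200 for the efficiency-slope
recovery at n = 47 — sizes chosen so each study resolves the tested rate
to a few percent. The likelihood-dominance check (truth vs doubled attack
rate) wins ~86% of seeds with a strongly positive mean NLL gap:
handling-time saturation masks attack-rate changes at high density, a
real identifiability feature of this design, which is also why attack
coefficients profile wide.

## Known limitations

- `q` is never estimated; intermediate shapes are out of scope.
- No dish-level random effects or overdispersion in either arm; the
  reference analysis fits plain likelihoods and OLS, and so does this
  package.
- With-mortality fits pool controls and treatments in one likelihood;
  estimating `m` solely from controls would be a small variation not
  implemented.
- The body-length exclusion threshold (default 1.2 mm, the low end of the
  published adult ranges) is a configurable convention, not an inferred
  value.
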