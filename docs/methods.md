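# Methods

## The model

Let T be the presentation number (1…10) at which an object outline is first
named correctly; trials with no correct naming by the horizon are
right-censored at presentation 10. The discrete-time hazard
h(t) = P(T = t | T ≥ t) is modelled on the complementary log-log scale,

    cloglog h(t) = ln(−ln(1 − h(t)))
                 = α₀ + α₁(TIME−c) + … + α_d(TIME−c)^d
                   + Σ_j β_j · X_j · (TIME−c)^{p_j},

where the α's describe the baseline hazard as a degree-d polynomial of
centred presentation number and each covariate term is a product of binary
dummies (Patient, Manmade, Symmetry, Complex, MP, Repetition) times a power
of centred time. The cloglog link is the discrete-time counterpart of a
continuous-time proportional-hazards model: an additive shift a on the
linked scale multiplies the cumulative-hazard increment by exp(a), which is
reported as a hazard ratio, the convention in this literature (strictly it
is a ratio of cumulative-hazard increments, not of the discrete hazards
themselves; the package reports it under the customary name without
reinterpreting it).

Estimation works on the person-period expansion: a trial with event at
presentation k contributes k Bernoulli observations with EVENT = 0,…,0,1, a
censored trial contributes 10 zeros, and the likelihood
Σ [EVENT·ln h + (1−EVENT)·ln(1−h)] is then an ordinary binary-regression
likelihood. This is exact for right-censored discrete-time data under
noninformative censoring.

### Defaults and parameters that matter

- `baseline_degree` defaults to 4. The published final model carries a
  quartic time polynomial even though the model-equation exposition stops at
  the cubic; the quartic is what the printed coefficient table contains, so
  it is the default, and the degree is configurable.
- `center` defaults to 1 (first presentation), so power-0 coefficients
  describe effects at the first presentation. `FitResult.recenter(c)`
  re-expresses the fit around any presentation by the exact binomial-shift
  reparameterization (see below), which is what the published recentred
  columns correspond to.
- Terms are named in product style (`Manmade*Symmetry*PT^2`); covariate
  order is normalized alphabetically, `PT^0` is elided and `PT^1` prints as
  `PT`. A colon before the time factor is accepted on input.

## Fitting and inference

Newton–Raphson on the cloglog-binomial likelihood, using the observed
information as the Hessian with a Fisher-scoring fallback when it is not
invertible, and step-halving whenever a step would decrease the likelihood.
Convergence is declared when the relative log-likelihood change falls below
1e-10, with a cap of 100 iterations. The linear predictor is clipped to
±30 inside the likelihood for floating-point safety (hazards are then
bounded away from 0/1 by ~1e-13, far outside any data-supported range).
Estimates whose magnitude exceeds 15 on the cloglog scale abort with a
separation error; a rank-deficient design aborts with the offending columns
named.

Covariances:

- model-based: inverse observed information at the optimum;
- cluster-robust: the sandwich A⁻¹BA⁻¹ with cluster-summed scores in the
  meat and a G/(G−1) small-sample factor; confidence intervals use t(G−1)
  critical values, the standard prescription when clusters are few. Wald
  statistics are reported as χ²(1) = (PE/SE)², matching the convention of
  the published coefficient table.

The cluster unit is configurable and defaults to the participant, the
conservative choice for real repeated-measures data. One caveat the user
should understand: with a single patient among eight participants, a
participant-level sandwich cannot estimate between-cluster variance for the
patient contrast (there is one treated cluster), and its CIs for that
coefficient are far too short — in our simulations, 52% coverage at nominal
95%. The simulation-based validation studies therefore cluster on the trial,
which is the actually independent unit of the generator; with trial
clustering, pooled coverage across the ten coefficients of the recovery
study is 95.4% (200 replicates). For real data with suspected
participant-level dependence, model-based or participant-clustered intervals
for the patient effect should both be treated with caution; this is a
limitation of the design, not of any estimator.

### Recentring

Within each covariate product the model is a polynomial in (TIME − c);
re-expanding around c′ via the binomial theorem gives an exact linear map
M with β′ = Mβ, applied to estimates and both covariances (V′ = MVMᵀ). The
map exists whenever the power set of each product is downward closed, which
hierarchical closure guarantees. Likelihood and every predicted function are
invariant (verified to 1e-8 in the tests, and against a full refit at the
new centre).

## Backward selection

Starting from the full model — all five main effects, their ten two-way
interactions, linear and quadratic time interactions for each of those
fifteen products, the repetition control, and the baseline time polynomial —
terms are removed one at a time: at each step the removable term (not
marginal to any retained term; the intercept never) with the largest Wald
p-value above `alpha_crit` (default 0.05, the conventional level) is
dropped and the model refitted. Ties are broken toward the higher time power
and then alphabetically, so runs are deterministic. One term per step; the
trace records every removal with its p-value so alternative schedules can be
audited.

## The simulator

The generator reproduces the study conditions: 7 controls plus one patient;
100 objects, 51 manmade; symmetric with probability .51 (manmade) and .31
(natural), implemented as fixed per-category counts so the composition is
exact in every dataset; complexity Bernoulli(.5) independent of category
(the original dichotomization of the outline-homogeneity measure is not
reproducible without the stimulus set, so this is a neutral stand-in);
each object once per fragmentation type, 200 trials per participant, order
randomized under the no-adjacent-repeat constraint by shuffle with local
swap repair (the original scheduler is unspecified; any scheduler
satisfying the constraint is admissible); geometric fragmentation schedule
with α = .77 over 10 levels, rounding half-up (which reproduces the
published percentage sequence exactly, including 100·0.77⁹ = 9.52 → 10).
Outcomes are drawn presentation-by-presentation from the specified hazard
model; the default truth is the published model's quartic baseline plus its
six time-invariant main effects. The patient is simulated purely through the
Patient dummy (and any interactions present in the supplied coefficients) —
no separate generative mechanism. A single seeded generator produces the
whole dataset, with the trial-level uniforms drawn in trial order, so equal
seeds give byte-identical output files.

What the simulator does **not** emulate: participant-level random effects
(controls are exchangeable), object-level recognizability differences beyond
the four coded factors, semantic/lexical response processes, reaction times
in milliseconds, and learning across sessions. Passing recovery tests
therefore show that the estimator chain is correct under the stated model,
not that the model captures every dependence present in real data.

## Numerical and design choices

- Life-table hazards at an empty risk set are reported as missing with a
  warning, never as zero; survivor estimation stops at the last estimable
  presentation.
- The saturated-model cross-check of the life table uses one indicator per
  time bin rather than a degree-(T−1) polynomial, whose Vandermonde matrix
  is numerically rank deficient over ten presentations.
- The fitter is cross-checked on small instances against a derivative-free
  optimizer of the same likelihood (agreement to 1e-6) and against an
  independent IRLS implementation (statsmodels GLM with a cloglog link).
- The transcribed published coefficient table ships inside
  `fragsurv.published`; its recentred columns agree with exact recentring of
  the presentation-1 estimates to within 0.005 everywhere (differences are
  transcription rounding). One derived value in the source is internally
  inconsistent: the printed baseline survivor S(5) = .05, while the printed
  coefficients give 0.0442 — including when the baseline polynomial is
  re-derived by interpolating the five printed recentred intercepts, so the
  inconsistency is not a transcription artifact. The replication report
  computes the honest value and flags the row instead of correcting either
  side.
- Validation problem sizes: the recovery study runs 50 replicates of the
  full 8×200-trial design against the ten-term truth; the selection study
  runs 100 replicates of a 6-control, 50-object design with one injected
  pure-noise dummy. Both were chosen so the whole suite runs comfortably on
  a laptop while leaving Monte-Carlo error well below the decision margins.

## Known limitations

- No frailty / random-effects hazards, no continuous-time Cox model, no
  Firth penalization for separated data, no Greenwood variance bands.
- Wald-based selection can behave poorly near separation; the fitter
  detects and refuses separated fits rather than silently returning huge
  estimates.
- The hazard-ratio label follows the field's convention (see above) and is
  exact only as a cumulative-hazard-increment ratio.
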