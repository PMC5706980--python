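# fragsurv

Discrete-time survival (event-history) analysis of repeated-presentation
("build-up") object-identification experiments.

In a build-up paradigm a fragmented object outline is shown again and again —
with more of the contour revealed at each step — until the observer names the
object correctly or the presentation sequence runs out. The natural datum is
*which presentation* (1–10) produced the first correct naming, and trials with
no correct naming by the last presentation are right-censored. Means of such
data are biased; the principled summary is the discrete-time hazard

    h(t) = P(T = t | T >= t),

the conditional probability of correct identification at presentation *t*
given failure before it, together with the survivor function
S(t) = P(T > t) = ∏_{j≤t} (1 − h(j)). `fragsurv` is written for
psychophysicists and neuropsychologists analysing such paradigms — in
particular designs contrasting a single patient with a group of controls
across stimulus factors (object category, symmetry, outline complexity,
fragment type, trial repetition).

## What it implements

- **Experiment simulator** — the full design: 7 controls + 1 patient, 100
  objects (51 manmade / 49 natural, symmetry more frequent among manmade),
  each object shown once per fragmentation type (MP / SP) for 200 trials per
  participant, order randomized so that no object occupies two consecutive
  trials, and a geometric contour schedule `100·α^(n−x)` (α = .77: 10, 12,
  16, 21, 27, 35, 46, 59, 77, 100 percent). Outcomes are drawn
  presentation-by-presentation from a known hazard model.
- **Person-period expansion** — one row per presentation at risk, with
  `TIME`, a binary `EVENT`, and centred-polynomial design matrices.
- **Life tables** — nonparametric ĥ(t) and Ŝ(t), overall or per condition.
- **Cloglog hazard GLM** — maximum likelihood for

      cloglog h(t) = ln(−ln(1 − h(t)))
                   = [α₀ + α₁(TIME−c) + … + α_d(TIME−c)^d] + Σ_j β_j X_j (TIME−c)^{p_j}

  by Newton–Raphson, with model-based (observed information) and
  cluster-robust (sandwich) covariances, Wald χ²(1) statistics, exact
  recentring of the time polynomial on any presentation *c*, hazard ratios
  `HR = exp(β)`, and model-implied cloglog[h(t)], h(t), S(t) per condition.
- **Backward model selection** under the hierarchical principle (a term is
  removable only when no retained higher-order term contains it).
- **Replication module** — a transcribed copy of the published 61-term final
  model from the study this package emulates, and a report that recomputes
  every derived value printed there (baseline hazards, survivor value,
  hazard ratios, recentred coefficients) at printed precision.

Everything is exposed both as scikit-learn-style estimators
(`PersonPeriodExpander`, `LifeTableEstimator`, `CloglogHazardGLM`,
`BackwardSelector`) and as plain functions, plus a thin `fragsurv` CLI
(`simulate`, `expand`, `lifetable`, `fit`, `select`, `predict`, `replicate`,
`pipeline`).

## Worked example

```python
import fragsurv as fs

cfg = fs.SimulationConfig(seed=7)               # the full 8-participant design
trials = fs.simulate_dataset(cfg)
pp = fs.expand_to_person_period(fs.encode_predictors(trials))
print(f"{len(trials)} trials -> {len(pp)} person-period rows")

lt = fs.estimate_lifetable(pp, by=["is_patient"])
print(lt[lt.TIME.isin([1, 5, 10])].round(3).to_string(index=False))

spec = fs.HazardModelSpec(baseline_degree=4, center=1,
                          terms=("Repetition", "Manmade", "Symmetry",
                                 "Complex", "Patient"))
fit = fs.fit_hazard_model(pp, spec)
print(fit.wald().round(4))
print(f"log-likelihood {fit.loglik:.1f}, "
      f"hazard ratio (Patient) {fit.hazard_ratio('Patient'):.3f}")
```

prints

```
1600 trials -> 6328 person-period rows
 is_patient  TIME  n_at_risk  n_events  hazard  survivor
          0     1       1400       794   0.567     0.433
          0     5        374        40   0.107     0.239
          0    10        206        35   0.170     0.122
          1     1        200        15   0.075     0.925
          1     5        173         4   0.023     0.845
          1    10        156         3   0.019     0.765
            estimate      se  wald_chi2    p
Intercept     0.5076  0.0635    63.9498  0.0
PT           -1.5062  0.0818   338.7282  0.0
PT^2          0.4977  0.0523    90.6619  0.0
PT^3         -0.0665  0.0102    42.5535  0.0
PT^4          0.0032  0.0006    26.1396  0.0
Repetition    0.6055  0.0328   341.3299  0.0
Manmade      -0.3606  0.0309   136.0914  0.0
Symmetry     -0.9769  0.0829   138.8837  0.0
Complex      -0.7662  0.0910    70.8810  0.0
Patient      -2.5360  0.0710  1276.0970  0.0
log-likelihood -2171.0, hazard ratio (Patient) 0.079
```

Controls identify over half the objects on the very first (10% contour)
presentation, whereas the patient's hazard never leaves the low single digits
and three quarters of his trials survive the whole sequence. The fitted
coefficients recover the generating values (the simulation truth is the
published model's main-effect structure): e.g. `Patient = −2.54` against a
truth of −2.45, i.e. the patient's identification hazard is about
`exp(−2.5) ≈ 0.08` times the controls' on the first presentation.

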