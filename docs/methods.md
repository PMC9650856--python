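# Methods

`stepsel` implements an integrated step-selection analysis (iSSA) for
GPS-tracked animals on seasonally dynamic landscapes, together with a
forward simulator that generates data from the same model family so the
whole pipeline can be validated by parameter recovery.

## Model

Movement is decomposed into 4-h *steps*. For each observed (used) step, nine
*available* steps are sampled from an empirical movement kernel sharing the
used step's start point and time; the ten form one *stratum*. Habitat
selection is the conditional (matched) logistic model

```
P(step i used | stratum s) = exp(beta' x_i) / sum_{j in s} exp(beta' x_j)
```

maximised over strata by Newton–Raphson on the partial log-likelihood

```
l(beta) = sum_s [ beta' x_case(s) - log sum_{j in s} exp(beta' x_j) ].
```

`x` holds, per step endpoint: the NDVI anomaly (aNDVI), the 16-day NDVI
change (dNDVI), elevation, terrain ruggedness (TRI) and temperature; the
movement correction terms *step length* and *log step length* (which absorb
the gap between the tentative gamma kernel and the true step-length
distribution — the gamma family is a two-parameter exponential family with
exactly these sufficient statistics); quadratics for aNDVI, dNDVI and (dry
season only) temperature; and one-way interactions of each base term with
two stratum-constant moderators, post-release **experience** (days since
release) and chain-rule **group size**. Because the moderators are constant
within a stratum, their main effects cancel from the conditional likelihood
and are excluded from the estimable design; a `keep_inestimable` option
appends them for inspection/export, but fitting such a design fails with a
clear diagnostic — the information matrix is exactly singular, so the
estimator cannot produce the near-zero/huge-SE estimates one might expect
from merely *nearly* constant columns.

Four nested candidate tiers are compared per season by AICc: M1
(environment only), M2 (+ experience interactions), M3 (+ group-size
interactions), M4 (both). AICc uses `n = number of strata` — the
independent contributions to the conditional likelihood; step counts or row
counts would overstate the information. Ties rank toward smaller `k`.
Temperature's quadratic and interactions appear only in the dry-season
roster, where thermal stress is the operative constraint; the wet-season
roster omits them.

### Variance

The naive covariance is the inverse observed information. Because strata
from one animal are serially dependent, inference uses the cluster-robust
sandwich `A^-1 B A^-1`, clusters = animals, with the CR1 small-sample factor
`G/(G-1)` on `B`: studies of this kind track tens of animals, not hundreds,
and the uncorrected sandwich is anticonservative at that cluster count.
P-values are two-sided from the normal reference distribution on robust SEs.

### Standardization

Base covariates (including the movement terms and moderators) are centred
and scaled to sample SD 1 over **all** rows (used + available) of the
season's strata; quadratics and interactions are products of standardized
bases and are *not* re-standardized, so a moderator level of ±1 is exactly
±1 SD and the reporting categories (−1/0/+1 SD = low/median/high experience,
small/median/large group) stay interpretable. Stored (mean, SD) pairs allow
back-transformation. Zero-variance columns are rejected by name.

### Relative selection strength

RSS = exp(coefficient): the ratio of selection probabilities of two
otherwise-identical steps whose endpoints differ by one standardized unit.
Prediction curves compare a grid of standardized values `x` against the
season mean (`x_ref = 0`):

```
log-RSS(x) = b_lin (x - x_ref) + b_quad (x^2 - x_ref^2) + m * b_int (x - x_ref)
```

with `m` the moderator level in SD units. 95% bands are delta-method on the
log scale using the robust covariance; they are symmetric in log space and
exact (width zero) at the reference.

## Pipeline stages and their parameters

| stage | parameter | default | why |
|---|---|---|---|
| resampling | interval | 4 h | the common analysis cadence for mixed 1/2/4-h collar schedules |
| resampling | tolerance | ±30 min | 12.5% of the interval; admits jittered schedules without distorting spacing |
| resampling | min burst length | 3 fixes | two steps are needed before a turning angle exists |
| steps | zero-length floor | 1 m | log step length must stay finite; 1 m is below GPS error |
| kernel | per-season fit | on | each final model is season-specific, so its available steps should be too |
| strata | available per used | 9 | the analysis design (1:9 case/control) |
| landscape | analysis resolution | 500 m | balance of landscape heterogeneity and 4-h movement capacity |
| landscape | aNDVI baseline | per-slot mean, 4 years | anomaly relative to the long-term *seasonal cycle*; a grand-mean mode exists for comparison |
| landscape | temporal matching | most recent composite at or before the step end | no look-ahead |
| landscape | point lookup | nearest cell | grids are already at the analysis resolution; bilinear available |
| social | chain threshold | 200 m | two animals this close are linked; groups are connected components |
| seasons | dry / wet months | Jan–Jun / Jul–Dec | the Sahelian rainfall regime |
| model | VIF screen | warn at ≥ 4 | collinearity report on the full design |
| model | Newton | tol 1e-8 on the gradient max-norm, ≤ 200 iterations, step-halving, trust-region cap 5 | see numerical notes |

Resampling is greedy forward selection: from each anchor, the fix nearest
`anchor + interval` within the tolerance is kept; a gap closes the burst and
the next unconsumed fix opens a new one. A step takes the season of its
*start* timestamp (the decision is made at the step's start); moderators are
likewise evaluated at the stratum's start fix. Strata with any missing
covariate (e.g. an available endpoint off the mapped area) are dropped
whole, preserving the 1:9 balance that the conditional likelihood assumes.

## Synthetic data generator

The generator emulates the study system — a large semi-arid reserve seen
through 16-day NDVI composites — not any particular year of it:

* **NDVI**: a spatially correlated mean field (5 km correlation length) plus
  a seasonal cosine peaking after the rains (day ~260) and a per-composite
  correlated anomaly field (SD 0.04). Slot-wise anomalies are therefore
  recoverable by construction.
* **Terrain**: elevation spans the reserve's 190–461 m and mixes broad
  structure (10 km) with a fine-scale component (1.5 km, 30% of the
  variance). The fine component matters: terrain with only broad structure
  makes TRI ≈ 0 almost everywhere, and a covariate that degenerate is not
  merely noisy — the coefficient an estimator based on sampled available
  steps converges to then depends on the available-set size. Multi-scale
  roughness (wadis, outcrops) is also what real terrain looks like.
* **Temperature**: seasonal cosine peaking before the rains (day ~135), an
  elevational lapse of −6.5 °C/km, correlated noise.
* **Movement**: gamma(shape 2, scale 300 m) step lengths and von Mises
  (kappa 1) turning angles — ~600 m mean 4-h displacements with moderate
  directional persistence. At each step an animal draws `n_candidates`
  kernel steps and picks one with probability ∝ exp(utility), where the
  utility applies the true coefficients to covariates standardized by
  *landscape-wide* moments (recorded in the truth manifest so recovery
  compares like with like).
* **Candidate count**: the discrete choice among `n_candidates` kernel draws
  converges to the continuous step-selection density only as the count
  grows. Measured on these landscapes, 50 candidates leave a 15–25%
  attenuation of fine-scale coefficients; a few hundred is the knee. The
  default is 500, configurable.
* **Cohesion**: optionally, members of a planted group pay a utility cost
  per km of distance between a candidate endpoint and the centroid of their
  group-mates (self excluded, so stragglers feel the full gradient).
  Group-size moderation of selection is simulated by interacting the chain
  rule group size — computed live from the simulated positions — with
  environmental terms.
* **Experience**: simulated as interaction terms on the standardized day
  count, matching the analysis model rather than a mechanistic learning
  process, because recovery must target the implemented estimator.

All randomness flows from one seed through named substreams (landscape,
movement) so stages can be tested in isolation; the same seed is
bit-reproducible.

### Fixture profiles

* `tiny` — 2 cohesive animals × 50 steps on a 20 km landscape: fast
  end-to-end plumbing runs. Too small and too collinear for faithful
  estimates, deliberately.
* `recovery` — 15 animals × 300 steps, two release cohorts 20 days apart,
  truth over aNDVI (+0.5), dNDVI (−0.3), elevation (+0.25), TRI (−0.4) and
  two experience interactions (aNDVI −0.25, TRI +0.3): the coverage/bias
  benchmark.
* `grouped` — 12 animals in 3 cohesive groups of 4: chain-rule detection
  against a planted partition.
* `moderated` / `null` — 9 animals × 150 steps for the model-selection
  experiment; `moderated` plants unequal group sizes (1/3/5) and real
  experience and group-size interactions (M4 is the generating tier),
  `null` has environmental selection only (M1 is). These two profiles use
  shorter landscape correlation lengths (2 km NDVI, 4 km elevation) because
  moderator-interaction information lives in within-stratum covariate
  contrast, which broad-scale fields do not provide at 600-m steps.

### What the generator does not emulate

No GPS error, collar failure or irregular duty cycles beyond schedule
jitter; no cloud/QA artefacts in NDVI; no births, deaths or dispersal; no
mechanistic learning (experience enters exactly as the estimator models
it); phenology is a smooth cosine, not real Sahelian green-up. Passing
recovery therefore shows the estimator is correct *for data from its own
model family at realistic sizes* — it does not certify robustness to the
measurement pathologies of field data.

## Validation experiments

* **Recovery** (`stepsel.experiments.recovery_experiment`): 20 seeded
  replicates of the recovery profile through the full pipeline (resampling,
  per-season kernel fit, 9 available steps, extraction, moderators,
  conditional fit). Reported: per-term CI coverage and mean bias on the
  standardized scale. Fitting uses the truth manifest's standardization
  moments so the estimate and the generating value share a scale.
* **Model selection** (`selection_experiment`): rates at which M4 wins AICc
  on `moderated` data and M1 lands within 2 AICc of the best on `null`
  data, 20 replicates each. A tier whose moderator never varies
  (zero-variance column) or whose fit diverges by near-separation is a
  rejected candidate for that replicate; the remaining tiers compete.

Both experiments, plus the in-source identities and oracles (published-table
RSS identity, grid-search likelihood oracle, chain-rule union-find oracle,
covariate formula oracles, AICc closed form), are recomputed from scratch by
`scripts/acceptance.py`.

## Numerical choices

* Newton–Raphson with analytic gradient and observed information; step
  halving when a step decreases the likelihood, with the acceptance slack
  scaled to the likelihood's floating-point noise floor (`1e-11·(1+|l|)`);
  a trust-region cap of 5 on the Newton step length guards ill-conditioned
  information; convergence is gradient max-norm < 1e-8 (a step-halving
  dead-end with gradient < 1e-5 is accepted as converged — the iterate is at
  the optimum up to floating noise).
* Separation is detected three ways: a non-finite or huge (>1e3) Newton
  step, coefficient norm exceeding 50 on the standardized scale, or the
  likelihood attaining its supremum of 0 (every used step predicted with
  certainty).
* The von Mises concentration solves `I1(k)/I0(k) = R` by Brent's method on
  exponentially scaled Bessel functions (stable for large k); resultant
  length numerically 0 yields kappa = 0 (uniform), and R = 1 is a
  degenerate-data error. The gamma MLE is seeded by method-of-moments and
  never returns a lower likelihood than that start.
* Bilinear resampling excludes no-data cells and renormalises the remaining
  weights; sampling points between the outermost cell centres and the grid
  edge clamp to edge values, points beyond the extent return no-data.
* TRI at borders uses the neighbours that exist (no padding values).
* Ten-row strata are kept *whole or not at all* so the case/control ratio
  is constant; stratum-constant columns are rejected at design time by an
  exact within-stratum constancy check.
* Zero-length steps are floored at 1 m before the log transform.

## Known limitations

* The movement kernel is population-level (per season), not per animal;
  individual kernel heterogeneity is absorbed only through the cluster
  variance.
* No iterative kernel updating from the fitted movement coefficients; the
  tentative kernel is fitted once from observed steps.
* Turning-angle mismatch between the tentative and true kernel is not
  corrected (no cos-turning-angle term in the design), mirroring the
  analysis design; with kernels fitted from ~4,000 steps the residual
  mismatch is small.
* Cluster-robust inference rests on the number of animals; below ~10
  clusters even CR1 coverage degrades.
* The chain rule is evaluated at the 4-h fix times only; whether animals
  stayed within the threshold throughout the interval is unobservable at
  this cadence.
* Coordinates must arrive projected in metres; the package deliberately
  contains no geodesy.
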