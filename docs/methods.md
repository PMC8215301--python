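# Methods

## The estimand and the estimator

The package measures socio-economic inequality in an outcome with the
concentration index.  Individuals carry a fractional rank `r` on an ordered
socio-economic variable (origin social class by default): each group, ordered
most disadvantaged first, is coded at the midpoint of its ranked cumulative
weighted proportion, `r_g = Σ_{h<g} s_h + s_g/2` with `s_g` the normalized
weighted share of group `g`.  Five equal groups therefore code to
0.1/0.3/0.5/0.7/0.9, and the weighted mean of the ranks is exactly 0.5 for
any weights (an algebraic identity the tests assert at 1e-10).  All members
of a group share the group midpoint; no within-group jitter is applied.

Outcomes are oriented as *attainment* (larger = better health) and
*shortfall* (`1 −` attainment) and scaled to `[0, 1]` — by declared
instrument bounds when known, otherwise by the observed weighted range; the
bounds used are recorded on the coding object.  Scaling makes the relative
index invariant to positive affine rescalings of the raw outcome (with
matching bounds), which the property tests verify.

Estimation uses the convenient-regression form: the scaled outcome is
multiplied by `2·var_w(r)/μ_w` and regressed on `r` by weighted least
squares; the slope is the relative concentration index and equals
`2·cov_w(y, r)/μ_w` to machine precision.  The absolute index multiplies the
transformed variable by a further `4·μ_w`, giving slope `8·cov_w(y, r)` —
appropriate for 0–1-bounded outcomes, where it is invariant (up to sign)
between the attainment and shortfall orientations.  Two mirror identities
hold exactly and are asserted at 1e-10:

- `absolute_attainment = − absolute_shortfall`
- `μ·C_attain = −(1−μ)·C_shortfall`

Sign convention: a positive index means the good outcome is concentrated
among the advantaged.

### School-system contrasts

To compare inequality between the comprehensive and selective systems the
package fits one weighted regression of the transformed outcome on
`rank + system + rank×system`.  The transform's `μ` and `var(r)` — and the
rank coding itself — are computed *within each system arm*, not pooled.  A
pooled transform would make the interaction coefficient a
mixture of slope and transform differences; the arm-specific choice makes the
interaction exactly `C_selective − C_comprehensive`, i.e. the difference of
the stand-alone arm indices, which the tests verify algebraically at 1e-10.

### Uncertainty

The default interval is a nonparametric bootstrap: records are resampled with
replacement, the rank coding, means and variances are recomputed per
replicate, and percentile 2.5/97.5 limits are taken over 999 replicates
(configurable).  The supplied analysis weights are carried along but not
re-estimated per replicate — re-fitting the propensity model inside every
replicate is disproportionate at this package's problem sizes; a full
weights-refitting bootstrap can be composed at pipeline level if needed.
Inside the bootstrap loop the index is computed by the covariance form, which
equals the regression slope to 1e-10 (asserted by a dedicated dual-route
test), keeping 999 replicates cheap.  The alternative `se_method="robust"`
uses the HC1 sandwich of the final WLS fit; simulation tests show the
bootstrap interval covers a planted truth 92–98% of the time at n = 10,000.

## Balancing weights

The exposure model is the probability of attending a selective-system school
given baseline confounders.  Three propensity candidates are provided:

- `logistic` — main-effects logistic regression (indicator-coded categorical
  confounders, z-scored continuous ones);
- `spline` — the same model with the continuous ability score expanded in a
  natural cubic spline basis (default 4 df, knots at equally spaced
  quantiles), standing in for a generalized additive fit;
- `ridge` — L2-penalized logistic regression with the penalty chosen by
  5-fold cross-validated deviance (fixed fold seed), for use under (near)
  perfect separation.

Weights are `1/p` (selective) and `1/(1−p)` (comprehensive): each weighted
arm estimates the whole-population counterfactual "everyone under this
system", so each arm's weighted size is close to n and each arm's weighted
confounder distribution matches the full sample.  Truncation is available
(e.g. at the 99th weight percentile) but off by default.

Entropy balancing solves, within each arm, min KL(w‖uniform) subject to the
weighted first moments of the confounder design equaling the full-sample
moments.  The dual is a smooth strictly convex problem in the Lagrange
multipliers; it is solved by damped Newton iterations with the exact softmax
Hessian, and a solution is accepted only if the worst first-moment error is
below 1e-8.  Weights are positive by construction; an infeasible target
(outside the arm's convex hull) raises an error rather than producing
negative weights.

Among candidates, the selector returns the weight set with the smallest mean
absolute standardized mean difference across all confounder levels (SMD:
difference in weighted arm means over the pooled weighted SD), ties broken by
the smaller weight coefficient of variation.  This is a deliberately
transparent replacement for cross-validated model stacking: achieved balance
is the operative criterion for a weighting method.  A generalized-boosted
candidate can be plugged in as a pre-computed `WeightSet`.

## The synthetic cohort

The generator emulates a one-week national birth cohort followed to mid-life:

- **Confounders.**  Sex, broad ethnicity, region, parental education,
  teacher-rated parental interest and state-primary attendance are
  independent categoricals with margins echoing the real cohorts' baseline
  tables (e.g. origin-class probabilities 0.16/0.05/0.21/0.58 for higher
  managerial / lower managerial / intermediate / routine).  The raw ability
  score and origin class share a latent advantage factor (correlation 0.3 by
  default); the real joint distribution is unpublished, so this dependence
  structure is a stand-in, configurable and disclosed here.  Ability is
  standardised to mean 100, SD 15 (weighted convention Σw(x−m)²/Σw).
- **Exposure.**  Selective-system attendance follows a logistic model in
  ability, class rank and selected indicators; defaults give ≈ 40% selective
  attendance enriched among advantaged, higher-ability children, matching
  the observed direction of confounding.
- **Outcomes.**  Continuous outcomes live on [0, 1] with mean-zero *uniform*
  noise (sd parameter matched via `a = sd·√3`), so the support provably
  stays in bounds and the closed-form truth is exact — truncated normal
  noise would bias the planted index.  Binary outcomes use a logistic link
  in the class rank; ordinal ones a proportional-odds construction.  True
  means and indices per outcome × system are computed by exact enumeration
  over the four classes and returned as `SimulationTruth`
  (`absolute = 4·μ·relative` holds by construction).
  `planted_continuous_outcome` inverts `C = 2βvar(r)/μ` so tests can plant a
  target index directly.  A baseline BMI-like negative-control column is
  always generated independently of class, ability and system.
- **Missingness.**  Wave non-response (blanks all outcomes) and per-variable
  item non-response follow logistic MAR models in the always-observed
  baseline confounders; models referencing potentially missing columns are
  rejected.

What the generator does *not* emulate: the real cohorts' joint confounder
distribution, region-specific school-system rollout, measurement error in
class coding, and non-ignorable (MNAR) missingness.  Passing tests therefore
demonstrate estimator correctness under a known data-generating process, not
agreement with the restricted cohort data.

An `exact_class_counts` option apportions classes deterministically
(largest-remainder), making realized ranks equal population ranks so that
estimator-vs-truth checks can be run at machine precision.

## Missing data

The two-stage MI/IPW strategy is a reconstruction of the general approach the
field uses, not a replication of any specific unpublished recipe: inverse
probability-of-response weights (logistic model of "any outcome observed" on
baseline confounders; responders weighted `1/p̂`, non-responders excluded)
handle unit non-response, chained-equation multiple imputation handles item
non-response among responders, and the final analysis weight is the product
of response and confounding weights.  The imputation engine draws linear
models with proper parameter draws (σ² from scaled inverse-χ², β from its
normal posterior), logistic draws with parameter perturbation, and
proportional-odds draws without parameter perturbation (a known mild
understatement of imputation variance for ordinal variables).  The analysis
weight enters imputation models as a standardized covariate.  Defaults:
m = 5 imputations, 10 chained iterations, fixed seed.  Estimates are pooled
with Rubin's rules (variance = within + (1+1/m)·between; t reference with
the conventional degrees of freedom).

Simulations in the test suite show class-dependent item missingness biases
the complete-case index downward by roughly a third of its value under the
default MAR mechanism, while the pooled MI estimate removes essentially all
of that bias.

## Pipeline, problem sizes and numerical choices

`run_pipeline` executes simulate → missingness → weights → concentration in a
fixed order, derives all stage seeds from one master seed via
`SeedSequence.spawn`, and emits long-format result tables plus a manifest
(config hash, seeds, per-stage wall time and row counts) sufficient to replay
any table.  The negative-control check refuses configurations that list the
control among the confounders, and flags (never fails) when its interval
excludes zero.

Simulation-based tests use cohorts of 1,000–50,000 records and 100–200
replicates, sizes at which Monte-Carlo error is small relative to the effects
being checked while the whole suite stays quick; bootstrap-based tests pass
smaller explicit replicate counts (199–299) than the production default, the
interval construction being identical.  Tolerances follow the quantity being
checked: algebraic identities at 1e-10, probability/moment constraints at
1e-8, stochastic recoveries at 3 Monte-Carlo SEs.  Degenerate inputs fail
loudly: constant outcomes (μ of 0 or 1) make relative indices undefined,
single-class arms cannot support a rank slope, all-zero weights and unordered
class variables are rejected, and SMDs with zero pooled variance are an error
unless both arms are constant and equal.

## Known limitations

- The balance-criterion selector is not a cross-validated stacking learner;
  with many candidates it can overfit in-sample balance.
- Bootstrap intervals treat analysis weights as fixed (see above).
- The entropy-balancing dual assumes a non-degenerate moment design;
  perfectly collinear confounder levels should be pruned upstream.
- Ordinal imputation understates between-imputation variance slightly.
- Relative indices for shortfall-coded rare outcomes are numerically fragile
  when μ approaches 1 (small `1−μ` denominators); the absolute index is the
  stable summary there.
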