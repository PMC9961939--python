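# Methods

This note documents the models, parameter choices and limitations behind
`corticorl`. It covers what the synthetic generator emulates (and does
not), the decision-process conventions, the learning algorithm, the
off-policy evaluation machinery, the explainability methods, and the
numerical choices made where the design was genuinely open.

## 1. Synthetic EHR generator

### Generative model

Each admission carries a latent daily severity `s ∈ [0, 1]`, a one-number
summary of organ dysfunction. It evolves as a clipped mean-reverting
random walk

```
s_{t+1} = clip(s_t + κ(μ − s_t) − g_a (s_t − p) + ε_t),   ε_t ~ N(0, σ²)
```

with reversion rate κ = 0.15 toward an attractor μ = 0.35 (natural
recovery), noise σ = 0.08, and a treatment drift `−g_a (s_t − p)` pulled
toward the pivot p = 0.45 with per-action gains
g = (0, 0.25, 0.45, 0.35, 0.20). The drift is the mechanism that makes
the optimal policy non-trivial: a moderate dose (bin 2) reduces next-day
severity when the patient is sicker than the pivot and raises it when
they are not.

Stay length is geometric with mean 6 days (capped at 60); on the
discharge day the patient dies in ICU with probability

```
P(death) = sigmoid(β₀ + β₁ s + τ_a),   β₀ = −3, β₁ = 4,
τ = (0, 0.10, 0.15, 0.45, 0.90)
```

evaluated at that day's severity and dose action — τ encodes
dose-dependent direct harm (hyperglycemia, superinfection, myopathy in
the real world). Because death depends only on the current day's
severity and action, the process is Markov.

The clinician behavior policy is a severity-monotone softmax over the
five dose bins, `softmax(intercepts + slopes·s)` with intercepts
(2.5, 0, −0.5, −1.5, −2.2) and slopes (−2, 1.5, 3, 2.5, 2): sicker
patients receive more steroids, which creates the confounding-by-severity
that makes naive outcome comparisons misleading and off-policy
evaluation necessary. The coefficients were chosen so clinicians withhold
steroids on roughly half of patient-days and cohort ICU mortality sits
near 23%, matching the treatment intensity and case fatality reported
for adult sepsis cohorts.

Observables are emitted per day from severity-linked Gaussian models
(e.g. MAP 88 − 35 s mmHg, lactate 0.8 + 4.2 s mmol/L, platelets
250 − 220 s ×10⁹/L, GCS 15 − 11 s), with Poisson event counts per day
(vitals 8/day, labs 1.5/day) thinned by whole-day missingness (2% / 12%)
and uniform within-day timestamps. Severity above 0.5 triggers
norepinephrine infusions, above 0.6 mechanical ventilation. Infected
admissions (85%) receive a blood culture plus antibiotics inside the
suspicion window; steroid days emit compound-level boluses
(hydrocortisone, prednisolone, methylprednisolone or dexamethasone)
whose hydrocortisone equivalent is drawn strictly inside the day's
action bin, so the true action is exactly recoverable by re-binning.
Small fractions of minors (2%) and sub-24 h stays (5%) exercise the
exclusion rules.

### What it does not emulate

No diurnal or ward-schedule structure in sampling times; no
multi-dimensional physiology (one latent severity drives everything, so
features are strongly collinear); no informative missingness beyond the
per-class rates; no withdrawal-of-care decisions; no inter-admission
dynamics for readmitted patients. Passing tests therefore demonstrate
that the pipeline's machinery is correct and calibrated on data of this
structure — not that the learned policies would transfer to real ICU
data, where confounding is richer and the state is far from Markov.

### The enumerable oracle

`SeverityMDP` discretizes severity onto a K-point grid (default 21),
integrates the Gaussian step over grid cells to get exact per-action
transition matrices, and computes any policy's expected terminal return
by backward induction over the 60-day horizon — no sampling.
`true_policy_value` is the ground truth against which Monte-Carlo means,
importance-sampling estimates and confidence bounds are checked, and
`best_threshold_policy` grid-searches single-threshold policies as the
reference optimum for policy-recovery experiments. With the default
scenario the behavior policy's value is +0.520 (expected mortality
24.0%) and the best threshold policy's +0.580 (21.0%; bin 2 when
severity ≥ 0.5) — both recomputed at runtime by the examples and tests,
never hard-coded.

## 2. Cohort identification

Sepsis-3 is operationalized as: suspected infection (a culture paired
with an antibiotic administration within −24 h/+72 h; suspicion at the
earlier of the pair) AND new organ dysfunction (total SOFA ≥ 2 on the
admission day, or a rise of ≥ 2 points above the running minimum since
admission) AND age ≥ 18 AND ICU stay ≥ 24 h. The episode runs from onset
(the first day the SOFA condition holds) through ICU discharge or death.
Repeated admissions are independent episodes.

The SOFA grid uses the standard published thresholds, encoded once in
`cohort.py` (units: PaO₂/FiO₂ mmHg with a ventilation flag for scores
3–4, platelets ×10⁹/L, bilirubin mg/dL, MAP mmHg plus vasopressor dose
rules in µg/kg/min, GCS, creatinine mg/dL plus urine output mL/day).
Each subscore takes the worst value in the admission-anchored 24 h
window; missing inputs score 0 — the conservative convention when
pre-admission organ function is unknown. The rise baseline is the
running minimum, which captures "new" dysfunction without pre-ICU data.
Septic shock is flagged as any vasopressor use plus any lactate
> 2 mmol/L during the stay. The suspicion windows are configurable
because published operationalizations vary.

## 3. Feature states

Events become a daily state matrix in four steps, all fitted on the
training split only:

1. **Bin & aggregate**: 24 h windows from sepsis onset; frequently
   sampled measurements contribute mean/max/min/sd (population sd; sd of
   one observation is 0), drug variables the 24 h sum. Which variable is
   which is declared in a shipped registry, not inferred, so the state
   layout is reproducible. Steroid compounds and the outcome are
   deliberately absent from the registry: the dose is the action and
   mortality the reward.
2. **Coverage filter**: variables observed on ≤ 2% of training
   admission-days are dropped everywhere.
3. **Imputation**: forward fill within admission for measurements,
   zero for missing drug sums, training median for gaps before a
   variable's first observation (zero would falsely encode "normal" for
   labs). The pre-imputation observation mask is kept alongside.
4. **Normalization**: min–max to [−1, 1] with training-split bounds;
   out-of-range held-out values are clipped; constant variables map
   to 0. De-normalizing an unclipped value recovers the original to
   1e−9.

Property tests assert that mutating held-out rows can never change the
fitted bounds, the coverage decisions, or the trained model.

## 4. Decision process

Doses are converted to hydrocortisone equivalents with a configurable
potency registry (hydrocortisone 1, prednisolone/prednisone 4,
methylprednisolone 5, dexamethasone 26.7 — the standard equivalence
table) and binned with left-open/right-closed boundaries: 0; (0, 100];
(100, 200]; (200, 300]; (300, ∞) mg. Terminal reward is ±1 rather than
a larger magnitude so that returns live in [−1, 1] and expected return J
maps to expected mortality (1 − J)/2 in closed form. The discount
defaults to γ = 0.99; experiments that compare against the exact oracle
use γ = 1 so values are exactly expected survival probabilities shifted
to [−1, 1]. Splitting is admission-level (all days of an admission share
a split) at 70/20/10 with largest-remainder rounding — 3051 admissions
yield exactly 2136/610/305.

## 5. Actor-critic learner

Two separate multilayer perceptrons (default two hidden layers of 64
tanh units; linear outputs), implemented directly in numpy with manual
backpropagation — desk-scale networks do not need an autograd framework,
and owning the forward pass gives the relevance-propagation code exact
access to layer activations. Training replays the logged transitions in
shuffled minibatches (size 256): the critic takes semi-gradient steps on
δ², the actor ascends δ∇log π plus an entropy bonus (coefficient 1e−2,
linearly decayed to 0) that delays premature determinism. Optimizer is
SGD with momentum 0.9; learning rates 1e−3 (critic) and 1e−4 (actor);
optional linear annealing of both rates (`final_lr_fraction`) reduces
stochastic-approximation noise when a precise value estimate is needed.
Per epoch the log records the mean TD loss, the relative error (mean
loss divided by the first epoch's, so epoch 1 is 1.0 by definition), the
action histogram of the argmax policy, and concordance with the logged
actions on the training and optionally validation split; training stops
early when the relative error plateaus (window 25, tolerance 1e−3)
and aborts with diagnostics on non-finite loss.

Training applies no importance correction — it is off-policy regression
on logged data, and the OPE module is where the resulting policy's value
is honestly quantified. Recommendations are argmax actions with ties
broken toward the lower (more restrictive) bin.

Verified behavior: the critic reproduces exact policy-evaluation values
(linear solve) on enumerable MDPs within 0.05; on the reference
scenario the recommended policy's oracle value lands within 0.05 of the
grid-searched best threshold policy and strictly above the behavior
policy, across training seeds.

## 6. Off-policy evaluation

The behavior policy b(a|s) is not observed and must be estimated — the
single most consequential modeling gap in any offline RL evaluation.
Default: the random-forest behavior clone's predicted probabilities,
mixed with a uniform floor, `b' = (1 − 5 p_min) b + p_min` with
p_min = 0.01, so the logged action never has probability below the floor
and importance ratios stay bounded. An alternative `empirical` estimator
(k-means state clusters with per-cluster action frequencies) is
provided; floors of 0.2 or more are rejected because they would flatten
the 5-way distribution. On discrete-MDP experiments the generator's
exact softmax behavior policy is used instead, since it is known.

Importance weights are trajectory-level products of π_e/b truncated at
c = 100 (per-decision weights available as an option). Three lower-bound
methods are implemented and selectable:

* **concentration** (default): empirical-Bernstein,
  `mean − sqrt(2 V ln(2/δ)/n) − 7·range·ln(2/δ)/(3(n−1))`, using the
  sample variance and sample range of the truncated weighted returns; a
  degenerate all-equal sample yields the common value itself.
* **t_test**: one-sided Student-t bound `mean − t_{1−δ,n−1}·s/√n`.
* **bootstrap_bca**: lower end of the BCa bootstrap interval.

All require n ≥ 30 trajectories. Empirical coverage of the
concentration bound, measured against the DP oracle with π_e = b over
200 replicates of 300 trajectories, is essentially 100% — the bound is
conservative by construction, which is the desired failure direction for
a safety claim. Untruncated importance sampling is verified unbiased
against the oracle to within Monte-Carlo error at 50,000 trajectories.

A practical caveat the synthetic experiments make visible: on
high-dimensional states with a near-deterministic learned policy,
trajectory-level weights degenerate (most collapse toward 0), and the
plain IS estimate and its bound become very pessimistic. This is a
property of the estimator, not a bug; the enumerable-MDP experiments
are where calibration claims are made.

Concordance-stratified outcomes label each test-split day-state
concordant if the recommendation equals the logged action, attribute
mortality at the day level (every day of a non-survivor is a
death-day), and stratify by agent-withheld vs agent-prescribed and by
septic-shock status; empty strata report NaN. Per-day usage and mean
dose curves use bin midpoints (50/150/250 mg, 350 mg for the open top
bin) for both policies.

## 7. Explainability

LRP uses the ε-stabilized rule with relevances initialized at the
recommended action's pre-softmax logit and propagated through each
linear layer as `R_j = Σ_k a_j w_jk/(z_k + ε·sign(z_k)) R_k` with
`z_k = Σ_j a_j w_jk`. Biases are excluded from the denominator, which
makes conservation exact: with ε = 0 and no vanishing denominator the
input relevances sum to the explained logit (asserted to 1e−4);
vanishing denominators contribute 0. Default ε = 0.01; the explained
quantity (recommended-action logit) is a choice — probabilities or other
actions can be explained by passing `action`. Global rankings are mean
absolute relevance across day-states, descending, ties alphabetical.

The behavior clone is a scikit-learn random forest (500 trees,
unlimited depth, class-balanced weights) scored by micro-average
one-vs-rest multiclass AUROC on the validation split. Its impurity-based
feature importances are compared with the agent's LRP ranking by
Spearman rank correlation over the shared feature universe. High
relevance is not causality: with one latent severity driving every
observable, many features are interchangeable explanations.

## 8. Pipeline, determinism and problem sizes

Every source of randomness derives from the run config's single seed
(generator: seed; training: seed+1; splitting: seed+2; clone: seed+3;
bootstrap: seed+4; LRP subsampling: seed+5); identical configs produce
byte-identical run reports, which is asserted in tests. The run report
is validated against a versioned pydantic schema on write, and each run
logs stage timings and record counts to `run.log`.

Default problem sizes were chosen so the full test suite runs in a few
minutes on one CPU: 300-admission cohorts for pipeline and cohorting
tests, 2000 admissions (~12,000 day-states) for policy recovery, 50,000
sampled stays for unbiasedness checks, 200 × 300 trajectories for
coverage. All scale up by changing the config only.

## Known limitations

* One latent severity dimension: no distinct phenotypes, so "who
  benefits" reduces to "how sick".
* Behavior-policy estimation via the clone is itself a model; its error
  propagates into the importance weights un-quantified.
* Trajectory-level IS has high variance for long stays; per-decision
  weights mitigate but are not the default.
* The critic's values are only trustworthy on the state distribution
  actually visited by the behavior policy.
* The SOFA grid assumes the generator's units; real databases need
  unit harmonization before the cohort module applies.
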