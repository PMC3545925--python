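# Methods

## The question

Population risk algorithms are routinely applied to self-reported height and
weight, which carry measurement error. This package quantifies, by Monte-Carlo
simulation, how two kinds of error in those inputs affect a fixed
BMI-to-diabetes risk equation:

* **random (nondirectional) error** — zero-mean noise that inflates the
  observed variance without shifting the mean, parameterised by the intraclass
  correlation coefficient (ICC), the fraction of total observed variance due
  to true between-individual variation; and
* **systematic (directional) error, "bias"** — constant misreporting, with
  height over-reported (0 to +3.0 cm) and weight under-reported (0 to
  −3.0 kg), the directions the self-report literature documents.

Performance is summarised by three quantities per scenario: the mean
observed-minus-true predicted risk, the share of replications passing a fixed
calibration cutoff, and the mean C-statistic.

## The risk model

Ten-year diabetes risk follows a quadratic logistic model,

    logit(p_i) = β0 + β1·BMI_i + β2·BMI_i²,

with sex-specific coefficients estimated in a population-survey derivation
cohort (males: β = (−10.4034, 0.4202, −0.00437); females:
(−10.8967, 0.4565, −0.00509)). Because β2 < 0 the risk curve has an interior
maximum near BMI 48 (males) / 45 (females); the implementation never assumes
monotonicity. The coefficients stay **fixed** throughout all error scenarios —
the study models external validation of a frozen equation, not refitting.
`fit_logistic_quadratic` (IRLS, weighted least squares solved by QR because
the uncentred {1, BMI, BMI²} design is poorly conditioned) exists only to
validate that simulated cohorts give back the generating equation.

## The data-generating process

Per replication, for a cohort of n individuals (9,177 males / 10,618 females):

1. **Latent truth.** (true height, true weight) is bivariate normal. The
   published anthropometric moments (males 1.768 ± 0.075 m, 81.624 ± 13.805 kg,
   r = 0.475; females 1.627 ± 0.069 m, 64.761 ± 12.320 kg, r = 0.311) describe
   the *observed* measurements, so the generator is **observed-anchored**:

   * true SD = observed SD × √ICC (σ²_obs = σ²_true + σ²_error with
     σ²_true = ICC·σ²_obs);
   * true mean = observed mean − bias (the observed distribution is the one
     whose moments are anchored; removing a −3 kg weight bias yields a true
     mean BMI of ≈ 25.61 in females, matching the published example);
   * true height-weight correlation = r / √(ICC_h·ICC_w), clipped below 1
     with a logged warning. Independent error attenuates correlations by
     √(ICC_h·ICC_w), so this disattenuation makes the *observed* correlation
     equal r at every error level. It also reproduces the published true-BMI
     spread (3.87 at female ICC 0.8; the non-disattenuated alternative gives
     ≈ 4.02 and was rejected).

2. **Observation.** observed = true + bias + ε, with ε_height ⊥ ε_weight ⊥
   truth, ε ~ N(0, σ²·(1 − ICC)). With ICC = 1 and zero bias the observed
   arrays are bit-identical to the true ones.

3. **Outcomes.** BMI = weight / height²; each subject's outcome is
   Bernoulli(p) at the risk predicted from **true** BMI. The equation is
   therefore exactly calibrated in the error-free world and any degradation
   is attributable to predictor error alone.

Normal draws are used as drawn (no truncation): at the study parameters a
non-positive height/weight is > 20 SDs out, and `compute_bmi` raises rather
than silently repairing if it ever happens.

### What the generator does not emulate

Real anthropometrics are right-skewed, misreporting varies with the true value
(heavier people under-report more) and with disease status, and survey data
carry sampling weights and clustering. None of that is modelled; passing tests
show the behaviour of the idealised error mechanisms, not of any particular
survey's error structure.

## Metrics

* **Calibration** — grouped ("modified") Hosmer-Lemeshow chi-square for
  externally specified models: sort by predicted risk (stable sort; ties keep
  input order), split into 10 contiguous near-equal groups (remainder subjects
  go to the lowest-risk groups), then
  χ² = Σ_g (O_g − E_g)² / (n_g·p̄_g·(1−p̄_g)). A replication is *calibrated*
  when χ² < 20, the 99th percentile of χ²₈, the conventional cutoff for
  validating risk algorithms; p-values use n_groups − 2 df.
* **Discrimination** — C-statistic via the rank-sum identity (midranks for
  ties), equal to the probability a random case outranks a random non-case
  with ties counted ½. Verified against O(n²) pair enumeration in tests.
* **Risk difference** — mean predicted risk from observed BMI minus mean
  predicted risk from true BMI; case counts are round(difference × n) with the
  sex-specific n.

## Replication design and seeding

Each scenario runs 500 replications (the study design; tests use 20–500
depending on the precision the assertion needs). Replication r of a scenario
uses `numpy.random.default_rng(base_seed + r)`; grids give scenario i the base
seed `base_seed + 1000·i`, so seed blocks never overlap (stride > n_reps) and
every run is bit-reproducible from one configured integer. Replications whose
metrics are undefined (e.g. a degenerate risk decile) are logged and excluded;
a scenario aborts if more than 1% fail. Aggregation is the arithmetic mean
(and SD) across replications.

## Numerical choices

* Inverse logit via `scipy.special.expit` (overflow-safe); extreme BMI values
  saturate smoothly.
* IRLS convergence: max |score| < 1e−8 or relative log-likelihood change
  < 1e−10, at most 100 iterations; complete separation is detected (likelihood
  at numerical zero) and raised, never returned.
* Correlation clip at 0.999; disattenuated correlations above 1 are clipped
  with a warning (they do not occur on the default grids: the worst case is
  male ICC 0.5/0.5, r_true = 0.95).
* Biases are configured in the units the sweeps are quoted in (cm, kg) and
  converted to SI at the interface boundary; all internal computation is m/kg.

## Design choices that were genuinely open

* The published scalar description of the generator does not say how the
  height-weight correlation was induced; the bivariate-normal construction
  with disattenuation was chosen because it reproduces the published observed
  *and* true BMI moments simultaneously.
* The ICC grid step (0.1 over [0.5, 1.0]) matches the granularity of the
  published result surfaces; the joint bias-by-random-error runs pair each
  single-axis bias scenario with ICC ∈ {1.0, 0.8, 0.6} on both axes.
* The derivation-cohort intercept has no published standard error, so the
  validation flag for β0 falls back to the refit's own standard error.

## Known limitations

* A single-cohort refit of the collinear quadratic design has a β1 sampling
  SD of ≈ 0.107 at n = 9,177 — about 3× the published derivation standard
  error — so individual refits land outside the 3-SE band roughly a quarter
  of the time; the validation analysis therefore averages refits over
  replications when a powerful check is needed.
* Under the observed-anchored conventions above, moderate random error
  (ICC ≈ 0.8 on both axes) already degrades calibration substantially
  (top-decile predicted risk over-predicts events by ~25% through
  regression-to-the-mean attenuation) and lowers the C-statistic by ~0.05.
  The error level at which performance becomes "safe" is therefore closer to
  ICC ≥ 0.9 in this implementation; no alternative variance/correlation
  convention changes this while still matching the published moment
  structure.
* Scenario summaries are means over replications; no inferential comparison
  between scenarios is attempted.
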