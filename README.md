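# riskerror

Monte-Carlo study of how measurement error in self-reported height and weight
affects a BMI-based diabetes risk prediction model.

Population risk algorithms are often applied to self-reported anthropometrics,
which are misreported in two characteristic ways: random noise (people report
imprecisely) and directional bias (height over-reported, weight
under-reported). This package simulates cohorts with controlled amounts of
both kinds of error and measures what they do to a fixed quadratic-logistic
risk equation,

    logit(p_i) = β0 + β1·BMI_i + β2·BMI_i²,

evaluated on observed versus true BMI. Performance is summarised per scenario
by the mean observed-minus-true predicted risk, the share of 500 replications
passing the calibration cutoff (grouped Hosmer-Lemeshow χ² < 20, the 99th
percentile of χ² with 8 df), and the mean C-statistic (area under the ROC
curve). Random error is parameterised by the intraclass correlation
coefficient (ICC = σ²_true/σ²_obs, 1 = error-free); bias by a constant shift
in cm/kg. It is written for epidemiologists and biostatisticians studying
how predictor error propagates into external validation of risk scores.

## Worked example

Run the maximal weight-under-reporting scenario for males (−3.0 kg, no random
error, 500 replications of a 9,177-person cohort):

```
$ riskerror scenario --sex male --bias-weight-kg -3 --reps 500 --seed 7 --out male_w3.csv
male icc_h=1,icc_w=1,bias_h=0cm,bias_w=-3kg: risk difference -1.42 pp, 7.8% calibrated, mean C = 0.679 -> male_w3.csv
```

Reading: under-reporting weight by 3 kg shifts every observed BMI down by
about one unit, so the frozen equation under-predicts 10-year diabetes risk
by 1.42 percentage points on average (≈ 131 missed cases in this cohort),
only ~8% of replications still pass the calibration cutoff, while
discrimination is essentially untouched (C = 0.679 vs 0.686 without error) —
a constant shift barely reorders subjects.

The full study is scripted as numbered analysis steps (each accepts
`--reps/--seed/--out-dir` and writes CSV tables under `results/`):

```
python analysis/01_validate_model.py    # refit check + error-free baseline
python analysis/02_random_error_grid.py # factorial ICC grid, no bias
python analysis/03_bias_sweeps.py       # single-axis bias sweeps
python analysis/04_joint_error.py       # bias x random error, average misreporting
```

Step 2, for instance, prints:

```
male: C falls from 0.686 (no error) to 0.540 at ICC 0.5/0.5; max upward risk bias 0.99 pp (91 extra predicted cases)
male: weight error dominates — at ICC 0.5 on one axis, calibration 0% (weight) vs 49% (height)
```

i.e. random error biases predicted risk *upwards* (variance inflation widens
the BMI distribution into the steep part of the risk curve), degrades
calibration and attenuates discrimination, and weight error matters more than
height error. The same machinery is available programmatically:

```python
from riskerror import (DEFAULT_COHORTS, DEFAULT_COEFFICIENTS,
                       ErrorSpecification, run_scenario)

summary = run_scenario(DEFAULT_COHORTS["female"],
                       ErrorSpecification(icc_height=0.8, icc_weight=0.8),
                       DEFAULT_COEFFICIENTS["female"],
                       n_reps=500, base_seed=7)
print(summary.mean_risk_difference, summary.pct_calibrated, summary.mean_c_statistic)
```

See `docs/methods.md` for the generative model, the observed-anchored
variance convention, metric definitions and known limitations.

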