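"""Replication engine: run error scenarios many times and aggregate.

One *scenario* is a (sex, error specification) pair.  A scenario is executed
as ``n_reps`` independent replications — simulate a cohort, score it with the
frozen risk equation — each with its own seed ``base_seed + r``, and the
per-replication results are averaged.  The default experiment follows the
study design: 500 replications per scenario, a factorial ICC grid over
[0.5, 1.0] in steps of 0.1 for height and weight, and single-axis bias sweeps
from 0 to 3.0 cm (height over-report) and 0 to -3.0 kg (weight under-report)
in 0.5 steps, plus joint bias-by-random-error runs at ICC levels
{1.0, 0.8, 0.6}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_COHORTS,
    CohortParameters,
    ErrorSpecification,
    simulate_cohort,
)
from .metrics import (
    MetricError,
    ReplicationResult,
    c_statistic,
    evaluate_replication,
    hosmer_lemeshow,
)
from .risk_model import (
    DEFAULT_COEFFICIENTS,
    DERIVATION_STANDARD_ERRORS,
    RiskCoefficients,
    fit_logistic_quadratic,
    predict_risk,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioError",
    "GridSpecification",
    "ScenarioSummary",
    "ValidationReport",
    "run_scenario",
    "run_random_error_grid",
    "run_bias_grid",
    "run_joint_grid",
    "validate_against_derivation",
    "summaries_to_frame",
]

#: Seed stride between scenarios in a grid; larger than any supported n_reps
#: so per-replication seed blocks never overlap.
SCENARIO_SEED_STRIDE = 1000

#: A scenario fails if more than this fraction of replications raise.
MAX_FAILURE_FRACTION = 0.01


class ScenarioError(RuntimeError):
    """Too many replications of a scenario raised metric errors."""


@dataclass(frozen=True)
class GridSpecification:
    """Full experiment definition (grids, replication count, seeding)."""

    sexes: tuple[str, ...] = ("male", "female")
    icc_grid: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    bias_height_grid_cm: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    bias_weight_grid_kg: tuple[float, ...] = (0.0, -0.5, -1.0, -1.5, -2.0, -2.5, -3.0)
    joint_icc_levels: tuple[float, ...] = (1.0, 0.8, 0.6)
    n_reps: int = 500
    base_seed: int = 1729

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if self.n_reps > SCENARIO_SEED_STRIDE:
            raise ValueError(f"n_reps must not exceed {SCENARIO_SEED_STRIDE}")
        for name in ("sexes", "icc_grid", "bias_height_grid_cm", "bias_weight_grid_kg"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        for icc in self.icc_grid + self.joint_icc_levels:
            if not 0.0 < icc <= 1.0:
                raise ValueError(f"ICC grid values must lie in (0, 1], got {icc}")


@dataclass(frozen=True)
class ScenarioSummary:
    """Replication-averaged performance of one (sex, error) scenario."""

    sex: str
    icc_height: float
    icc_weight: float
    bias_height_cm: float
    bias_weight_kg: float
    n: int  # cohort size
    n_reps: int
    n_failed: int
    base_seed: int
    mean_risk_difference: float  # probability scale
    sd_risk_difference: float
    case_difference: int  # round(mean_risk_difference * n)
    pct_calibrated: float  # 0..100
    mean_chi2_hl: float
    mean_c_statistic: float
    sd_c_statistic: float
    mean_p_obs: float
    mean_p_true: float
    mean_p90_obs: float
    mean_p90_true: float
    mean_obs_bmi: float
    sd_obs_bmi: float
    mean_true_bmi: float
    sd_true_bmi: float


def _aggregate(
    sex: str,
    params: CohortParameters,
    spec: ErrorSpecification,
    results: list[ReplicationResult],
    n_failed: int,
    n_reps: int,
    base_seed: int,
) -> ScenarioSummary:
    def mean(attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in results]))

    def sd(attr: str) -> float:
        values = [getattr(r, attr) for r in results]
        return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0

    mean_rd = mean("risk_difference")
    return ScenarioSummary(
        sex=sex,
        icc_height=spec.icc_height,
        icc_weight=spec.icc_weight,
        bias_height_cm=spec.bias_height * 100.0,
        bias_weight_kg=spec.bias_weight,
        n=params.n,
        n_reps=n_reps,
        n_failed=n_failed,
        base_seed=base_seed,
        mean_risk_difference=mean_rd,
        sd_risk_difference=sd("risk_difference"),
        case_difference=int(round(mean_rd * params.n)),
        pct_calibrated=100.0 * float(np.mean([r.calibrated for r in results])),
        mean_chi2_hl=mean("chi2_hl"),
        mean_c_statistic=mean("c_statistic"),
        sd_c_statistic=sd("c_statistic"),
        mean_p_obs=mean("mean_p_obs"),
        mean_p_true=mean("mean_p_true"),
        mean_p90_obs=mean("p90_obs"),
        mean_p90_true=mean("p90_true"),
        mean_obs_bmi=mean("mean_obs_bmi"),
        sd_obs_bmi=mean("sd_obs_bmi"),
        mean_true_bmi=mean("mean_true_bmi"),
        sd_true_bmi=mean("sd_true_bmi"),
    )


def run_scenario(
    params: CohortParameters,
    spec: ErrorSpecification,
    coeffs: RiskCoefficients,
    n_reps: int = 500,
    base_seed: int = 1729,
    collect_replications: bool = False,
) -> ScenarioSummary | tuple[ScenarioSummary, pd.DataFrame]:
    """Run one scenario for ``n_reps`` replications and aggregate.

    Replication ``r`` uses seed ``base_seed + r``, so the whole scenario is
    deterministic given its base seed.  Replications whose metrics are
    undefined (e.g. a degenerate risk-decile) are logged and excluded; the
    scenario fails outright if more than 1% of replications do so.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    results: list[ReplicationResult] = []
    rows: list[dict] = []
    n_failed = 0
    for r in range(n_reps):
        seed = base_seed + r
        cohort = simulate_cohort(params, spec, coeffs, seed)
        try:
            result = evaluate_replication(cohort, coeffs)
        except MetricError as exc:
            n_failed += 1
            logger.warning(
                "scenario sex=%s %s seed=%d replication=%d failed: %s",
                params.sex, spec.label(), seed, r, exc,
            )
            continue
        results.append(result)
        if collect_replications:
            rows.append(
                {
                    "replication": r,
                    "seed": seed,
                    "chi2_hl": result.chi2_hl,
                    "hl_pvalue": result.hl_pvalue,
                    "calibrated": result.calibrated,
                    "c_statistic": result.c_statistic,
                    "mean_p_obs": result.mean_p_obs,
                    "mean_p_true": result.mean_p_true,
                    "risk_difference": result.risk_difference,
                    "p90_obs": result.p90_obs,
                    "p90_true": result.p90_true,
                }
            )
    if n_failed > MAX_FAILURE_FRACTION * n_reps:
        raise ScenarioError(
            f"scenario sex={params.sex} {spec.label()}: "
            f"{n_failed}/{n_reps} replications failed"
        )
    summary = _aggregate(params.sex, params, spec, results, n_failed, n_reps, base_seed)
    if collect_replications:
        return summary, pd.DataFrame(rows)
    return summary


def summaries_to_frame(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    """Flatten scenario summaries into one row per scenario."""
    return pd.DataFrame(
        [{f.name: getattr(s, f.name) for f in fields(ScenarioSummary)} for s in summaries]
    )


def _resolve(
    cohorts: dict[str, CohortParameters] | None,
    coefficients: dict[str, RiskCoefficients] | None,
) -> tuple[dict[str, CohortParameters], dict[str, RiskCoefficients]]:
    return cohorts or DEFAULT_COHORTS, coefficients or DEFAULT_COEFFICIENTS


def _run_grid(
    grid: GridSpecification,
    scenarios: list[tuple[str, ErrorSpecification]],
    cohorts: dict[str, CohortParameters] | None,
    coefficients: dict[str, RiskCoefficients] | None,
) -> pd.DataFrame:
    cohorts, coefficients = _resolve(cohorts, coefficients)
    summaries = []
    for index, (sex, spec) in enumerate(scenarios):
        seed = grid.base_seed + SCENARIO_SEED_STRIDE * index
        summaries.append(
            run_scenario(cohorts[sex], spec, coefficients[sex], grid.n_reps, seed)
        )
    return summaries_to_frame(summaries)


def run_random_error_grid(
    grid: GridSpecification,
    cohorts: dict[str, CohortParameters] | None = None,
    coefficients: dict[str, RiskCoefficients] | None = None,
) -> pd.DataFrame:
    """Factorial ICC grid (height x weight), no bias, per sex."""
    scenarios = [
        (sex, ErrorSpecification(icc_height=icc_h, icc_weight=icc_w))
        for sex in grid.sexes
        for icc_h in grid.icc_grid
        for icc_w in grid.icc_grid
    ]
    return _run_grid(grid, scenarios, cohorts, coefficients)


def _bias_scenarios(grid: GridSpecification) -> list[ErrorSpecification]:
    """Single-axis bias sweeps: weight-only rows then height-only rows."""
    specs = [
        ErrorSpecification(bias_weight=bw) for bw in grid.bias_weight_grid_kg
    ]
    specs += [
        ErrorSpecification(bias_height=bh / 100.0)
        for bh in grid.bias_height_grid_cm
        if bh != 0.0  # the zero row is already covered by the weight sweep
    ]
    return specs


def run_bias_grid(
    grid: GridSpecification,
    cohorts: dict[str, CohortParameters] | None = None,
    coefficients: dict[str, RiskCoefficients] | None = None,
) -> pd.DataFrame:
    """Single-axis systematic-error sweeps with no random error, per sex."""
    scenarios = [(sex, spec) for sex in grid.sexes for spec in _bias_scenarios(grid)]
    return _run_grid(grid, scenarios, cohorts, coefficients)


def run_joint_grid(
    grid: GridSpecification,
    cohorts: dict[str, CohortParameters] | None = None,
    coefficients: dict[str, RiskCoefficients] | None = None,
) -> pd.DataFrame:
    """Bias sweeps crossed with random-error levels on both axes."""
    scenarios = []
    for sex in grid.sexes:
        for icc in grid.joint_icc_levels:
            for base in _bias_scenarios(grid):
                spec = ErrorSpecification(
                    icc_height=icc,
                    icc_weight=icc,
                    bias_height=base.bias_height,
                    bias_weight=base.bias_weight,
                )
                scenarios.append((sex, spec))
    return _run_grid(grid, scenarios, cohorts, coefficients)


@dataclass(frozen=True)
class ValidationReport:
    """Side-by-side comparison of a refit with the derivation equation."""

    sex: str
    reference: RiskCoefficients
    fitted: RiskCoefficients
    standard_errors: np.ndarray = field(repr=False)  # beta0, beta1, beta2
    chi2_hl: float
    hl_pvalue: float
    c_statistic: float
    flags: dict[str, bool]  # True = coefficient outside 3 published SEs

    @property
    def ok(self) -> bool:
        return not any(self.flags.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(("beta0", "beta1", "beta2")):
            rows.append(
                {
                    "sex": self.sex,
                    "coefficient": name,
                    "reference": getattr(self.reference, name),
                    "fitted": getattr(self.fitted, name),
                    "fit_se": self.standard_errors[i],
                    "outside_3se": self.flags.get(name, False),
                }
            )
        frame = pd.DataFrame(rows)
        frame["chi2_hl"] = self.chi2_hl
        frame["c_statistic"] = self.c_statistic
        return frame


def validate_against_derivation(
    params: CohortParameters,
    coeffs: RiskCoefficients,
    seed: int,
    n_override: int | None = None,
) -> ValidationReport:
    """Refit the risk equation on one error-free simulated cohort.

    Checks that a cohort generated from the published parameters gives back
    near-identical coefficients when the quadratic-logistic model is
    re-estimated, and reports the calibration and discrimination of the
    refit predictions.  Coefficients further than 3 published standard
    errors from the reference are flagged (the intercept, whose published
    standard error is unavailable, is compared against 3 refit SEs).
    """
    if n_override is not None:
        params = CohortParameters(
            sex=params.sex,
            mean_height=params.mean_height,
            sd_height=params.sd_height,
            mean_weight=params.mean_weight,
            sd_weight=params.sd_weight,
            r_hw=params.r_hw,
            n=n_override,
            reference_incidence=params.reference_incidence,
        )
    cohort = simulate_cohort(params, ErrorSpecification(), coeffs, seed)
    fitted, se, _ = fit_logistic_quadratic(cohort.true_bmi, cohort.outcome)

    published = DERIVATION_STANDARD_ERRORS.get(params.sex, {})
    flags = {}
    for i, name in enumerate(("beta0", "beta1", "beta2")):
        tolerance = 3.0 * published.get(name, se[i])
        flags[name] = bool(
            abs(getattr(fitted, name) - getattr(coeffs, name)) > tolerance
        )

    p_fit = predict_risk(fitted, cohort.true_bmi)
    hl = hosmer_lemeshow(p_fit, cohort.outcome)
    c = c_statistic(p_fit, cohort.outcome)
    return ValidationReport(
        sex=params.sex,
        reference=coeffs,
        fitted=fitted,
        standard_errors=se,
        chi2_hl=hl.chi2,
        hl_pvalue=hl.p_value,
        c_statistic=c,
        flags=flags,
    )
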