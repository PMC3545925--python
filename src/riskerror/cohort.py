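"""Synthetic cohort generation with controlled measurement error.

The generator emulates a population survey in which height and weight are
self-reported and therefore measured with error.  Each individual carries a
latent *true* height/weight pair drawn from a bivariate normal distribution,
plus an *observed* (self-reported) pair obtained by adding

* a constant directional reporting bias (height over-reported, weight
  under-reported), and
* zero-mean random error whose magnitude is controlled by an intraclass
  correlation coefficient (ICC), the fraction of the total observed variance
  attributable to true between-individual variation.

The published anthropometric moments describe the *observed* (error-containing)
measurements, so the generator is observed-anchored: the observed mean/SD and
height-weight correlation match the configured parameters for every error
level, and the latent true distribution is derived from them
(``sd_true = sd * sqrt(icc)``, true correlation disattenuated by
``1/sqrt(icc_h * icc_w)``, true mean = observed mean minus bias).

Diabetes outcomes are Bernoulli draws from the *true*-BMI risk, so the risk
equation is correct in the error-free world and any loss of performance is
attributable purely to measurement error in the predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortParameters",
    "ErrorSpecification",
    "SimulatedCohort",
    "DEFAULT_COHORTS",
    "NO_ERROR",
    "sample_true_anthropometrics",
    "add_measurement_error",
    "compute_bmi",
    "simulate_outcomes",
    "simulate_cohort",
]

# Correlations are capped just below 1 so the bivariate normal stays full rank.
_MAX_CORRELATION = 0.999

# Reporting-bias ranges (metres / kilograms) covered by the study design;
# values outside are allowed but logged, since they leave the territory the
# systematic-review evidence supports.
_STUDY_BIAS_HEIGHT_M = (0.0, 0.03)
_STUDY_BIAS_WEIGHT_KG = (-3.0, 0.0)


@dataclass(frozen=True)
class CohortParameters:
    """Sex-specific anthropometric distribution and cohort size.

    Means/SDs describe the observed (self-reported) measurements; ``r_hw`` is
    the observed height-weight correlation.  ``reference_incidence`` is the
    10-year diabetes incidence of the derivation cohort and is informational
    (outcomes are generated from the risk equation, not from this number).
    """

    sex: str
    mean_height: float  # metres
    sd_height: float  # metres
    mean_weight: float  # kilograms
    sd_weight: float  # kilograms
    r_hw: float  # observed height-weight correlation
    n: int  # cohort size
    reference_incidence: float  # proportion in [0, 1]

    def __post_init__(self) -> None:
        if self.sd_height <= 0 or self.sd_weight <= 0:
            raise ValueError("standard deviations must be positive")
        if not abs(self.r_hw) < 1:
            raise ValueError(f"r_hw must satisfy |r| < 1, got {self.r_hw}")
        if self.n <= 0:
            raise ValueError(f"cohort size must be positive, got {self.n}")
        if not 0.0 <= self.reference_incidence <= 1.0:
            raise ValueError("reference_incidence must lie in [0, 1]")


#: Derivation-cohort starting values (1996/97 National Population Health
#: Survey, Ontario, 10-year follow-up).
DEFAULT_COHORTS: dict[str, CohortParameters] = {
    "male": CohortParameters(
        sex="male",
        mean_height=1.768,
        sd_height=0.075,
        mean_weight=81.624,
        sd_weight=13.805,
        r_hw=0.475,
        n=9_177,
        reference_incidence=0.0917,
    ),
    "female": CohortParameters(
        sex="female",
        mean_height=1.627,
        sd_height=0.069,
        mean_weight=64.761,
        sd_weight=12.320,
        r_hw=0.311,
        n=10_618,
        reference_incidence=0.0735,
    ),
}


@dataclass(frozen=True)
class ErrorSpecification:
    """One measurement-error scenario.

    ``icc_height``/``icc_weight`` control random error (1 = none); biases are
    the constant reporting shifts added to the true values, in SI units
    (``bias_height`` in metres, positive = over-reported height;
    ``bias_weight`` in kilograms, negative = under-reported weight).
    """

    icc_height: float = 1.0
    icc_weight: float = 1.0
    bias_height: float = 0.0  # metres
    bias_weight: float = 0.0  # kilograms

    def __post_init__(self) -> None:
        for name in ("icc_height", "icc_weight"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        for name, (lo, hi) in (
            ("bias_height", _STUDY_BIAS_HEIGHT_M),
            ("bias_weight", _STUDY_BIAS_WEIGHT_KG),
        ):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite")
            if not lo <= value <= hi:
                logger.warning(
                    "%s=%g is outside the study range [%g, %g]",
                    name, value, lo, hi,
                )

    @property
    def is_error_free(self) -> bool:
        return (
            self.icc_height == 1.0
            and self.icc_weight == 1.0
            and self.bias_height == 0.0
            and self.bias_weight == 0.0
        )

    def label(self) -> str:
        return (
            f"icc_h={self.icc_height:g},icc_w={self.icc_weight:g},"
            f"bias_h={self.bias_height * 100:g}cm,bias_w={self.bias_weight:g}kg"
        )


def true_correlation(params: CohortParameters, spec: ErrorSpecification) -> float:
    """Disattenuated correlation between true height and true weight.

    Independent measurement error attenuates an observed correlation by
    ``sqrt(icc_h * icc_w)``; the true values are therefore generated with the
    inverse inflation so that adding error restores the observed ``r_hw``.
    Values that would exceed 1 are clipped (with a warning) to keep the
    covariance matrix positive definite.
    """
    r = params.r_hw / np.sqrt(spec.icc_height * spec.icc_weight)
    if abs(r) > 1.0:
        logger.warning(
            "disattenuated correlation %.4f exceeds 1 for %s (%s); "
            "clipping to %.3f", r, params.sex, spec.label(), _MAX_CORRELATION,
        )
    return float(np.clip(r, -_MAX_CORRELATION, _MAX_CORRELATION))


def sample_true_anthropometrics(
    params: CohortParameters,
    spec: ErrorSpecification,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the latent true height (m) and weight (kg) for one cohort.

    The true distribution is derived from the observed-anchored parameters:
    mean = observed mean - bias, SD = observed SD * sqrt(ICC), correlation
    disattenuated (see :func:`true_correlation`).
    """
    sd_h = params.sd_height * np.sqrt(spec.icc_height)
    sd_w = params.sd_weight * np.sqrt(spec.icc_weight)
    if sd_h <= 0 or sd_w <= 0:
        raise ValueError("true-value standard deviations must be positive")
    r = true_correlation(params, spec)

    z_h, z_w = rng.standard_normal((2, params.n))
    true_height = (params.mean_height - spec.bias_height) + sd_h * z_h
    true_weight = (params.mean_weight - spec.bias_weight) + sd_w * (
        r * z_h + np.sqrt(1.0 - r * r) * z_w
    )
    return true_height, true_weight


def add_measurement_error(
    true_height: np.ndarray,
    true_weight: np.ndarray,
    spec: ErrorSpecification,
    params: CohortParameters,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Produce observed (self-reported) values: true + bias + random error.

    The random errors are independent of the true values and of each other,
    with variances ``sd^2 * (1 - icc)``.  With ICC = 1 and zero bias the
    observed arrays equal the true arrays exactly.
    """
    true_height = np.asarray(true_height, dtype=float)
    true_weight = np.asarray(true_weight, dtype=float)
    if true_height.shape != true_weight.shape:
        raise ValueError(
            f"height/weight length mismatch: {true_height.shape} vs {true_weight.shape}"
        )
    n = true_height.shape[0]
    sd_eps_h = params.sd_height * np.sqrt(1.0 - spec.icc_height)
    sd_eps_w = params.sd_weight * np.sqrt(1.0 - spec.icc_weight)
    obs_height = true_height + spec.bias_height + sd_eps_h * rng.standard_normal(n)
    obs_weight = true_weight + spec.bias_weight + sd_eps_w * rng.standard_normal(n)
    return obs_height, obs_weight


def compute_bmi(height: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Body mass index: weight (kg) / height (m) squared, element-wise."""
    height = np.asarray(height, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if height.shape != weight.shape:
        raise ValueError("height and weight must have the same length")
    if np.any(height <= 0):
        raise ValueError("heights must be strictly positive to form a BMI")
    return weight / (height * height)


def simulate_outcomes(p_true: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(p) outcome draws (1 = develops diabetes)."""
    p_true = np.asarray(p_true, dtype=float)
    if not np.all(np.isfinite(p_true)):
        raise ValueError("probabilities must be finite")
    if np.any((p_true < 0.0) | (p_true > 1.0)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (rng.random(p_true.shape[0]) < p_true).astype(np.int64)


@dataclass(frozen=True)
class SimulatedCohort:
    """One simulated cohort: latent truth, observations and outcomes."""

    params: CohortParameters
    spec: ErrorSpecification
    true_height: np.ndarray = field(repr=False)
    true_weight: np.ndarray = field(repr=False)
    obs_height: np.ndarray = field(repr=False)
    obs_weight: np.ndarray = field(repr=False)
    true_bmi: np.ndarray = field(repr=False)
    obs_bmi: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return int(self.true_height.shape[0])

    def to_dataframe(self) -> pd.DataFrame:
        """Per-individual table, one row per simulated subject."""
        return pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "true_height_m": self.true_height,
                "true_weight_kg": self.true_weight,
                "obs_height_m": self.obs_height,
                "obs_weight_kg": self.obs_weight,
                "true_bmi": self.true_bmi,
                "obs_bmi": self.obs_bmi,
                "outcome": self.outcome,
            }
        )


def simulate_cohort(
    params: CohortParameters,
    spec: ErrorSpecification,
    coeffs,
    rng: np.random.Generator | int,
) -> SimulatedCohort:
    """Generate one complete cohort under a given error scenario.

    Outcomes are drawn from the risk predicted at the *true* BMI, so the risk
    equation holds exactly in the error-free world.  ``rng`` may be a seeded
    generator or an integer seed.
    """
    from .risk_model import predict_risk  # deferred: avoids import cycle

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    true_h, true_w = sample_true_anthropometrics(params, spec, rng)
    obs_h, obs_w = add_measurement_error(true_h, true_w, spec, params, rng)
    true_bmi = compute_bmi(true_h, true_w)
    obs_bmi = compute_bmi(obs_h, obs_w)
    p_true = predict_risk(coeffs, true_bmi)
    outcome = simulate_outcomes(p_true, rng)
    return SimulatedCohort(
        params=params,
        spec=spec,
        true_height=true_h,
        true_weight=true_w,
        obs_height=obs_h,
        obs_weight=obs_w,
        true_bmi=true_bmi,
        obs_bmi=obs_bmi,
        outcome=outcome,
    )


#: Convenience scenario: no random error, no bias.
NO_ERROR = ErrorSpecification()
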