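"""Quadratic-logistic BMI -> 10-year diabetes risk equation.

The model is ``logit(p) = b0 + b1*BMI + b2*BMI^2`` with b2 < 0, so risk rises
with BMI up to an interior maximum at ``-b1/(2*b2)`` (~48 kg/m^2 at the
default coefficients) and is not monotone over the whole real line.  During
scenario evaluation the coefficients stay fixed — the point of the study is
external validation of a frozen equation — and refitting exists only as a
cohort-validation utility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "RiskCoefficients",
    "DEFAULT_COEFFICIENTS",
    "DERIVATION_STANDARD_ERRORS",
    "FitError",
    "ConvergenceError",
    "SeparationError",
    "FitReport",
    "predict_risk",
    "fit_logistic_quadratic",
]


@dataclass(frozen=True)
class RiskCoefficients:
    """Log-odds coefficients of the quadratic-logistic risk equation."""

    beta0: float  # intercept
    beta1: float  # per kg/m^2
    beta2: float  # per (kg/m^2)^2
    sex: str = ""

    @property
    def bmi_at_max_risk(self) -> float:
        """BMI at which predicted risk peaks (only meaningful for beta2 < 0)."""
        if self.beta2 == 0:
            return float("inf")
        return -self.beta1 / (2.0 * self.beta2)

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])


#: Derivation-cohort coefficients (National Population Health Survey,
#: 10-year follow-up), per sex.
DEFAULT_COEFFICIENTS: dict[str, RiskCoefficients] = {
    "male": RiskCoefficients(beta0=-10.4034, beta1=0.4202, beta2=-0.00437, sex="male"),
    "female": RiskCoefficients(beta0=-10.8967, beta1=0.4565, beta2=-0.00509, sex="female"),
}

#: Published standard errors of the derivation-cohort fit (BMI and BMI^2 terms;
#: the intercept standard error was not reported).
DERIVATION_STANDARD_ERRORS: dict[str, dict[str, float]] = {
    "male": {"beta1": 0.0383, "beta2": 0.000618},
    "female": {"beta1": 0.0554, "beta2": 0.00091},
}


class FitError(RuntimeError):
    """Base class for logistic-fit failures."""


class ConvergenceError(FitError):
    """IRLS failed to converge within the iteration budget."""


class SeparationError(FitError):
    """The likelihood is unbounded (complete or quasi-complete separation)."""


@dataclass(frozen=True)
class FitReport:
    iterations: int
    log_likelihood: float
    converged: bool


def predict_risk(coeffs: RiskCoefficients, bmi: np.ndarray) -> np.ndarray:
    """Predicted 10-year diabetes probability at each BMI value.

    Uses an overflow-safe inverse logit, so extreme BMI draws (possible under
    heavy measurement error) saturate smoothly instead of raising.
    """
    bmi = np.asarray(bmi, dtype=float)
    if not np.all(np.isfinite(bmi)):
        raise ValueError("BMI values must be finite")
    eta = coeffs.beta0 + bmi * (coeffs.beta1 + coeffs.beta2 * bmi)
    return expit(eta)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), with a stable log1p-exp
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_logistic_quadratic(
    bmi: np.ndarray,
    outcome: np.ndarray,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    loglik_rtol: float = 1e-10,
) -> tuple[RiskCoefficients, np.ndarray, FitReport]:
    """Maximum-likelihood refit of the quadratic-logistic model.

    Iteratively reweighted least squares on the design {1, BMI, BMI^2}; each
    step solves the weighted least-squares problem via QR (``lstsq``) rather
    than the normal equations, since the uncentred quadratic design is poorly
    conditioned.  Returns the fitted coefficients, their standard errors
    (from the inverse Fisher information) and a convergence report.
    """
    bmi = np.asarray(bmi, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if bmi.shape != y.shape:
        raise ValueError("bmi and outcome must have the same length")
    if bmi.shape[0] < 10:
        raise ValueError("need at least 10 observations to refit")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("outcomes must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both outcome classes must be present to refit")

    X = np.column_stack([np.ones_like(bmi), bmi, bmi * bmi])
    prevalence = y.mean()
    beta = np.array([np.log(prevalence / (1.0 - prevalence)), 0.0, 0.0])
    eta = X @ beta
    loglik = _log_likelihood(eta, y)

    for iteration in range(1, max_iter + 1):
        p = expit(eta)
        w = p * (1.0 - p)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < score_tol:
            break

        w_safe = np.maximum(w, 1e-12)
        sqrt_w = np.sqrt(w_safe)
        z = eta + (y - p) / w_safe
        beta_new, *_ = np.linalg.lstsq(sqrt_w[:, None] * X, sqrt_w * z, rcond=None)
        if not np.all(np.isfinite(beta_new)):
            raise SeparationError("diverging coefficients; data may be separated")

        eta_new = X @ beta_new
        loglik_new = _log_likelihood(eta_new, y)
        beta, eta = beta_new, eta_new

        # fitted probabilities pinned at 0/1 for every subject of each class
        # mean the likelihood is unbounded
        p_new = expit(eta)
        if np.min(p_new[y == 1], initial=1.0) > 1 - 1e-10 and np.max(
            p_new[y == 0], initial=0.0
        ) < 1e-10:
            raise SeparationError("complete separation: fitted probabilities at 0/1")

        if abs(loglik_new - loglik) <= loglik_rtol * (abs(loglik) + 1e-300):
            loglik = loglik_new
            break
        loglik = loglik_new
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    # a log-likelihood at (numerically) zero means every subject is fitted
    # perfectly: the MLE does not exist
    if loglik > -1e-6:
        raise SeparationError("complete separation: likelihood attains zero")

    p = expit(eta)
    w = np.maximum(p * (1.0 - p), 1e-12)
    # covariance = (X' W X)^{-1} via the R factor of the weighted design
    _, r_factor = np.linalg.qr(np.sqrt(w)[:, None] * X)
    r_inv = np.linalg.solve(r_factor, np.eye(3))
    cov = r_inv @ r_inv.T
    se = np.sqrt(np.diag(cov))

    coeffs = RiskCoefficients(
        beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]), sex="refit"
    )
    report = FitReport(iterations=iteration, log_likelihood=loglik, converged=True)
    return coeffs, se, report
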