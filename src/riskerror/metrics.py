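"""Calibration and discrimination metrics for one simulated cohort.

Calibration is the grouped (modified) Hosmer-Lemeshow chi-square used for
external validation of a frozen risk equation: subjects are split into
deciles of predicted risk and the squared observed-minus-expected event
counts are scaled by the binomial variance ``n_g * pbar_g * (1 - pbar_g)``.
Following the convention for evaluating observed against predicted values of
risk algorithms, a fixed cutoff of 20 (the 99th percentile of a chi-square
with 8 degrees of freedom) marks sufficient calibration.

Discrimination is the C-statistic (area under the ROC curve): the probability
that a randomly chosen case is assigned a higher predicted risk than a
randomly chosen non-case, ties counted one half.  It is computed through the
rank-sum (Mann-Whitney) identity in O(n log n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .cohort import SimulatedCohort
from .risk_model import RiskCoefficients, predict_risk

__all__ = [
    "MetricError",
    "HL_CALIBRATION_CUTOFF",
    "HosmerLemeshowResult",
    "ReplicationResult",
    "hosmer_lemeshow",
    "c_statistic",
    "is_calibrated",
    "evaluate_replication",
]


class MetricError(ValueError):
    """A metric is undefined for the given cohort (degenerate input)."""


#: Chi-square value below which a replication counts as calibrated
#: (99th percentile of a chi-square distribution with 8 degrees of freedom,
#: rounded to the conventional cutoff of 20).
HL_CALIBRATION_CUTOFF = 20.0


def is_calibrated(chi2_hl: float) -> bool:
    """Whether a Hosmer-Lemeshow statistic passes the fixed cutoff of 20."""
    return chi2_hl < HL_CALIBRATION_CUTOFF


@dataclass(frozen=True)
class HosmerLemeshowResult:
    chi2: float
    p_value: float
    table: pd.DataFrame  # one row per risk group, for audit


def hosmer_lemeshow(
    p: np.ndarray, y: np.ndarray, n_groups: int = 10
) -> HosmerLemeshowResult:
    """Grouped chi-square comparing observed and predicted events.

    Subjects are sorted by predicted risk (stable sort, so tied predictions
    keep their input order) and partitioned into ``n_groups`` contiguous
    groups whose sizes differ by at most one; when the cohort does not divide
    evenly the extra subjects go to the lowest-risk groups.  The p-value uses
    ``n_groups - 2`` degrees of freedom.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("p and y must have the same length")
    if p.shape[0] < n_groups:
        raise MetricError(
            f"need at least {n_groups} subjects for {n_groups} risk groups"
        )
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("predicted risks must lie in [0, 1]")

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    y_sorted = y[order]

    rows = []
    statistic = 0.0
    for g, (p_g, y_g) in enumerate(
        zip(np.array_split(p_sorted, n_groups), np.array_split(y_sorted, n_groups))
    ):
        n_g = p_g.shape[0]
        expected = float(p_g.sum())
        observed = float(y_g.sum())
        p_bar = expected / n_g
        if p_bar <= 0.0 or p_bar >= 1.0:
            raise MetricError(
                f"risk group {g} has degenerate mean predicted risk {p_bar}"
            )
        contribution = (observed - expected) ** 2 / (n_g * p_bar * (1.0 - p_bar))
        statistic += contribution
        rows.append(
            {
                "group": g,
                "n": n_g,
                "observed": observed,
                "expected": expected,
                "mean_risk": p_bar,
                "contribution": contribution,
            }
        )

    p_value = float(chi2.sf(statistic, df=n_groups - 2))
    return HosmerLemeshowResult(
        chi2=float(statistic), p_value=p_value, table=pd.DataFrame(rows)
    )


def c_statistic(p: np.ndarray, y: np.ndarray) -> float:
    """Concordance between predicted risk and binary outcome (ties = 1/2)."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError("p and y must have the same length")
    cases = y == 1
    n_cases = int(np.count_nonzero(cases))
    n_controls = p.shape[0] - n_cases
    if n_cases == 0 or n_controls == 0:
        raise MetricError("C-statistic requires both outcome classes")
    ranks = rankdata(p)  # midranks handle ties
    rank_sum = float(ranks[cases].sum())
    return (rank_sum - n_cases * (n_cases + 1) / 2.0) / (n_cases * n_controls)


@dataclass(frozen=True)
class ReplicationResult:
    """Performance of the frozen risk equation on one simulated cohort.

    Predicted risk is evaluated twice per subject — from observed
    (self-reported) BMI and from the latent true BMI — while outcomes always
    come from the true risk.  The calibration and discrimination metrics are
    those of the observed-BMI predictions against the outcomes.
    """

    chi2_hl: float
    hl_pvalue: float
    calibrated: bool
    c_statistic: float
    mean_p_obs: float
    mean_p_true: float
    risk_difference: float  # mean_p_obs - mean_p_true, probability scale
    min_p_obs: float
    p90_obs: float
    max_p_obs: float
    min_p_true: float
    p90_true: float
    max_p_true: float
    mean_obs_bmi: float
    sd_obs_bmi: float
    mean_true_bmi: float
    sd_true_bmi: float


def evaluate_replication(
    cohort: SimulatedCohort, coeffs: RiskCoefficients, n_groups: int = 10
) -> ReplicationResult:
    """Score one cohort: H-L and C of observed-BMI risk, risk differences."""
    p_obs = predict_risk(coeffs, cohort.obs_bmi)
    p_true = predict_risk(coeffs, cohort.true_bmi)
    hl = hosmer_lemeshow(p_obs, cohort.outcome, n_groups=n_groups)
    c = c_statistic(p_obs, cohort.outcome)
    mean_p_obs = float(p_obs.mean())
    mean_p_true = float(p_true.mean())
    return ReplicationResult(
        chi2_hl=hl.chi2,
        hl_pvalue=hl.p_value,
        calibrated=is_calibrated(hl.chi2),
        c_statistic=c,
        mean_p_obs=mean_p_obs,
        mean_p_true=mean_p_true,
        risk_difference=mean_p_obs - mean_p_true,
        min_p_obs=float(p_obs.min()),
        p90_obs=float(np.quantile(p_obs, 0.9)),
        max_p_obs=float(p_obs.max()),
        min_p_true=float(p_true.min()),
        p90_true=float(np.quantile(p_true, 0.9)),
        max_p_true=float(p_true.max()),
        mean_obs_bmi=float(cohort.obs_bmi.mean()),
        sd_obs_bmi=float(cohort.obs_bmi.std(ddof=1)),
        mean_true_bmi=float(cohort.true_bmi.mean()),
        sd_true_bmi=float(cohort.true_bmi.std(ddof=1)),
    )
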