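"""Cohort generator: distributional structure, error partition, determinism."""

import numpy as np
import pytest

from riskerror import (
    DEFAULT_COEFFICIENTS,
    DEFAULT_COHORTS,
    CohortParameters,
    ErrorSpecification,
    add_measurement_error,
    compute_bmi,
    sample_true_anthropometrics,
    simulate_cohort,
    simulate_outcomes,
)
from riskerror.cohort import true_correlation

from conftest import BASE_SEED


class TestParameterDefaults:
    def test_bundled_survey_values(self):
        male = DEFAULT_COHORTS["male"]
        assert (male.mean_height, male.sd_height) == (1.768, 0.075)
        assert (male.mean_weight, male.sd_weight) == (81.624, 13.805)
        assert (male.r_hw, male.n, male.reference_incidence) == (0.475, 9177, 0.0917)
        female = DEFAULT_COHORTS["female"]
        assert (female.mean_height, female.sd_height) == (1.627, 0.069)
        assert (female.mean_weight, female.sd_weight) == (64.761, 12.320)
        assert (female.r_hw, female.n, female.reference_incidence) == (0.311, 10618, 0.0735)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sd_height": 0.0},
            {"sd_weight": -1.0},
            {"r_hw": 1.0},
            {"n": 0},
            {"reference_incidence": 1.2},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(
            sex="male", mean_height=1.768, sd_height=0.075, mean_weight=81.624,
            sd_weight=13.805, r_hw=0.475, n=9177, reference_incidence=0.0917,
        )
        with pytest.raises(ValueError):
            CohortParameters(**{**base, **kwargs})

    @pytest.mark.parametrize("kwargs", [{"icc_height": 0.0}, {"icc_weight": 1.5}])
    def test_invalid_icc_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ErrorSpecification(**kwargs)

    def test_out_of_study_range_bias_is_flagged_not_rejected(self, caplog):
        with caplog.at_level("WARNING"):
            spec = ErrorSpecification(bias_weight=-5.0)
        assert spec.bias_weight == -5.0
        assert any("bias_weight" in record.message for record in caplog.records)


class TestTrueAnthropometrics:
    def test_no_error_moments_match_survey(self, female_params, rng):
        spec = ErrorSpecification()
        height, weight = sample_true_anthropometrics(female_params, spec, rng)
        n = female_params.n
        # 4 standard errors of the mean / SD at the configured n
        assert height.mean() == pytest.approx(1.627, abs=4 * 0.069 / np.sqrt(n))
        assert height.std(ddof=1) == pytest.approx(0.069, rel=0.02)
        assert weight.mean() == pytest.approx(64.761, abs=4 * 12.32 / np.sqrt(n))
        assert weight.std(ddof=1) == pytest.approx(12.320, rel=0.02)

    def test_true_distribution_shrinks_with_icc(self, male_params, rng):
        spec = ErrorSpecification(icc_height=0.64, icc_weight=0.49)
        height, weight = sample_true_anthropometrics(male_params, spec, rng)
        assert height.std(ddof=1) == pytest.approx(0.075 * 0.8, rel=0.03)
        assert weight.std(ddof=1) == pytest.approx(13.805 * 0.7, rel=0.03)

    def test_bias_shifts_true_mean_not_observed(self, female_params, rng):
        spec = ErrorSpecification(bias_weight=-3.0)
        height, weight = sample_true_anthropometrics(female_params, spec, rng)
        # true weight sits 3 kg above the observed anchor
        assert weight.mean() == pytest.approx(67.761, abs=0.5)
        obs_h, obs_w = add_measurement_error(height, weight, spec, female_params, rng)
        assert obs_w.mean() == pytest.approx(64.761, abs=0.5)

    def test_true_mean_bmi_under_weight_bias(self, female_params, female_coeffs):
        # replication-averaged mean of true BMI under a -3 kg reporting bias
        spec = ErrorSpecification(bias_weight=-3.0)
        means = []
        for r in range(20):
            cohort = simulate_cohort(female_params, spec, female_coeffs, BASE_SEED + r)
            means.append(cohort.true_bmi.mean())
        assert np.mean(means) == pytest.approx(25.61, abs=0.05)

    def test_disattenuated_correlation_clip_warns(self, caplog):
        params = CohortParameters(
            sex="male", mean_height=1.768, sd_height=0.075, mean_weight=81.624,
            sd_weight=13.805, r_hw=0.9, n=100, reference_incidence=0.1,
        )
        spec = ErrorSpecification(icc_height=0.5, icc_weight=0.5)
        with caplog.at_level("WARNING"):
            r = true_correlation(params, spec)
        assert r == 0.999
        assert any("clipping" in record.message for record in caplog.records)


class TestMeasurementError:
    def test_no_error_identity_is_exact(self, params, rng):
        spec = ErrorSpecification()
        height, weight = sample_true_anthropometrics(params, spec, rng)
        obs_h, obs_w = add_measurement_error(height, weight, spec, params, rng)
        np.testing.assert_array_equal(obs_h, height)
        np.testing.assert_array_equal(obs_w, weight)

    def test_error_variance_partition(self, male_params, rng):
        """Var(obs) = Var(true) + Var(error) and empirical ICC matches.

        The error component is recovered exactly as obs - true - bias, so the
        moment identity can be checked on the generated pieces themselves.
        """
        spec = ErrorSpecification(icc_height=0.7, icc_weight=0.6, bias_height=0.02)
        height, weight = sample_true_anthropometrics(male_params, spec, rng)
        obs_h, obs_w = add_measurement_error(height, weight, spec, male_params, rng)
        n = male_params.n
        for true, obs, bias, icc in (
            (height, obs_h, 0.02, 0.7),
            (weight, obs_w, 0.0, 0.6),
        ):
            eps = obs - true - bias
            var_true, var_eps, var_obs = true.var(), eps.var(), obs.var()
            # three Monte-Carlo standard errors of a variance (~ sqrt(2/n))
            mc = 3 * np.sqrt(2.0 / n)
            assert var_obs == pytest.approx(var_true + var_eps, rel=mc * 2)
            assert var_true / var_obs == pytest.approx(icc, rel=mc * 3)
            # error independent of the true value
            rho = np.corrcoef(eps, true)[0, 1]
            assert abs(rho) < 4 / np.sqrt(n)

    def test_attenuation_restores_observed_correlation(self, female_params, rng):
        spec = ErrorSpecification(icc_height=0.6, icc_weight=0.8)
        height, weight = sample_true_anthropometrics(female_params, spec, rng)
        obs_h, obs_w = add_measurement_error(height, weight, spec, female_params, rng)
        r_true = np.corrcoef(height, weight)[0, 1]
        r_obs = np.corrcoef(obs_h, obs_w)[0, 1]
        expected_true = 0.311 / np.sqrt(0.6 * 0.8)
        mc = 4 / np.sqrt(female_params.n)
        assert r_true == pytest.approx(expected_true, abs=3 * mc)
        assert r_obs == pytest.approx(0.311, abs=3 * mc)

    def test_observed_bmi_dispersion_example(self, female_params, female_coeffs):
        # at ICC 0.8 on both axes the observed BMI spread exceeds the true one
        spec = ErrorSpecification(icc_height=0.8, icc_weight=0.8)
        obs_sd, true_sd = [], []
        for r in range(20):
            cohort = simulate_cohort(female_params, spec, female_coeffs, BASE_SEED + r)
            obs_sd.append(cohort.obs_bmi.std(ddof=1))
            true_sd.append(cohort.true_bmi.std(ddof=1))
        assert np.mean(obs_sd) == pytest.approx(4.51, abs=0.05)
        assert np.mean(true_sd) == pytest.approx(3.87, abs=0.05)

    def test_bmi_sd_inflation_monotone_in_icc(self, male_params, male_coeffs):
        """Observed-minus-true BMI spread grows as the ICC falls."""
        inflation = []
        for icc in (1.0, 0.9, 0.7, 0.5):
            spec = ErrorSpecification(icc_height=icc, icc_weight=icc)
            deltas = [
                (c := simulate_cohort(male_params, spec, male_coeffs, BASE_SEED + r))
                .obs_bmi.std(ddof=1) - c.true_bmi.std(ddof=1)
                for r in range(5)
            ]
            inflation.append(np.mean(deltas))
        assert inflation[0] == pytest.approx(0.0, abs=1e-12)
        assert all(a < b for a, b in zip(inflation, inflation[1:]))

    def test_length_mismatch_rejected(self, male_params, rng):
        with pytest.raises(ValueError, match="mismatch"):
            add_measurement_error(
                np.ones(5), np.ones(6), ErrorSpecification(), male_params, rng
            )


class TestBmiAndOutcomes:
    @pytest.mark.parametrize(
        "height, weight, expected",
        [
            (1.0, 25.0, 25.0),
            (2.0, 100.0, 25.0),
            (1.768, 81.624, 81.624 / 1.768**2),
        ],
    )
    def test_bmi_values(self, height, weight, expected):
        assert compute_bmi([height], [weight])[0] == pytest.approx(expected)

    def test_bmi_rejects_nonpositive_height(self):
        with pytest.raises(ValueError, match="positive"):
            compute_bmi([1.7, 0.0], [70.0, 70.0])

    def test_degenerate_probabilities(self, rng):
        outcomes = simulate_outcomes(np.array([0.0, 1.0, 0.0, 1.0]), rng)
        np.testing.assert_array_equal(outcomes, [0, 1, 0, 1])

    def test_probability_bounds_enforced(self, rng):
        with pytest.raises(ValueError):
            simulate_outcomes(np.array([0.5, 1.2]), rng)
        with pytest.raises(ValueError):
            simulate_outcomes(np.array([-0.1]), rng)

    def test_outcome_mean_tracks_probability_mean(self):
        """Binomial oracle: mean outcome within 3 SE of mean(p) almost always."""
        p = np.random.default_rng(7).uniform(0.01, 0.3, size=5000)
        se = np.sqrt(np.mean(p * (1 - p)) / p.size)
        hits = 0
        for r in range(100):
            outcome = simulate_outcomes(p, np.random.default_rng(BASE_SEED + r))
            hits += abs(outcome.mean() - p.mean()) <= 3 * se
        assert hits >= 99

    def test_no_error_incidence_near_reference(self, params, coeffs):
        means = [
            simulate_cohort(params, ErrorSpecification(), coeffs, BASE_SEED + r)
            .outcome.mean()
            for r in range(10)
        ]
        # combined Monte-Carlo and model-approximation tolerance
        assert np.mean(means) == pytest.approx(params.reference_incidence, abs=0.004)


class TestDeterminism:
    def test_identical_seed_gives_identical_cohort(self, params, coeffs):
        spec = ErrorSpecification(icc_height=0.8, icc_weight=0.9, bias_weight=-1.0)
        a = simulate_cohort(params, spec, coeffs, 123)
        b = simulate_cohort(params, spec, coeffs, 123)
        for attr in ("true_height", "true_weight", "obs_height", "obs_weight",
                     "true_bmi", "obs_bmi", "outcome"):
            np.testing.assert_array_equal(getattr(a, attr), getattr(b, attr))

    def test_dataframe_dump_schema(self, no_error_cohort):
        frame = no_error_cohort.to_dataframe()
        assert list(frame.columns) == [
            "id", "true_height_m", "true_weight_kg", "obs_height_m",
            "obs_weight_kg", "true_bmi", "obs_bmi", "outcome",
        ]
        assert len(frame) == no_error_cohort.params.n
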