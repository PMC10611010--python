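"""Synthetic cohort generator: calibration, closure, reproducibility, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pm25ascvd import (
    CONSTITUENTS,
    CovariateConfig,
    ExposureConfig,
    MonthlySeries,
    OutcomeConfig,
    apply_exclusions,
    assign_outcome,
    generate_cohort,
    sample_covariates,
    sample_exposures,
    window_average,
)
from pm25ascvd.cohort import CalibrationError, CoverageError, TOTAL_PM25_MEAN


class TestExposures:
    def test_total_mean_matches_configured_value(self):
        cfg = ExposureConfig()
        df = sample_exposures(cfg, 31_162, seed=1)
        se = 9.602 / np.sqrt(31_162)
        assert abs(df["pm25"].mean() - TOTAL_PM25_MEAN) < 2 * se

    def test_constituent_means_within_3se(self):
        cfg = ExposureConfig()
        n = 20_000
        df = sample_exposures(cfg, n, seed=2)
        for name in CONSTITUENTS:
            se = cfg.sigma[name] / np.sqrt(n)
            assert abs(df[name].mean() - cfg.mu[name]) < 3 * se

    def test_default_correlations_span_expected_range(self):
        df = sample_exposures(ExposureConfig(), 31_162, seed=3)
        corr = df[list(CONSTITUENTS)].corr().to_numpy()
        off = corr[~np.eye(6, dtype=bool)]
        assert off.min() > 0.45 and off.max() < 1.0
        assert (off > 0).all()

    def test_identity_correlation_gives_independence(self):
        cfg = ExposureConfig(corr=np.eye(6))
        df = sample_exposures(cfg, 10_000, seed=4)
        corr = df[list(CONSTITUENTS)].corr().to_numpy()
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_exact_sum_closure_is_machine_exact(self):
        cfg = ExposureConfig(closure_mode="exact_sum")
        df = sample_exposures(cfg, 500, seed=5)
        gap = df["pm25"] - df[list(CONSTITUENTS)].sum(axis=1)
        assert np.abs(gap).max() == 0.0

    def test_all_concentrations_nonnegative_even_lognormal(self):
        for dist in ("truncated_normal", "lognormal"):
            df = sample_exposures(ExposureConfig(distribution=dist), 2_000, seed=6)
            assert (df.to_numpy() >= 0).all()

    def test_non_psd_correlation_rejected_naming_eigenvalue(self):
        bad = np.full((6, 6), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99
        with pytest.raises(ValueError, match="eigenvalue"):
            sample_exposures(ExposureConfig(corr=bad), 10, seed=0)

    def test_negative_sigma_rejected(self):
        cfg = ExposureConfig()
        cfg.sigma["BC"] = -1.0
        with pytest.raises(ValueError, match="sigma"):
            sample_exposures(cfg, 10, seed=0)

    def test_reproducible_by_seed(self):
        a = sample_exposures(ExposureConfig(), 100, seed=9)
        b = sample_exposures(ExposureConfig(), 100, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCovariates:
    def test_category_frequencies_within_3se(self):
        cfg = CovariateConfig()
        n = 31_162
        df = sample_covariates(cfg, n, seed=1)
        for name, probs in cfg.categorical_fields().items():
            for level, p in probs.items():
                if p in (0.0, 1.0):
                    continue
                se = np.sqrt(p * (1 - p) / n)
                obs = (df[name] == level).mean()
                assert abs(obs - p) < 3 * se, (name, level)

    def test_female_share_near_61_percent(self):
        df = sample_covariates(CovariateConfig(), 31_162, seed=2)
        p = 0.60968
        se = np.sqrt(p * (1 - p) / 31_162)
        assert abs((df["gender"] == "female").mean() - p) < 2 * se

    def test_degenerate_probability_yields_constant_column(self):
        cfg = CovariateConfig(gender={"female": 1.0, "male": 0.0})
        df = sample_covariates(cfg, 200, seed=3)
        assert (df["gender"] == "female").all()

    def test_invalid_probability_vector_rejected(self):
        cfg = CovariateConfig(gender={"female": 0.6, "male": 0.5})
        with pytest.raises(ValueError, match="sum"):
            sample_covariates(cfg, 10, seed=0)

    def test_same_seed_identical_tables(self):
        a = sample_covariates(CovariateConfig(), 500, seed=4)
        b = sample_covariates(CovariateConfig(), 500, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestOutcome:
    def test_null_model_prevalence_calibrated(self):
        cohort = generate_cohort(50_000, seed=42, outcome_config=OutcomeConfig())
        assert 0.276 <= cohort["high_risk"].mean() <= 0.286

    def test_prevalence_calibration_with_strong_effects(self):
        cohort = generate_cohort(
            50_000, seed=43,
            outcome_config=OutcomeConfig(true_beta={"BC": np.log(1.493)}),
        )
        assert abs(cohort["high_risk"].mean() - 0.28143) < 0.005

    def test_symmetric_target_gives_centered_intercept(self):
        rng = np.random.default_rng(0)
        cohort = pd.DataFrame({"x": rng.standard_normal(40_000)})
        out = assign_outcome(
            cohort, OutcomeConfig(true_beta={"x": 0.0}, target_prevalence=0.5, seed=1)
        )
        assert abs(out.attrs["outcome_intercept"]) < 1e-3

    def test_unreachable_prevalence_reported(self):
        cohort = pd.DataFrame({"x": np.full(100, 1e6)})
        with pytest.raises(CalibrationError, match="unreachable"):
            assign_outcome(
                cohort,
                OutcomeConfig(true_beta={"x": -1.0}, target_prevalence=0.5),
            )

    def test_chinapar_mechanism_thresholds_at_10_percent(self):
        from pm25ascvd.risk import example_coefficient_table

        cohort = generate_cohort(2_000, seed=8)
        out = assign_outcome(
            cohort.drop(columns=["risk", "high_risk"]),
            OutcomeConfig(mechanism="chinapar"),
            risk_table=example_coefficient_table(),
        )
        assert ((out["risk"] >= 0.10) == (out["high_risk"] == 1)).all()


def _series(values, start=(2013, 7), baseline=(2016, 7)):
    periods = pd.period_range(
        pd.Period(year=start[0], month=start[1], freq="M"),
        periods=len(values), freq="M",
    )
    return MonthlySeries(
        participant_id=1,
        pollutant="pm25",
        values=pd.DataFrame(
            {"year": periods.year, "month": periods.month, "value": values}
        ),
        baseline=baseline,
    )


class TestWindowAverage:
    def test_constant_series(self):
        assert window_average(_series([80.16] * 36), 3) == pytest.approx(80.16)

    def test_arithmetic_mean_of_1_to_36(self):
        assert window_average(_series(list(range(1, 37))), 3) == pytest.approx(18.5)

    def test_short_series_raises_coverage_error_naming_month(self):
        with pytest.raises(CoverageError, match="2013-07"):
            window_average(_series([1.0] * 35, start=(2013, 8)), 3)

    def test_baseline_month_excluded(self):
        # 37 months ending at the baseline month: the baseline value (999)
        # must not enter the 36-month average
        vals = [1.0] * 36 + [999.0]
        s = _series(vals, start=(2013, 7), baseline=(2016, 7))
        assert window_average(s, 3) == pytest.approx(1.0)


class TestExclusions:
    def test_reference_cascade(self):
        remaining, audit = apply_exclusions(39_259, 476, 3_537, 4_084)
        assert remaining == 31_162
        assert [a["remaining"] for a in audit] == [39_259, 38_783, 35_246, 31_162]

    def test_no_exclusions(self):
        assert apply_exclusions(100, 0, 0, 0)[0] == 100

    def test_infeasible_cascade_errors(self):
        with pytest.raises(ValueError):
            apply_exclusions(10, 5, 6, 0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 200),
    seed=st.integers(0, 2**31 - 1),
    mode=st.sampled_from(["exact_sum", "residual_mass"]),
)
def test_exposure_invariants_property(n, seed, mode):
    """Nonnegativity, positive total, and exact closure hold for any draw."""
    df = sample_exposures(ExposureConfig(closure_mode=mode), n, seed)
    assert (df.to_numpy() >= 0).all()
    assert (df["pm25"] > 0).all()
    if mode == "exact_sum":
        gap = df["pm25"] - df[list(CONSTITUENTS)].sum(axis=1)
        assert np.abs(gap).max() == 0.0
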