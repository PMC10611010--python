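"""Risk engine: Cox-score arithmetic, classification threshold, monotonicity."""

import io

import numpy as np
import pandas as pd
import pytest

from pm25ascvd.risk import (
    RiskCoefficientTable,
    RiskTerm,
    classify_risk,
    example_coefficient_table,
    linear_predictor,
    load_coefficient_table,
    score_cohort,
    ten_year_risk,
)


def _table(terms, s0=0.95):
    return RiskCoefficientTable(sex="any", terms=terms, s0=s0)


class TestLinearPredictor:
    def test_zero_coefficients_give_zero_lp(self):
        table = _table([RiskTerm("age", "identity", 0.0, 50.0, field="age")])
        rec = pd.DataFrame({"age": [44.0, 91.0]})
        assert np.allclose(linear_predictor(rec, table, validate_ranges=False), 0.0)

    def test_single_term_arithmetic(self):
        table = _table([RiskTerm("x", "identity", 0.5, 0.0, field="x")])
        rec = pd.DataFrame({"x": [2.0]})
        assert linear_predictor(rec, table) == pytest.approx(1.0)

    def test_three_term_dot_product_matches_hand_value(self):
        # 0.07*60 + 0.6*ln(190) - 0.5*1 = 6.84759269...
        table = _table(
            [
                RiskTerm("age", "identity", 0.07, 55.0, field="age"),
                RiskTerm("log_tc", "log", 0.6, 5.2, field="tc"),
                RiskTerm("diab", "indicator", -0.5, 0.1, field="diabetes", level=1),
            ]
        )
        rec = pd.DataFrame({"age": [60.0], "tc": [190.0], "diabetes": [1]})
        expected = 0.07 * 60 + 0.6 * np.log(190.0) - 0.5
        assert linear_predictor(rec, table)[0] == pytest.approx(expected, abs=1e-12)

    def test_missing_field_named_in_error(self):
        table = _table([RiskTerm("age", "identity", 0.1, 50.0, field="age")])
        with pytest.raises(KeyError, match="age"):
            linear_predictor(pd.DataFrame({"sbp": [120.0]}), table)

    def test_product_term_uses_previously_computed_terms(self):
        table = _table(
            [
                RiskTerm("sbp", "identity", 0.0, 120.0, field="sbp"),
                RiskTerm("treated", "indicator", 0.0, 0.1, field="bp_treated", level=1),
                RiskTerm("sbp_x_treated", "product", 0.01, 12.0,
                         factors=("sbp", "treated")),
            ]
        )
        rec = pd.DataFrame({"sbp": [140.0], "bp_treated": [1]})
        assert linear_predictor(rec, table)[0] == pytest.approx(1.4)

    def test_out_of_range_value_warns_not_errors(self):
        table = _table([RiskTerm("sbp", "identity", 0.0, 120.0, field="sbp")])
        with pytest.warns(UserWarning, match="sbp"):
            linear_predictor(pd.DataFrame({"sbp": [300.0]}), table)


class TestTenYearRisk:
    def test_mean_centered_lp_gives_one_minus_s0(self):
        table = _table([RiskTerm("x", "identity", 0.3, 2.0, field="x")], s0=0.95)
        res = ten_year_risk(table.lp_mean, table)
        assert res.risk[0] == pytest.approx(0.05)

    def test_ln2_above_mean_squares_the_survival(self):
        table = _table([RiskTerm("x", "identity", 0.0, 0.0, field="x")], s0=0.95)
        res = ten_year_risk(np.log(2.0), table)
        assert res.risk[0] == pytest.approx(1 - 0.95**2)
        assert res.risk[0] == pytest.approx(0.0975)

    def test_risk_vanishes_as_lp_decreases(self):
        table = _table([RiskTerm("x", "identity", 0.0, 0.0, field="x")], s0=0.95)
        assert ten_year_risk(-40.0, table).risk[0] == pytest.approx(0.0, abs=1e-12)

    def test_risk_strictly_increasing_and_bounded(self):
        table = _table([RiskTerm("x", "identity", 0.0, 0.0, field="x")], s0=0.9)
        # stay clear of float saturation at extreme linear predictors
        lps = np.linspace(-8, 4, 101)
        risk = ten_year_risk(lps, table).risk
        assert (np.diff(risk) > 0).all()
        assert risk.min() > 0 and risk.max() < 1

    def test_invalid_s0_rejected_at_construction(self):
        with pytest.raises(ValueError, match="S0"):
            _table([RiskTerm("x", "identity", 0.0, 0.0, field="x")], s0=1.0)


class TestClassification:
    @pytest.mark.parametrize(
        "risk,expected",
        [(0.10, "high"), (0.0999, "low"), (0.28143, "high"), (0.0, "low"), (1.0, "high")],
    )
    def test_threshold_inclusive_on_high_side(self, risk, expected):
        assert classify_risk(risk)[0] == expected

    def test_out_of_range_risk_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(1.5)


class TestTableLoading:
    def test_yaml_round_trip(self):
        doc = """
        version: "v1"
        tables:
          female:
            s0: 0.98
            terms:
              - {name: age, transform: identity, field: age, coefficient: 0.08, mean: 52.0}
        """
        tables = load_coefficient_table(io.StringIO(doc))
        assert tables["female"].s0 == 0.98
        assert tables["female"].lp_mean == pytest.approx(0.08 * 52.0)

    def test_duplicate_term_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            _table(
                [
                    RiskTerm("age", "identity", 0.1, 50.0, field="age"),
                    RiskTerm("age", "identity", 0.2, 50.0, field="age"),
                ]
            )

    def test_shipped_synthetic_table_scores_a_cohort(self):
        from pm25ascvd import generate_cohort

        tables = example_coefficient_table()
        assert set(tables) == {"female", "male"}
        cohort = generate_cohort(500, seed=3)
        scored = score_cohort(cohort, tables)
        assert scored["risk"].between(0, 1).all()
        assert ((scored["risk"] >= 0.10) == (scored["high_risk"] == 1)).all()

    def test_monotone_in_positive_coefficient_factor(self):
        tables = example_coefficient_table()
        base = pd.DataFrame(
            {
                "age": [55.0], "smoking": ["never"], "waist_circumference": [84.0],
                "sbp": [125.0], "bp_treated": [0], "family_history_ascvd": [0],
                "total_cholesterol": [185.0], "hdl_cholesterol": [51.0],
                "diabetes": [0], "region": ["north"],
            }
        )
        older = base.assign(age=70.0)
        t = tables["male"]
        r0 = ten_year_risk(linear_predictor(base, t), t).risk[0]
        r1 = ten_year_risk(linear_predictor(older, t), t).risk[0]
        assert r1 > r0
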