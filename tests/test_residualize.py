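"""Step-1 trend model: exact recovery, OLS orthogonality, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from bpevent import (
    TrendFitError,
    TrendModel,
    build_group_panel,
    compute_residuals,
    fit_trend,
    predict_counterfactual,
    simulate_cohort,
)


def baseline_rows(records):
    """records: (patient, event_month, calendar, age, sbp)."""
    df = pd.DataFrame(
        records, columns=["patient_id", "event_month", "calendar_month_index", "age_years", "sbp_mmhg"]
    )
    df["n_readings"] = 1
    df["source"] = "office"
    df["group"] = "htn_only"
    df["took_up"] = False
    return df


def test_constant_outcome_gives_intercept_only():
    rows = baseline_rows([("p1", e, e + 20, 60, 130.0) for e in range(-12, -1)])
    model = fit_trend(rows)
    assert model.intercept == pytest.approx(130.0, abs=1e-10)
    assert model.calendar_slope == pytest.approx(0.0, abs=1e-12)
    assert model.age_coefficients == {60: 0.0}


def test_noiseless_slope_recovered_to_machine_precision():
    rows = baseline_rows(
        [("p1", e, e + 20, 60, 100.0 + 0.5 * (e + 20)) for e in range(-12, -1)]
    )
    model = fit_trend(rows)
    assert model.calendar_slope == pytest.approx(0.5, abs=1e-12)


def test_two_age_groups_offset_recovered_exactly():
    records = []
    for e in range(-12, -1):
        records.append(("young", e, e + 20, 55, 120.0))
        records.append(("old", e, e + 20, 70, 124.0))
    model = fit_trend(baseline_rows(records))
    diff = model.age_coefficients[70] - model.age_coefficients[55]
    assert diff == pytest.approx(4.0, abs=1e-10)


def test_reference_age_is_modal_with_younger_tie_break():
    records = [("a", -5, 15, 50, 120.0), ("b", -5, 15, 64, 120.0), ("c", -6, 14, 64, 121.0),
               ("d", -6, 14, 50, 119.0), ("e", -7, 13, 70, 125.0)]
    model = fit_trend(baseline_rows(records))
    assert model.reference_age == 50
    assert model.age_coefficients[50] == 0.0


def test_predict_hand_arithmetic_and_nearest_age_fallback():
    model = TrendModel(
        intercept=130.0, calendar_slope=0.5,
        age_coefficients={60: 0.0, 65: 2.0}, reference_age=60,
    )
    assert model.predict(10, 65) == pytest.approx(137.0)
    # at the reference age, calendar month 0 -> intercept
    assert model.predict(0, 60) == pytest.approx(130.0)
    # above any fitted age -> maximum fitted age's coefficient
    assert model.predict(10, 80) == pytest.approx(137.0)
    # below any fitted age -> minimum fitted age's coefficient
    assert model.predict(10, 40) == pytest.approx(135.0)
    # equidistant tie (62.5 between 60 and 65) -> younger age wins
    assert model.predict(0, 62.5) == pytest.approx(130.0)


def test_single_calendar_month_is_rank_deficient():
    rows = baseline_rows([(f"p{i}", -5, 7, 60, 130.0 + i) for i in range(4)])
    with pytest.raises(TrendFitError, match="calendar"):
        fit_trend(rows)


def test_empty_fit_window_rejected():
    rows = baseline_rows([("p1", -5, 15, 60, 130.0)])
    with pytest.raises(TrendFitError, match="no rows"):
        fit_trend(rows, fit_window=(-12, -10))
    with pytest.raises(TrendFitError, match="empty"):
        fit_trend(rows, fit_window=(-2, -12))


def test_ols_matches_statsmodels_oracle(small_cohort):
    """Coefficients agree with an independently constructed OLS fit to 1e-8."""
    sm = pytest.importorskip("statsmodels.api")
    cfg, obs, pats, _ = small_cohort
    panel = build_group_panel(obs, pats, "htn_only")
    model = fit_trend(panel)

    lo, hi = model.fit_window
    rows = panel.data[(panel.data["event_month"] >= lo) & (panel.data["event_month"] <= hi)]
    dummies = pd.get_dummies(rows["age_years"].astype(int), prefix="age", dtype=float)
    dummies = dummies.drop(columns=f"age_{model.reference_age}")
    X = sm.add_constant(
        pd.concat([rows["calendar_month_index"].astype(float), dummies], axis=1)
    )
    fit = sm.OLS(rows["sbp_mmhg"].to_numpy(), X.to_numpy()).fit()
    assert model.intercept == pytest.approx(fit.params[0], abs=1e-8)
    assert model.calendar_slope == pytest.approx(fit.params[1], abs=1e-8)
    ages = [int(c.split("_")[1]) for c in dummies.columns]
    for age, coef in zip(ages, fit.params[2:]):
        assert model.age_coefficients[age] == pytest.approx(coef, abs=1e-8)


def test_fit_window_residuals_orthogonal_to_design(small_cohort):
    """OLS residuals: zero mean and zero calendar-trend correlation to 1e-8."""
    cfg, obs, pats, _ = small_cohort
    panel = build_group_panel(obs, pats, "htn_only")
    model = fit_trend(panel)
    panel = compute_residuals(model, panel)
    lo, hi = model.fit_window
    rows = panel.data[(panel.data["event_month"] >= lo) & (panel.data["event_month"] <= hi)]
    assert abs(rows["residual"].mean()) < 1e-8
    assert abs(np.corrcoef(rows["residual"], rows["calendar_month_index"])[0, 1]) < 1e-8


def test_residual_definition_observed_minus_predicted():
    model = TrendModel(intercept=137.0, calendar_slope=0.0,
                       age_coefficients={60: 0.0}, reference_age=60)
    rows = baseline_rows([("p1", -5, 15, 60, 120.0)])
    assert (rows["sbp_mmhg"] - predict_counterfactual(model, rows)).iloc[0] == pytest.approx(-17.0)


def test_kv_serialization_round_trip(tmp_path, small_cohort):
    cfg, obs, pats, _ = small_cohort
    model = fit_trend(build_group_panel(obs, pats, "htn_only"))
    path = tmp_path / "trend.kv"
    model.to_kv(path)
    loaded = TrendModel.from_kv(path)
    assert loaded.intercept == model.intercept
    assert loaded.calendar_slope == model.calendar_slope
    assert loaded.age_coefficients == model.age_coefficients
    assert loaded.fit_window == model.fit_window
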