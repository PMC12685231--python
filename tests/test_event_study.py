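"""Within estimator and clustered variance: oracles, invariances, baselines."""

import numpy as np
import pandas as pd
import pytest

from bpevent import (
    EstimationError,
    SimConfig,
    baseline_level,
    build_group_panel,
    estimate_pre_post,
    simulate_cohort,
)

from conftest import make_panel

MICRO_PANEL = [
    ("A", -2, 2.0), ("A", -1, 0.0), ("A", 8, -8.0),
    ("B", -3, 1.0), ("B", 7, -5.0), ("B", 9, -7.0),
]


def dummy_ols_oracle(panel):
    """Independent oracle: explicit per-patient dummy OLS with clustered SEs."""
    sm = pytest.importorskip("statsmodels.api")
    rows = panel.analysis_rows()
    y = rows["residual"].to_numpy(dtype=float)
    x = rows["in_post"].to_numpy(dtype=float)
    d = pd.get_dummies(rows["patient_id"], dtype=float)
    X = np.column_stack([x, d.to_numpy()])
    groups = pd.factorize(rows["patient_id"])[0]
    fit = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
    return fit.params[0], fit.bse[0]


def test_worked_micro_panel_effect_is_minus_eight():
    panel = make_panel(MICRO_PANEL)
    est = estimate_pre_post(panel)
    assert est.itt_effect == pytest.approx(-8.0, abs=1e-12)
    coef, _ = dummy_ols_oracle(panel)
    assert coef == pytest.approx(-8.0, abs=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_within_estimator_matches_dummy_ols_oracle(seed):
    """Point estimate and clustered SE equal the dummy-variable regression's."""
    r = np.random.default_rng(seed)
    n_pat = int(r.integers(3, 50))
    rows = []
    for i in range(n_pat):
        pre_months = r.choice(np.arange(-12, 0), size=r.integers(1, 5), replace=False)
        post_months = r.choice(np.arange(7, 13), size=r.integers(1, 4), replace=False)
        for e in np.concatenate([pre_months, post_months]):
            rows.append((f"p{i}", int(e), float(r.normal(0, 5))))
    panel = make_panel(rows)
    est = estimate_pre_post(panel)
    coef, se = dummy_ols_oracle(panel)
    assert est.itt_effect == pytest.approx(coef, abs=1e-10)
    assert est.cluster_se == pytest.approx(se, abs=1e-10)


def test_shift_equivariance():
    """Adding c to all post-window residuals shifts the effect by exactly c."""
    panel = make_panel(MICRO_PANEL)
    shifted = make_panel(
        [(p, e, v + (3.7 if e >= 7 else 0.0)) for p, e, v in MICRO_PANEL]
    )
    base = estimate_pre_post(panel).itt_effect
    assert estimate_pre_post(shifted).itt_effect == pytest.approx(base + 3.7, abs=1e-10)


def test_point_estimate_invariant_to_row_duplication():
    panel = make_panel(MICRO_PANEL)
    dup_data = pd.concat([panel.data] * 3, ignore_index=True)
    from bpevent import EventPanel

    dup = EventPanel(data=dup_data, pre_window=panel.pre_window, post_window=panel.post_window)
    assert estimate_pre_post(dup).itt_effect == pytest.approx(
        estimate_pre_post(panel).itt_effect, abs=1e-10
    )


def test_all_zero_residuals_give_zero_effect_and_se():
    panel = make_panel([("A", -2, 0.0), ("A", 8, 0.0), ("B", -1, 0.0), ("B", 9, 0.0)])
    est = estimate_pre_post(panel)
    assert est.itt_effect == 0.0
    assert est.cluster_se == 0.0


def test_single_patient_rejected():
    panel = make_panel([("A", -2, 1.0), ("A", 8, -3.0)])
    with pytest.raises(EstimationError, match="at least 2 patients"):
        estimate_pre_post(panel)


def test_filter_contract_violation_detected():
    """A patient present in only one window (filter bypassed) raises."""
    panel = make_panel(MICRO_PANEL)
    broken = panel.data[~((panel.data["patient_id"] == "B") & panel.data["in_post"])]
    from bpevent import EventPanel

    bad = EventPanel(data=broken, pre_window=panel.pre_window, post_window=panel.post_window)
    with pytest.raises(EstimationError, match="both windows"):
        estimate_pre_post(bad)


def test_clustered_se_detects_shared_patient_shocks():
    """With strong patient-level shocks, clustered SE exceeds the iid-OLS SE."""
    sm = pytest.importorskip("statsmodels.api")
    r = np.random.default_rng(42)
    exceed = 0
    reps = 40
    for _ in range(reps):
        rows = []
        for i in range(60):
            shock_pre, shock_post = r.normal(0, 8, 2)  # per-window patient shocks
            for e in (-6, -4, -2):
                rows.append((f"p{i}", e, float(shock_pre + r.normal(0, 1))))
            for e in (8, 10):
                rows.append((f"p{i}", e, float(shock_post + r.normal(0, 1))))
        panel = make_panel(rows)
        est = estimate_pre_post(panel)
        d = pd.get_dummies(panel.data["patient_id"], dtype=float)
        X = np.column_stack([panel.data["in_post"].to_numpy(float), d.to_numpy()])
        naive = sm.OLS(panel.data["residual"].to_numpy(), X).fit().bse[0]
        exceed += est.cluster_se > naive
    assert exceed / reps >= 0.95


def test_baseline_level_examples():
    panel = make_panel([("A", -1, 138.4), ("A", 8, 120.0), ("B", -2, 140.0), ("B", 9, 130.0)])
    mean, sd, n = baseline_level(panel)
    assert (mean, n) == (pytest.approx(138.4), 1)
    assert np.isnan(sd)

    two = make_panel([("A", -1, 130.0), ("A", 8, 0.0), ("B", -1, 150.0), ("B", 9, 0.0)])
    mean, sd, n = baseline_level(two)
    assert mean == pytest.approx(140.0)
    assert sd == pytest.approx(np.sqrt(200.0))

    none = make_panel([("A", -2, 130.0), ("A", 8, 0.0), ("B", -3, 150.0), ("B", 9, 0.0)])
    with pytest.warns(UserWarning, match="baseline"):
        mean, sd, n = baseline_level(none)
    assert np.isnan(mean) and n == 0


def test_synthetic_baseline_matches_configured_group_mean():
    """Default generator yields month −1 SBP near the configured 138.4 mm Hg."""
    cfg = SimConfig().single_group("htn_only", seed=13)
    obs, pats, _ = simulate_cohort(cfg)
    panel = build_group_panel(obs, pats, "htn_only")
    mean, sd, n = baseline_level(panel)
    assert n > 300
    assert abs(mean - 138.4) < 2 * sd / np.sqrt(n)
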