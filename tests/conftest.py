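import numpy as np
import pandas as pd
import pytest

from bpevent import EventPanel, SimConfig, apply_analysis_filter


def make_panel(rows, pre=(-12, -1), post=(7, 12), group="htn_only") -> EventPanel:
    """Build a filtered analysis panel from (patient_id, event_month, residual) triples.

    The residual column doubles as the sbp column so both Step-2 inputs exist;
    calendar time is event month shifted by a constant referral month.
    """
    df = pd.DataFrame(rows, columns=["patient_id", "event_month", "residual"])
    df["calendar_month_index"] = df["event_month"] + 10
    df["age_years"] = 60
    df["sbp_mmhg"] = df["residual"].astype(float)
    df["n_readings"] = 1
    df["source"] = "office"
    df["group"] = group
    df["took_up"] = True
    panel = apply_analysis_filter(df, pre, post)
    panel.data["residual"] = panel.data["residual"].astype(float)
    return panel


@pytest.fixture(scope="session")
def small_cohort():
    """A compact single-group cohort reused across read-only tests."""
    cfg = SimConfig().single_group("htn_only", n_patients_per_group=(150,), seed=7)
    from bpevent import simulate_cohort

    obs, pats, truth = simulate_cohort(cfg)
    return cfg, obs, pats, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
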