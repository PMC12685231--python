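"""Analysis-panel construction: event-time alignment, patient-month aggregation, inclusion filter.

The analysis panel is a long-format :class:`pandas.DataFrame` with one row per
patient per event month (months relative to the referral event).  Patients are
retained only if they contribute at least one patient-month in the pre-referral
window *and* one in the post-referral window; everything in between (the
program ramp-in months) is kept but flagged ``in_analysis=False`` so reports
can show it without it entering estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Condition groups, in the column order used throughout (hypertension only;
#: hypertension plus one of {type-2 diabetes, ischemic heart disease};
#: hypertension plus both).
GROUPS = ("htn_only", "htn_plus_one", "htn_plus_both")

GROUP_LABELS = {
    "htn_only": "Hypertension only",
    "htn_plus_one": "Hypertension + diabetes or IHD",
    "htn_plus_both": "Hypertension + diabetes and IHD",
}

OBSERVATION_COLUMNS = ["patient_id", "calendar_month_index", "sbp_mmhg", "source"]
PATIENT_COLUMNS = ["patient_id", "referral_month_index", "age_at_referral", "group", "took_up"]

#: Default estimation windows (inclusive event-month intervals).
PRE_WINDOW = (-12, -1)
POST_WINDOW = (7, 12)
TREND_WINDOW = (-12, -2)


class CohortError(ValueError):
    """Raised for contract violations while building the analysis panel."""


@dataclass(frozen=True)
class FilterStats:
    """Bookkeeping from :func:`apply_analysis_filter`."""

    n_input_rows: int
    n_kept_rows: int
    n_dropped_rows: int
    n_input_patients: int
    n_retained_patients: int
    n_dropped_patients: int


@dataclass
class EventPanel:
    """A filtered analysis panel plus its window metadata.

    ``data`` columns: patient_id, event_month, calendar_month_index, age_years,
    sbp_mmhg (patient-month mean), n_readings, source, group, took_up,
    in_pre, in_post, in_analysis, and (after residualization) residual.
    """

    data: pd.DataFrame
    pre_window: tuple[int, int] = PRE_WINDOW
    post_window: tuple[int, int] = POST_WINDOW
    stats: FilterStats | None = None
    trend_window: tuple[int, int] | None = None

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    def analysis_rows(self) -> pd.DataFrame:
        return self.data[self.data["in_analysis"]]


def align_event_time(observations: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Join observations to the patient table and express time relative to referral.

    ``event_month = calendar_month_index - referral_month_index``; age in whole
    years advances on calendar-year boundaries of elapsed months, i.e.
    ``age_years = age_at_referral + floor(event_month / 12)``.

    Raises :class:`CohortError` if any observation refers to an unknown patient.
    """
    known = set(patients["patient_id"])
    orphans = sorted(set(observations["patient_id"]) - known)
    if orphans:
        shown = ", ".join(map(str, orphans[:20]))
        more = "" if len(orphans) <= 20 else f" (+{len(orphans) - 20} more)"
        raise CohortError(f"observations reference unknown patient ids: {shown}{more}")

    rows = observations.merge(
        patients[PATIENT_COLUMNS], on="patient_id", how="left", validate="many_to_one"
    )
    rows["event_month"] = rows["calendar_month_index"] - rows["referral_month_index"]
    rows["age_years"] = rows["age_at_referral"] + rows["event_month"].floordiv(12)
    return rows.drop(columns=["referral_month_index", "age_at_referral"])


def aggregate_patient_month(rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse readings to one row per (patient, event month).

    SBP is the unweighted arithmetic mean of that month's readings; the number
    of pooled readings is retained in ``n_readings`` for optional weighting.
    A month mixing office and device readings gets source ``"mixed"``.
    """
    if rows.empty:
        out = rows.copy()
        out["n_readings"] = pd.Series(dtype=int)
        return out
    work = rows.copy()
    # factorize source so min/max stay on the cython fast path
    src_codes, src_levels = pd.factorize(work["source"])
    work["_src"] = src_codes
    agg = (
        work.groupby(["patient_id", "event_month"], as_index=False, sort=True)
        .agg(
            calendar_month_index=("calendar_month_index", "first"),
            age_years=("age_years", "first"),
            sbp_mmhg=("sbp_mmhg", "mean"),
            n_readings=("sbp_mmhg", "size"),
            _src_min=("_src", "min"),
            _src_max=("_src", "max"),
            group=("group", "first"),
            took_up=("took_up", "first"),
        )
    )
    agg["source"] = np.where(
        agg["_src_min"] == agg["_src_max"],
        np.asarray(src_levels)[agg["_src_min"]],
        "mixed",
    )
    return agg.drop(columns=["_src_min", "_src_max"])


def _check_window(name: str, window: tuple[int, int]) -> tuple[int, int]:
    lo, hi = int(window[0]), int(window[1])
    if lo > hi:
        raise CohortError(f"{name} window {window} is empty (lower bound exceeds upper bound)")
    return lo, hi


def apply_analysis_filter(
    rows: pd.DataFrame,
    pre_window: tuple[int, int] = PRE_WINDOW,
    post_window: tuple[int, int] = POST_WINDOW,
) -> EventPanel:
    """Apply the pre+post inclusion rule and trim to the analysis horizon.

    Keeps rows with ``event_month`` between the start of the pre window and the
    end of the post window; rows strictly between the two windows (the ramp-in
    period) are retained but flagged ``in_analysis=False``.  Patients lacking
    at least one patient-month in each window are dropped entirely.
    """
    pre_lo, pre_hi = _check_window("pre", pre_window)
    post_lo, post_hi = _check_window("post", post_window)
    if pre_hi >= post_lo:
        raise CohortError(
            f"pre window {pre_window} and post window {post_window} overlap or are out of order"
        )

    e = rows["event_month"]
    in_horizon = (e >= pre_lo) & (e <= post_hi)
    in_pre = (e >= pre_lo) & (e <= pre_hi)
    in_post = (e >= post_lo) & (e <= post_hi)

    horizon = rows[in_horizon].copy()
    horizon["in_pre"] = in_pre[in_horizon].to_numpy()
    horizon["in_post"] = in_post[in_horizon].to_numpy()
    horizon["in_analysis"] = horizon["in_pre"] | horizon["in_post"]

    has_pre = horizon.groupby("patient_id")["in_pre"].any()
    has_post = horizon.groupby("patient_id")["in_post"].any()
    retained_ids = has_pre.index[(has_pre & has_post)]
    kept = horizon[horizon["patient_id"].isin(retained_ids)].reset_index(drop=True)

    n_input_patients = rows["patient_id"].nunique()
    stats = FilterStats(
        n_input_rows=len(rows),
        n_kept_rows=len(kept),
        n_dropped_rows=len(rows) - len(kept),
        n_input_patients=n_input_patients,
        n_retained_patients=len(retained_ids),
        n_dropped_patients=n_input_patients - len(retained_ids),
    )
    return EventPanel(data=kept, pre_window=(pre_lo, pre_hi), post_window=(post_lo, post_hi), stats=stats)
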