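"""End-to-end study driver: cohort -> residualize -> estimate -> report."""

from __future__ import annotations

import logging

import pandas as pd

from .cohort import (
    POST_WINDOW,
    PRE_WINDOW,
    TREND_WINDOW,
    EventPanel,
    aggregate_patient_month,
    align_event_time,
    apply_analysis_filter,
)
from .event_study import EventStudyEstimate, estimate_pre_post
from .report import GroupResult, StudyReport, build_report
from .residualize import TrendModel, compute_residuals, fit_trend
from .takeup import contrast_groups, contrast_itt_pooled, estimate_takeup, scale_to_tot

log = logging.getLogger("bpevent")


def build_group_panel(
    observations: pd.DataFrame,
    patients: pd.DataFrame,
    group: str,
    pre_window: tuple[int, int] = PRE_WINDOW,
    post_window: tuple[int, int] = POST_WINDOW,
    source: str = "all",
) -> EventPanel:
    """Aligned, aggregated, filtered analysis panel for one condition group.

    ``source`` is ``"all"`` (pool office and device readings, the default) or
    ``"office"`` (office readings only, for sensitivity analysis).
    """
    pats = patients[patients["group"] == group]
    obs = observations[observations["patient_id"].isin(set(pats["patient_id"]))]
    rows = align_event_time(obs, pats)
    if source == "office":
        rows = rows[rows["source"] == "office"]
    elif source != "all":
        raise ValueError(f"unknown source filter {source!r}; expected 'all' or 'office'")
    rows = aggregate_patient_month(rows)
    panel = apply_analysis_filter(rows, pre_window, post_window)
    s = panel.stats
    log.info(
        "group %s: %d/%d patients retained (%d rows kept, %d dropped)",
        group, s.n_retained_patients, s.n_input_patients, s.n_kept_rows, s.n_dropped_rows,
    )
    return panel


def analyze_group(
    observations: pd.DataFrame,
    patients: pd.DataFrame,
    group: str,
    pre_window: tuple[int, int] = PRE_WINDOW,
    post_window: tuple[int, int] = POST_WINDOW,
    trend_window: tuple[int, int] = TREND_WINDOW,
    source: str = "all",
    trend_model: TrendModel | None = None,
    weight_by_readings: bool = False,
) -> tuple[EventStudyEstimate, TrendModel, EventPanel]:
    """Run both steps for one group; a pre-fitted trend model may be supplied."""
    panel = build_group_panel(observations, patients, group, pre_window, post_window, source)
    model = trend_model if trend_model is not None else fit_trend(panel, trend_window)
    panel = compute_residuals(model, panel)
    est = estimate_pre_post(panel, weight_by_readings=weight_by_readings, group=group)
    return est, model, panel


def run_study(
    observations: pd.DataFrame,
    patients: pd.DataFrame,
    groups: tuple[str, ...] | None = None,
    pre_window: tuple[int, int] = PRE_WINDOW,
    post_window: tuple[int, int] = POST_WINDOW,
    trend_window: tuple[int, int] = TREND_WINDOW,
    source: str = "all",
    pooled_trend: bool = False,
    weight_by_readings: bool = False,
    config_echo: dict | None = None,
) -> tuple[StudyReport, dict[str, TrendModel]]:
    """Full analysis across condition groups, with pairwise adjacent contrasts.

    By default the Step-1 trend is fit separately within each group (each
    column of the published table is a standalone analysis); with
    ``pooled_trend=True`` a single trend model is fit on all groups' baseline
    rows and shared.
    """
    if groups is None:
        groups = tuple(g for g in patients["group"].unique())
    pooled_model: TrendModel | None = None
    if pooled_trend:
        pooled_rows = pd.concat(
            [build_group_panel(observations, patients, g, pre_window, post_window, source).data
             for g in groups],
            ignore_index=True,
        )
        pooled_model = fit_trend(pooled_rows, trend_window)

    results: dict[str, GroupResult] = {}
    models: dict[str, TrendModel] = {}
    panels: dict[str, EventPanel] = {}
    for g in groups:
        est, model, panel = analyze_group(
            observations, patients, g, pre_window, post_window, trend_window,
            source, trend_model=pooled_model, weight_by_readings=weight_by_readings,
        )
        retained = patients[patients["patient_id"].isin(set(panel.data["patient_id"]))]
        tk = estimate_takeup(retained, g)
        results[g] = GroupResult(estimate=est, takeup=tk, scaled=scale_to_tot(est, tk),
                                 filter_stats=panel.stats)
        models[g] = model
        panels[g] = panel

    contrasts = []
    for ga, gb in zip(groups, groups[1:]):
        contrasts.append(contrast_itt_pooled(panels[ga], panels[gb]))
        contrasts.append(contrast_groups(results[ga].takeup, results[gb].takeup, kind="takeup"))

    echo = {
        "pre_window": pre_window, "post_window": post_window,
        "trend_window": trend_window, "source": source,
        "pooled_trend": pooled_trend, "weight_by_readings": weight_by_readings,
    }
    echo.update(config_echo or {})
    return build_report(results, contrasts, echo), models
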