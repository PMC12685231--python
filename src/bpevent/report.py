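"""Tabular study reports: per-group ITT / take-up / TOT plus contrasts.

Internal values stay at full precision; rounding (round-half-even, matching
the published tables' precision) is applied only when rendering.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from io import StringIO
from pathlib import Path

import pandas as pd

from .cohort import GROUP_LABELS, FilterStats
from .event_study import EventStudyEstimate
from .takeup import GroupContrast, ScaledEffect, TakeUpEstimate

_FORMATS = ("text", "csv")


class ReportError(ValueError):
    pass


def round_half_even(value: float, decimals: int) -> float:
    """Banker's rounding on the decimal representation of ``value``."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class GroupResult:
    """All estimates for one condition group."""

    estimate: EventStudyEstimate
    takeup: TakeUpEstimate
    scaled: ScaledEffect
    filter_stats: FilterStats | None = None


@dataclass
class StudyReport:
    """Assembled per-group results, pairwise contrasts and run configuration."""

    groups: list[str]
    results: dict[str, GroupResult]
    contrasts: list[GroupContrast]
    config_echo: dict

    def to_frame(self) -> pd.DataFrame:
        """Long tidy table (rounded display values) for CSV rendering."""
        rows = []
        for g in self.groups:
            r = self.results[g]
            rows += [
                ("part_a", "itt_effect", g, round_half_even(r.estimate.itt_effect, 3)),
                ("part_a", "cluster_se", g, round_half_even(r.estimate.cluster_se, 2)),
                ("part_a", "baseline_mean", g, round_half_even(r.estimate.baseline_mean, 1)),
                ("part_a", "baseline_sd", g, round_half_even(r.estimate.baseline_sd, 1)),
                ("part_b", "takeup_rate", g, round_half_even(r.takeup.rate, 4)),
                ("part_b", "takeup_se", g, round_half_even(r.takeup.se, 4)),
                ("part_c", "tot_effect", g, round_half_even(r.scaled.tot_effect, 2)),
                ("counts", "n_patients", g, r.estimate.n_patients),
            ]
        for c in self.contrasts:
            pair = f"{c.group_a}_vs_{c.group_b}"
            nd = 4 if c.kind == "takeup" else 2
            rows += [
                ("contrast", f"{c.kind}_difference", pair, round_half_even(c.difference, nd)),
                ("contrast", f"{c.kind}_se", pair, round_half_even(c.se, nd)),
            ]
        return pd.DataFrame(rows, columns=["section", "statistic", "group", "value"])

    def to_json(self, path: str | Path) -> None:
        record = {
            "groups": self.groups,
            "results": {g: asdict(r) for g, r in self.results.items()},
            "contrasts": [asdict(c) for c in self.contrasts],
            "config_echo": self.config_echo,
        }
        Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")


def build_report(
    results: dict[str, GroupResult],
    contrasts: list[GroupContrast] | None = None,
    config_echo: dict | None = None,
) -> StudyReport:
    """Assemble and sanity-check a study report.

    All groups must share identical pre/post windows, and each rendered
    Part C cell must equal the Part A cell divided by the Part B cell.
    """
    if not results:
        raise ReportError("no group results to report")
    groups = list(results)
    windows = {(r.estimate.pre_window, r.estimate.post_window) for r in results.values()}
    if len(windows) > 1:
        raise ReportError(f"estimation windows differ across groups: {sorted(windows)}")
    for g, r in results.items():
        implied = r.estimate.itt_effect / r.takeup.rate
        if round_half_even(implied, 2) != round_half_even(r.scaled.tot_effect, 2):
            raise ReportError(f"Part C inconsistency for group {g}: "
                              f"{r.scaled.tot_effect} != {implied}")
    return StudyReport(groups=groups, results=results,
                       contrasts=list(contrasts or []), config_echo=dict(config_echo or {}))


def _fmt(value: float, decimals: int) -> str:
    return f"{round_half_even(value, decimals):.{decimals}f}"


def render(report: StudyReport, format: str = "text") -> str:
    """Render a report as a fixed-width text table or a tidy CSV.

    Output is deterministic: identical reports render to identical bytes.
    """
    if format == "csv":
        buf = StringIO()
        report.to_frame().to_csv(buf, index=False)
        return buf.getvalue()
    if format != "text":
        raise ReportError(f"unknown format {format!r}; supported: {', '.join(_FORMATS)}")

    groups = report.groups
    label_w = 38
    col_w = max(26, *(len(GROUP_LABELS.get(g, g)) + 2 for g in groups))

    def line(label: str, cells: list[str]) -> str:
        return label.ljust(label_w) + "".join(c.rjust(col_w) for c in cells)

    out = [
        "Program impact on systolic blood pressure (mm Hg)",
        "=" * (label_w + col_w * len(groups)),
        line("", [GROUP_LABELS.get(g, g) for g in groups]),
        line("Part A: ITT effect (SE)",
             [f"{_fmt(report.results[g].estimate.itt_effect, 3)} "
              f"({_fmt(report.results[g].estimate.cluster_se, 2)})" for g in groups]),
        line("        Baseline SBP at month -1 (SD)",
             [f"{_fmt(report.results[g].estimate.baseline_mean, 1)} "
              f"({_fmt(report.results[g].estimate.baseline_sd, 1)})" for g in groups]),
        line("Part B: initial take-up rate (SE)",
             [f"{_fmt(report.results[g].takeup.rate, 4)} "
              f"({_fmt(report.results[g].takeup.se, 4)})" for g in groups]),
        line("Part C: effect scaled by take-up",
             [_fmt(report.results[g].scaled.tot_effect, 2) for g in groups]),
        line("Patients (retained)",
             [str(report.results[g].estimate.n_patients) for g in groups]),
    ]
    if report.contrasts:
        out.append("-" * (label_w + col_w * len(groups)))
        out.append("Between-group contrasts (B - A):")
        for c in report.contrasts:
            nd = 4 if c.kind == "takeup" else 2
            out.append(
                f"  {c.kind:7s} {c.group_a} vs {c.group_b}: "
                f"{_fmt(c.difference, nd)} (SE {_fmt(c.se, nd)}; P={_fmt(c.p_value, 3)})"
            )
    if report.config_echo:
        out.append("-" * (label_w + col_w * len(groups)))
        for key in sorted(report.config_echo):
            out.append(f"  {key} = {report.config_echo[key]}")
    return "\n".join(out) + "\n"
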