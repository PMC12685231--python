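"""Step 1: counterfactual trend model fit on the baseline window.

The counterfactual for each patient-month is an ordinary least squares fit of
observed SBP on an intercept, a linear calendar-month trend, and fixed effects
for integer year of age, estimated on the baseline window (event months -12 to
-2 by default; the month immediately before referral is excluded as
potentially transitory).  Residuals — observed minus predicted SBP — carry the
program signal into Step 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EventPanel, TREND_WINDOW


class TrendFitError(ValueError):
    """Raised when the baseline design cannot identify the trend model."""


@dataclass
class TrendModel:
    """Fitted counterfactual: intercept + calendar slope + age-year offsets.

    ``age_coefficients`` maps integer year-of-age to an SBP offset in mm Hg;
    the reference age has coefficient exactly 0.  Ages never seen in the fit
    are predicted with the nearest fitted age's coefficient (ties broken to
    the younger age): fixed effects carry no slope, so the nearest level is
    the minimal-assumption fallback.
    """

    intercept: float
    calendar_slope: float
    age_coefficients: dict[int, float]
    reference_age: int
    fit_window: tuple[int, int] = TREND_WINDOW
    n_rows_fit: int = 0
    residual_sd: float = float("nan")

    def __post_init__(self) -> None:
        self._ages = np.array(sorted(self.age_coefficients), dtype=float)
        self._coefs = np.array([self.age_coefficients[int(a)] for a in self._ages])
        if abs(self.age_coefficients[self.reference_age]) > 1e-12:
            raise TrendFitError("reference age coefficient must be exactly 0")

    def _nearest_age_coef(self, ages: np.ndarray) -> np.ndarray:
        # index of nearest fitted age; on a tie, the younger (left) age wins
        pos = np.searchsorted(self._ages, ages)
        pos = np.clip(pos, 1, len(self._ages) - 1)
        left, right = self._ages[pos - 1], self._ages[pos]
        use_left = (ages - left) <= (right - ages)
        idx = np.where(use_left, pos - 1, pos)
        idx = np.where(ages <= self._ages[0], 0, idx)
        idx = np.where(ages >= self._ages[-1], len(self._ages) - 1, idx)
        return self._coefs[idx]

    def predict(self, calendar_month_index, age_years) -> np.ndarray:
        """Counterfactual SBP (mm Hg) as if the referral had not occurred."""
        cal = np.asarray(calendar_month_index, dtype=float)
        age = np.asarray(age_years, dtype=float)
        return self.intercept + self.calendar_slope * cal + self._nearest_age_coef(age)

    # -- flat key-value audit file ------------------------------------------------

    def to_kv(self, path: str | Path) -> None:
        lines = [
            f"intercept = {self.intercept!r}",
            f"calendar_slope = {self.calendar_slope!r}",
            f"reference_age = {self.reference_age}",
            f"fit_window = {self.fit_window[0]} {self.fit_window[1]}",
            f"n_rows_fit = {self.n_rows_fit}",
            f"residual_sd = {self.residual_sd!r}",
        ]
        for age in sorted(self.age_coefficients):
            lines.append(f"age_coef[{age}] = {self.age_coefficients[age]!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_kv(cls, path: str | Path) -> "TrendModel":
        fields: dict[str, str] = {}
        ages: dict[int, float] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("age_coef["):
                ages[int(key[len("age_coef["):-1])] = float(value)
            else:
                fields[key] = value
        lo, hi = fields["fit_window"].split()
        return cls(
            intercept=float(fields["intercept"]),
            calendar_slope=float(fields["calendar_slope"]),
            age_coefficients=ages,
            reference_age=int(fields["reference_age"]),
            fit_window=(int(lo), int(hi)),
            n_rows_fit=int(fields["n_rows_fit"]),
            residual_sd=float(fields["residual_sd"]),
        )


def _reference_age(ages: pd.Series) -> int:
    """Most frequent integer age in the fit rows; ties broken to the younger."""
    counts = ages.value_counts()
    top = counts[counts == counts.max()]
    return int(min(top.index))


def fit_trend(panel: EventPanel | pd.DataFrame, fit_window: tuple[int, int] = TREND_WINDOW) -> TrendModel:
    """OLS of SBP on {1, calendar month, age-year indicators} over the baseline window.

    The fit pools all patients of the analyzed group; rows are patient-month
    means.  Raises :class:`TrendFitError` on an empty window or a design that
    cannot identify the calendar slope (fewer than two distinct calendar
    months).
    """
    df = panel.data if isinstance(panel, EventPanel) else panel
    lo, hi = int(fit_window[0]), int(fit_window[1])
    if lo > hi:
        raise TrendFitError(f"fit window {fit_window} is empty")
    rows = df[(df["event_month"] >= lo) & (df["event_month"] <= hi)]
    if rows.empty:
        raise TrendFitError(f"no rows in fit window [{lo}, {hi}]")

    cal = rows["calendar_month_index"].to_numpy(dtype=float)
    if len(np.unique(cal)) < 2:
        raise TrendFitError(
            "calendar_month_index is collinear with the intercept: "
            "baseline window contains a single calendar month"
        )
    ages = rows["age_years"].astype(int)
    ref_age = _reference_age(ages)
    age_levels = sorted(set(ages) - {ref_age})

    y = rows["sbp_mmhg"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(rows)), cal] + [(ages == a).to_numpy(dtype=float) for a in age_levels]
    )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise TrendFitError(
            "baseline design matrix is rank deficient; an age indicator is "
            "collinear with the intercept or the calendar trend"
        )
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    coefs = {ref_age: 0.0}
    coefs.update({int(a): float(b) for a, b in zip(age_levels, beta[2:])})
    return TrendModel(
        intercept=float(beta[0]),
        calendar_slope=float(beta[1]),
        age_coefficients=coefs,
        reference_age=ref_age,
        fit_window=(lo, hi),
        n_rows_fit=len(rows),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
    )


def predict_counterfactual(model: TrendModel, rows: pd.DataFrame) -> np.ndarray:
    """Vectorized counterfactual prediction for panel rows."""
    return model.predict(rows["calendar_month_index"], rows["age_years"])


def compute_residuals(model: TrendModel, panel: EventPanel) -> EventPanel:
    """Attach ``residual = sbp - predicted counterfactual`` to every panel row."""
    data = panel.data.copy()
    data["residual"] = data["sbp_mmhg"].to_numpy(dtype=float) - predict_counterfactual(model, data)
    return EventPanel(
        data=data,
        pre_window=panel.pre_window,
        post_window=panel.post_window,
        stats=panel.stats,
        trend_window=model.fit_window,
    )
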