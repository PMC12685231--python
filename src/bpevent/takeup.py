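"""Initial take-up rates, ITT→TOT scaling, and between-group contrasts.

Take-up is the proportion of referred patients who completed at least one
electronic BP reading.  Its SE is the sample-variance binomial formula
``sqrt(p(1-p)/(n-1))`` — identical to the heteroskedasticity-robust SE of an
intercept-only regression on the take-up indicator, which is what reproduces
the published values.  The treatment-on-treated effect is the Wald ratio
ITT / take-up; its delta-method SE is offered as supplementary output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import EventPanel
from .event_study import EstimationError, EventStudyEstimate, _within_ols


@dataclass(frozen=True)
class TakeUpEstimate:
    """Share of a group's referred patients with >=1 electronic BP reading."""

    group: str
    rate: float
    se: float
    n: int
    n_takers: int
    definition: str = ">=1 electronic BP reading"


@dataclass(frozen=True)
class ScaledEffect:
    """Treatment-on-treated effect: ITT scaled by the take-up rate.

    ``se`` is the delta-method SE sqrt((se_itt/p)^2 + (itt*se_p/p^2)^2),
    supplementary to the point estimate (published tables print none).
    """

    group: str
    tot_effect: float
    itt_effect: float
    rate: float
    se: float


@dataclass(frozen=True)
class GroupContrast:
    """Difference of ITT effects or take-up rates between two groups (B − A)."""

    kind: str  # "itt" | "takeup"
    group_a: str
    group_b: str
    difference: float
    se: float
    p_value: float
    method: str = ""


def estimate_takeup(patients: pd.DataFrame, group: str) -> TakeUpEstimate:
    """Take-up rate and SE for one condition group of a patient table."""
    sub = patients[patients["group"] == group]
    n = len(sub)
    if n == 0:
        raise EstimationError(f"no patients in group {group!r}")
    k = int(sub["took_up"].sum())
    rate = k / n
    if rate in (0.0, 1.0) or n < 2:
        se = 0.0
    else:
        se = float(np.sqrt(rate * (1.0 - rate) / (n - 1)))
    return TakeUpEstimate(group=group, rate=rate, se=se, n=n, n_takers=k)


def scale_to_tot(itt: EventStudyEstimate, takeup: TakeUpEstimate) -> ScaledEffect:
    """Wald ratio ITT / take-up: the average effect among program participants."""
    if takeup.rate <= 0:
        raise EstimationError(
            f"cannot scale by a zero take-up rate (group {takeup.group!r} has no takers)"
        )
    p = takeup.rate
    tot = itt.itt_effect / p
    se = float(np.sqrt((itt.cluster_se / p) ** 2 + (itt.itt_effect * takeup.se / p**2) ** 2))
    return ScaledEffect(group=takeup.group, tot_effect=tot, itt_effect=itt.itt_effect,
                        rate=p, se=se)


def contrast_groups(
    est_a: EventStudyEstimate | TakeUpEstimate,
    est_b: EventStudyEstimate | TakeUpEstimate,
    kind: str,
) -> GroupContrast:
    """Between-group difference (B − A) from two standalone estimates.

    Take-up contrasts use the independent-proportions SE
    sqrt(se_a^2 + se_b^2); ITT contrasts from bare estimates use the same
    independence approximation (see :func:`contrast_itt_pooled` for the
    regression-based version used in full reports).
    """
    if est_a.group == est_b.group:
        raise EstimationError(f"contrast requires two distinct groups, got {est_a.group!r} twice")
    if kind == "takeup":
        diff = est_b.rate - est_a.rate
    elif kind == "itt":
        diff = est_b.itt_effect - est_a.itt_effect
    else:
        raise ValueError(f"unknown contrast kind {kind!r}; expected 'itt' or 'takeup'")
    se_a = est_a.se if kind == "takeup" else est_a.cluster_se
    se_b = est_b.se if kind == "takeup" else est_b.cluster_se
    se = float(np.sqrt(se_a**2 + se_b**2))
    z = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
    p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return GroupContrast(kind=kind, group_a=est_a.group, group_b=est_b.group,
                         difference=float(diff), se=se, p_value=p, method="independence")


def contrast_itt_pooled(panel_a: EventPanel, panel_b: EventPanel,
                        residual_col: str = "residual") -> GroupContrast:
    """ITT difference (B − A) from a pooled interaction regression.

    Stacks the two groups' residualized panels and fits, with patient fixed
    effects, residual ~ post + post×group_B; the interaction coefficient is
    exactly itt_B − itt_A, and its patient-clustered SE accounts for the
    pooled within variation.
    """
    rows_a = panel_a.analysis_rows().copy()
    rows_b = panel_b.analysis_rows().copy()
    ga = rows_a["group"].iloc[0] if len(rows_a) else "A"
    gb = rows_b["group"].iloc[0] if len(rows_b) else "B"
    if ga == gb:
        raise EstimationError(f"contrast requires two distinct groups, got {ga!r} twice")
    overlap = set(rows_a["patient_id"]) & set(rows_b["patient_id"])
    if overlap:
        raise EstimationError("pooled ITT contrast requires disjoint patient sets")
    rows_a["_is_b"] = 0.0
    rows_b["_is_b"] = 1.0
    rows = pd.concat([rows_a, rows_b], ignore_index=True)
    y = rows[residual_col].to_numpy(dtype=float)
    post = rows["in_post"].to_numpy(dtype=float)
    X = np.column_stack([post, post * rows["_is_b"].to_numpy()])
    beta, cov, G, _ = _within_ols(y, X, rows["patient_id"].to_numpy())
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    t = beta[1] / se if se > 0 else (0.0 if beta[1] == 0 else np.inf)
    p = float(2 * sps.t.sf(abs(t), G - 1)) if np.isfinite(t) else 0.0
    return GroupContrast(kind="itt", group_a=ga, group_b=gb, difference=float(beta[1]),
                         se=se, p_value=p, method="pooled interaction regression")
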