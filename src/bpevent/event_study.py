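"""Step 2: pre/post change in residualized SBP with patient fixed effects.

The intention-to-treat effect is the coefficient on a post-window indicator in
a patient-fixed-effects regression of the Step-1 residuals, estimated by the
within (patient-demeaning) transformation.  Uncertainty uses the Liang–Zeger
cluster-robust sandwich with clusters at the patient level and the
small-sample factor (G/(G−1))·((N−1)/(N−K)), where K counts the post
indicator(s) plus the absorbed patient intercepts; p-values use a t
distribution with G−1 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import EventPanel


class EstimationError(ValueError):
    """Raised when the panel violates the estimator's contract."""


@dataclass(frozen=True)
class EventStudyEstimate:
    """ITT effect of referral on SBP for one condition group."""

    group: str
    itt_effect: float
    cluster_se: float
    p_value: float
    n_patients: int
    n_rows: int
    pre_window: tuple[int, int]
    post_window: tuple[int, int]
    baseline_mean: float = float("nan")
    baseline_sd: float = float("nan")
    baseline_n: int = 0


def _within_ols(
    y: np.ndarray, X: np.ndarray, clusters: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Fixed-effects OLS by cluster demeaning, with clustered sandwich covariance.

    Returns ``(beta, cov, n_clusters, n_rows)``.  Equivalent to OLS with one
    dummy per cluster; the sandwich matches the dummy-variable regression's
    cluster-robust covariance including its small-sample correction.
    """
    codes, uniques = pd.factorize(clusters)
    G = len(uniques)
    if G < 2:
        raise EstimationError("clustered variance requires at least 2 patients (clusters)")
    N, k = X.shape
    w = np.ones(N) if weights is None else np.asarray(weights, dtype=float)
    sw = np.bincount(codes, weights=w)

    def demean(v: np.ndarray) -> np.ndarray:
        means = np.bincount(codes, weights=w * v) / sw
        return v - means[codes]

    Xd = np.column_stack([demean(X[:, j]) for j in range(k)])
    yd = demean(y)
    XtX = (Xd * w[:, None]).T @ Xd
    if np.linalg.matrix_rank(XtX) < k:
        raise EstimationError("within-transformed design is rank deficient")
    beta = np.linalg.solve(XtX, (Xd * w[:, None]).T @ yd)
    u = yd - Xd @ beta

    scores = np.zeros((G, k))
    for j in range(k):
        scores[:, j] = np.bincount(codes, weights=w * Xd[:, j] * u)
    meat = scores.T @ scores
    K = k + G  # regressors + absorbed patient intercepts
    if N <= K:
        correction = G / (G - 1)
    else:
        correction = (G / (G - 1)) * ((N - 1) / (N - K))
    bread = np.linalg.inv(XtX)
    cov = correction * bread @ meat @ bread
    return beta, cov, G, N


def _check_both_windows(rows: pd.DataFrame) -> None:
    has_pre = rows.groupby("patient_id")["in_pre"].any()
    has_post = rows.groupby("patient_id")["in_post"].any()
    bad = sorted(has_pre.index[~(has_pre & has_post)])
    if bad:
        raise EstimationError(
            "panel violates the cohort-filter contract: patients without rows in "
            f"both windows: {', '.join(map(str, bad[:10]))}"
        )


def estimate_pre_post(
    panel: EventPanel,
    residual_col: str = "residual",
    weight_by_readings: bool = False,
    group: str | None = None,
) -> EventStudyEstimate:
    """Within-estimator ITT effect: residual on post-window indicator with patient FE."""
    rows = panel.analysis_rows()
    if residual_col not in rows.columns:
        raise EstimationError(f"panel has no '{residual_col}' column; run Step 1 first")
    if rows.empty:
        raise EstimationError("no analysis rows in panel")
    _check_both_windows(rows)

    y = rows[residual_col].to_numpy(dtype=float)
    X = rows["in_post"].to_numpy(dtype=float)[:, None]
    w = rows["n_readings"].to_numpy(dtype=float) if weight_by_readings else None
    beta, cov, G, N = _within_ols(y, X, rows["patient_id"].to_numpy(), w)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    t = beta[0] / se if se > 0 else (0.0 if beta[0] == 0 else np.inf)
    p = float(2 * sps.t.sf(abs(t), G - 1)) if np.isfinite(t) else 0.0
    if group is None:
        uniq = rows["group"].unique()
        group = uniq[0] if len(uniq) == 1 else "pooled"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # missing month −1 is warned on direct calls only
        base_mean, base_sd, base_n = baseline_level(panel)
    return EventStudyEstimate(
        group=group,
        itt_effect=float(beta[0]),
        cluster_se=se,
        p_value=p,
        n_patients=G,
        n_rows=N,
        pre_window=panel.pre_window,
        post_window=panel.post_window,
        baseline_mean=base_mean,
        baseline_sd=base_sd,
        baseline_n=base_n,
    )


def clustered_variance(panel: EventPanel, residual_col: str = "residual") -> float:
    """Cluster-robust SE of the post-indicator coefficient (patient clusters)."""
    rows = panel.analysis_rows()
    _check_both_windows(rows)
    y = rows[residual_col].to_numpy(dtype=float)
    X = rows["in_post"].to_numpy(dtype=float)[:, None]
    _, cov, _, _ = _within_ols(y, X, rows["patient_id"].to_numpy())
    return float(np.sqrt(max(cov[0, 0], 0.0)))


def baseline_level(panel: EventPanel, event_month: int = -1) -> tuple[float, float, int]:
    """Mean and SD of observed (not residualized) SBP across patients at month −1.

    Returns ``(mean, sd, n_patients)``; a missing-value result with a warning
    when no patient was observed in that month.
    """
    rows = panel.data[panel.data["event_month"] == event_month]
    if rows.empty:
        warnings.warn(
            f"no observations at event month {event_month}; baseline level undefined",
            stacklevel=2,
        )
        return float("nan"), float("nan"), 0
    values = rows["sbp_mmhg"].to_numpy(dtype=float)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")
    return float(values.mean()), sd, len(values)
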