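"""CSV interchange for cohorts: one observations file, one patient file.

Observations: patient_id, calendar_month_index, event_month, sbp_mmhg, source
(event_month is written for human inspection and recomputed on read).
Patients: patient_id, referral_month_index, age_at_referral, group, took_up.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GROUPS, OBSERVATION_COLUMNS, PATIENT_COLUMNS

_SOURCES = {"office", "device"}
_BOOL = {"true": True, "false": False, "1": True, "0": False}


class CohortIOError(ValueError):
    """Malformed cohort file: message names the file, row and column."""


def write_cohort(
    observations: pd.DataFrame,
    patients: pd.DataFrame,
    obs_path: str | Path,
    patients_path: str | Path,
) -> None:
    """Write the cohort CSV pair; observations gain a redundant event_month column."""
    obs = observations[OBSERVATION_COLUMNS].copy()
    referral = patients.set_index("patient_id")["referral_month_index"]
    obs["event_month"] = (
        obs["calendar_month_index"] - obs["patient_id"].map(referral)
    ).astype("Int64")
    obs = obs[["patient_id", "calendar_month_index", "event_month", "sbp_mmhg", "source"]]
    obs.to_csv(obs_path, index=False)
    patients[PATIENT_COLUMNS].to_csv(patients_path, index=False)


def _require_columns(df: pd.DataFrame, required: list[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortIOError(f"{path}: missing required columns: {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, path: str | Path, kind=float) -> pd.Series:
    raw = df[column]
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.notna()
    if bad.any() or raw.isna().any():
        i = int(np.flatnonzero(bad.to_numpy() | raw.isna().to_numpy())[0])
        value = raw.iloc[i]
        # +2: header line plus 1-based indexing
        raise CohortIOError(
            f"{path}: row {i + 2}, column '{column}': non-numeric value {value!r}"
        )
    if kind is int and not np.allclose(converted, np.round(converted)):
        i = int(np.flatnonzero(~np.isclose(converted, np.round(converted)))[0])
        raise CohortIOError(
            f"{path}: row {i + 2}, column '{column}': expected integer, got {raw.iloc[i]!r}"
        )
    return converted.astype(kind)


def read_cohort(
    obs_path: str | Path, patients_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort CSV pair written by :func:`write_cohort`.

    Returns ``(observations, patients)`` with the canonical in-memory schema
    (the redundant event_month column is dropped).  Malformed cells raise
    :class:`CohortIOError` naming the file, row and column.
    """
    obs = pd.read_csv(obs_path, dtype=str, keep_default_na=False).replace("", np.nan)
    pats = pd.read_csv(patients_path, dtype=str, keep_default_na=False).replace("", np.nan)
    _require_columns(obs, OBSERVATION_COLUMNS, obs_path)
    _require_columns(pats, PATIENT_COLUMNS, patients_path)

    observations = pd.DataFrame({
        "patient_id": obs["patient_id"].astype(str) if len(obs) else pd.Series(dtype=str),
        "calendar_month_index": _numeric(obs, "calendar_month_index", obs_path, int),
        "sbp_mmhg": _numeric(obs, "sbp_mmhg", obs_path, float),
        "source": obs["source"].astype(str) if len(obs) else pd.Series(dtype=str),
    })
    bad_source = ~observations["source"].isin(_SOURCES)
    if len(observations) and bad_source.any():
        i = int(np.flatnonzero(bad_source.to_numpy())[0])
        raise CohortIOError(
            f"{obs_path}: row {i + 2}, column 'source': "
            f"expected one of {sorted(_SOURCES)}, got {observations['source'].iloc[i]!r}"
        )

    took_raw = pats["took_up"].astype(str).str.lower() if len(pats) else pd.Series(dtype=str)
    bad_bool = ~took_raw.isin(_BOOL)
    if len(pats) and bad_bool.any():
        i = int(np.flatnonzero(bad_bool.to_numpy())[0])
        raise CohortIOError(
            f"{patients_path}: row {i + 2}, column 'took_up': "
            f"expected true/false, got {pats['took_up'].iloc[i]!r}"
        )
    patients = pd.DataFrame({
        "patient_id": pats["patient_id"].astype(str) if len(pats) else pd.Series(dtype=str),
        "referral_month_index": _numeric(pats, "referral_month_index", patients_path, int),
        "age_at_referral": _numeric(pats, "age_at_referral", patients_path, int),
        "group": pats["group"].astype(str) if len(pats) else pd.Series(dtype=str),
        "took_up": took_raw.map(_BOOL).astype(bool) if len(pats) else pd.Series(dtype=bool),
    })
    bad_group = ~patients["group"].isin(GROUPS)
    if len(patients) and bad_group.any():
        i = int(np.flatnonzero(bad_group.to_numpy())[0])
        raise CohortIOError(
            f"{patients_path}: row {i + 2}, column 'group': "
            f"expected one of {list(GROUPS)}, got {patients['group'].iloc[i]!r}"
        )
    return observations, patients
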