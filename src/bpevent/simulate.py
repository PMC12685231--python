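"""Synthetic EHR-panel generator for referral-program event studies.

Emulates the statistical structure the analysis model assumes: staggered
referrals over a fixed calendar window, patient-level SBP heterogeneity, a
secular linear calendar trend, an age gradient, group-specific take-up of the
monitoring program, and a treatment effect that ramps in over the months after
referral among patients who take it up.  Observation timing is irregular
(missing completely at random), so some patients lack pre- or post-window
data and exercise the cohort filter.

Latent SBP for patient i of group g at calendar month t (event month e):

    y_it = m_g + a_i + s·(t − t0) + b·(age_it − A_g) + U_i · tau_g · r(e) + eps_it

with patient intercept a_i ~ N(0, patient_sd), reading noise
eps_it ~ N(0, noise_sd), take-up indicator U_i ~ Bernoulli(p_g), and ramp
r(e) = min(1, e / ramp_months) for e >= 0, else 0.  Calendar time is centered
at t0 = E[referral month] − 1 and age at the group mean A_g so that the
configured group mean m_g is the expected observed SBP at event month −1,
matching how baselines are reported.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import GROUPS
from .residualize import TrendModel

_PROB_FIELDS = ("takeup_prob", "obs_prob_per_month", "device_label_prob")
_NONNEG_FIELDS = ("patient_sd", "noise_sd", "age_sd", "ramp_months", "extra_readings_rate")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a simulated referral cohort.

    Per-group tuples are aligned with ``groups``.  Defaults reproduce the
    published study conditions: group sizes 1318/745/143, take-up
    0.58/0.50/0.41, treatment-on-treated SBP shifts of −16.8/−13.2/−16.0
    mm Hg ramping in over 6 months, baseline group means 138.4/131.4/128.8
    mm Hg, and referrals staggered over a 22-calendar-month window.
    """

    groups: tuple[str, ...] = GROUPS
    n_patients_per_group: tuple[int, ...] = (1318, 745, 143)
    takeup_prob: tuple[float, ...] = (0.58, 0.50, 0.41)
    tot_effect: tuple[float, ...] = (-16.8, -13.2, -16.0)
    group_mean_sbp: tuple[float, ...] = (138.4, 131.4, 128.8)
    age_mean: tuple[float, ...] = (63.2, 67.1, 69.6)
    age_sd: tuple[float, ...] = (15.2, 12.8, 11.5)
    ramp_months: int = 6
    calendar_slope: float = 0.1
    age_effect_per_year: float = 0.4
    patient_sd: float = 13.0
    noise_sd: float = 17.0
    obs_prob_per_month: float = 0.35
    extra_readings_rate: float = 0.3
    device_label_prob: float = 0.7
    study_window_months: int = 22
    event_horizon_months: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------------------

    def validate(self) -> None:
        k = len(self.groups)
        for name in ("n_patients_per_group", "takeup_prob", "tot_effect",
                     "group_mean_sbp", "age_mean", "age_sd"):
            value = getattr(self, name)
            if len(value) != k:
                raise ValueError(f"{name} must have one entry per group ({k}), got {len(value)}")
        for name in ("takeup_prob", "tot_effect", "group_mean_sbp", "age_mean", "age_sd",
                     "calendar_slope", "age_effect_per_year", "patient_sd", "noise_sd",
                     "obs_prob_per_month", "extra_readings_rate", "device_label_prob"):
            value = getattr(self, name)
            vals = value if isinstance(value, tuple) else (value,)
            if not all(math.isfinite(v) for v in vals):
                raise ValueError(f"{name} must be finite, got {value}")
        for name in _PROB_FIELDS:
            value = getattr(self, name)
            vals = value if isinstance(value, tuple) else (value,)
            if not all(0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name in _NONNEG_FIELDS:
            value = getattr(self, name)
            vals = value if isinstance(value, tuple) else (value,)
            if not all(v >= 0 for v in vals):
                raise ValueError(f"{name} must be non-negative, got {value}")
        if any(n < 0 for n in self.n_patients_per_group):
            raise ValueError(f"n_patients_per_group must be non-negative, got {self.n_patients_per_group}")
        if self.study_window_months < 1:
            raise ValueError(f"study_window_months must be >= 1, got {self.study_window_months}")

    # -- convenience ----------------------------------------------------------------

    def group_index(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"unknown group {group!r}; known: {self.groups}") from None

    def single_group(self, group: str, **overrides) -> "SimConfig":
        """Restrict the configuration to one condition group (defaults preserved)."""
        i = self.group_index(group)
        base = dataclasses.replace(
            self,
            groups=(group,),
            n_patients_per_group=(self.n_patients_per_group[i],),
            takeup_prob=(self.takeup_prob[i],),
            tot_effect=(self.tot_effect[i],),
            group_mean_sbp=(self.group_mean_sbp[i],),
            age_mean=(self.age_mean[i],),
            age_sd=(self.age_sd[i],),
        )
        return dataclasses.replace(base, **overrides) if overrides else base

    @property
    def calendar_anchor(self) -> float:
        """Calendar month at which the latent trend equals the group mean: E[referral] − 1."""
        return (self.study_window_months - 1) / 2.0 - 1.0

    # -- flat key-value (YAML) config file -------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        record = {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(record, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()}
        return cls(**kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """True per-group effects behind a simulated cohort.

    The implied intention-to-treat effect is the treatment-on-treated effect
    diluted by take-up: ``itt = tot × takeup``, so |ITT| <= |TOT| always.
    """

    tot_effect: dict[str, float]
    takeup_prob: dict[str, float]
    itt_effect: dict[str, float]

    @classmethod
    def from_config(cls, config: SimConfig) -> "GroundTruth":
        tot = dict(zip(config.groups, config.tot_effect))
        take = dict(zip(config.groups, config.takeup_prob))
        return cls(tot_effect=tot, takeup_prob=take,
                   itt_effect={g: tot[g] * take[g] for g in config.groups})


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float,
                      hi: float, n: int) -> np.ndarray:
    """Rejection-sampled truncated normal draws (vectorized refill)."""
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    out = rng.normal(mean, sd, n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _ramp(event_months: np.ndarray, ramp_months: int) -> np.ndarray:
    post = event_months >= 0
    if ramp_months == 0:
        return post.astype(float)
    return np.where(post, np.minimum(1.0, event_months / float(ramp_months)), 0.0)


def simulate_cohort(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a full synthetic referral cohort.

    Returns ``(observations, patients, truth)``: observations with columns
    (patient_id, calendar_month_index, sbp_mmhg, source) — one row per
    reading — and a patient table with (patient_id, referral_month_index,
    age_at_referral, group, took_up).  Identical seed and config give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    H = config.event_horizon_months
    e_grid = np.arange(-H, H + 1)
    age_steps = np.floor_divide(e_grid, 12)

    obs_parts: list[pd.DataFrame] = []
    pat_parts: list[pd.DataFrame] = []
    for gi, group in enumerate(config.groups):
        n = config.n_patients_per_group[gi]
        if n == 0:
            continue
        ids = np.array([f"{group}-{i:05d}" for i in range(n)])
        referral = rng.integers(0, config.study_window_months, n)
        age_ref = np.rint(
            _truncated_normal(rng, config.age_mean[gi], config.age_sd[gi], 18, 100, n)
        ).astype(int)
        alpha = rng.normal(0.0, config.patient_sd, n)
        took = rng.random(n) < config.takeup_prob[gi]

        pat_parts.append(pd.DataFrame({
            "patient_id": ids,
            "referral_month_index": referral,
            "age_at_referral": age_ref,
            "group": group,
            "took_up": took,
        }))

        # patient-month grid (n, m): latent mean, then expand to readings
        cal = referral[:, None] + e_grid[None, :]
        age_years = age_ref[:, None] + age_steps[None, :]
        mu = (
            config.group_mean_sbp[gi]
            + alpha[:, None]
            + config.calendar_slope * (cal - config.calendar_anchor)
            + config.age_effect_per_year * (age_years - config.age_mean[gi])
            + took[:, None] * config.tot_effect[gi] * _ramp(e_grid, config.ramp_months)[None, :]
        )
        observed = rng.random((n, len(e_grid))) < config.obs_prob_per_month
        n_reads = np.where(observed, 1 + rng.poisson(config.extra_readings_rate, (n, len(e_grid))), 0)

        counts = n_reads.ravel()
        total = int(counts.sum())
        if total == 0:
            continue
        rep = np.repeat(np.arange(counts.size), counts)
        sbp = mu.ravel()[rep] + rng.normal(0.0, config.noise_sd, total)
        taker_post = (np.repeat(took[:, None], len(e_grid), axis=1).ravel()[rep]
                      & (np.tile(e_grid, n)[rep] >= 0))
        device = taker_post & (rng.random(total) < config.device_label_prob)
        obs_parts.append(pd.DataFrame({
            "patient_id": ids[rep // len(e_grid)],
            "calendar_month_index": cal.ravel()[rep],
            "sbp_mmhg": sbp,
            "source": np.where(device, "device", "office"),
        }))

    empty_obs = pd.DataFrame({"patient_id": pd.Series(dtype=str),
                              "calendar_month_index": pd.Series(dtype=int),
                              "sbp_mmhg": pd.Series(dtype=float),
                              "source": pd.Series(dtype=str)})
    empty_pat = pd.DataFrame({"patient_id": pd.Series(dtype=str),
                              "referral_month_index": pd.Series(dtype=int),
                              "age_at_referral": pd.Series(dtype=int),
                              "group": pd.Series(dtype=str),
                              "took_up": pd.Series(dtype=bool)})
    observations = pd.concat(obs_parts, ignore_index=True) if obs_parts else empty_obs
    patients = pd.concat(pat_parts, ignore_index=True) if pat_parts else empty_pat
    return observations, patients, GroundTruth.from_config(config)


def true_trend_model(config: SimConfig, group: str) -> TrendModel:
    """The generator's exact counterfactual as a :class:`TrendModel`.

    Used to validate Step-2 inference in isolation from Step-1 estimation
    error: residualizing with this model reproduces the latent
    ``patient intercept + noise`` decomposition exactly (treatment aside).
    """
    gi = config.group_index(group)
    ref_age = int(round(config.age_mean[gi]))
    b = config.age_effect_per_year
    ages = range(16, 104)  # covers [18, 100] referral ages ± panel aging
    coefs = {a: b * (a - ref_age) for a in ages}
    coefs[ref_age] = 0.0
    intercept = (
        config.group_mean_sbp[gi]
        - config.calendar_slope * config.calendar_anchor
        + b * (ref_age - config.age_mean[gi])
    )
    return TrendModel(
        intercept=float(intercept),
        calendar_slope=float(config.calendar_slope),
        age_coefficients=coefs,
        reference_age=ref_age,
        fit_window=(-12, -2),
        n_rows_fit=0,
        residual_sd=float(config.noise_sd),
    )
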