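"""Synthetic cohort generator for diary-validation studies.

Generates a cohort of problem drinkers enrolled in an internet
intervention: a latent (fully observed) daily drinking trajectory per
participant, a non-mandatory consumption diary obtained by sampling days
from that trajectory under a configurable missingness mechanism, and
gold-standard last-week timeline-followback (TLFB) totals plus AUDIT
scores at baseline and follow-up.

The latent trajectory is a two-phase process: a participant-level
baseline weekly rate, a step drop at enrollment to a week-one level, and
a small linear decline on normalized treatment time thereafter, with
negative-binomial day-level dispersion (many zero days, occasional heavy
days). The diary never distorts amounts — it only samples days — so the
latent table is an exact oracle for every downstream aggregate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from ._util import ConfigurationError, sigmoid, stage_seed

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "entry_probability",
    "plant_outcome_signal",
    "DEFAULT_ENTRY_PARAMS",
]

Mechanism = Literal["MCAR", "MNAR_amount", "MNAR_time", "full"]

#: Default entry-probability parameters per mechanism. The logistic
#: intercept/slopes are on the logit scale; ``propensity_sd`` is the SD of
#: a per-participant usage propensity added to the intercept (diary use in
#: real interventions is strongly bursty: a few heavy users, many light
#: ones). The MNAR_amount defaults are calibrated so that the induced
#: diary matches the cohort descriptives the generator targets
#: (~15 entries and ~3.9 diary-weeks per user, ~15% of users with entries
#: in the follow-up TLFB window).
#: Diary use is modeled as weekly *sessions*: a week-level presence
#: process (logistic with a per-participant propensity and a waning,
#: participant-specific time slope) decides whether the diary is used at
#: all that week; within a session week each day is logged independently
#: (logistic in that day's drinks under MNAR_amount, constant
#: otherwise). This reproduces the bursty structure of real diaries —
#: a few diary-weeks per user but ~4 logged days within each.
DEFAULT_ENTRY_PARAMS: dict[str, dict[str, float]] = {
    "full": {},
    "MCAR": {"p_week": 0.4, "p_day": 0.55, "propensity_sd": 0.0},
    "MNAR_time": {
        "week_intercept": 0.3,
        "slope": -7.0,  # mean week-presence decay per unit normalized time
        "time_slope_sd": 9.5,  # per-participant decay heterogeneity
        "propensity_sd": 1.2,
        "p_day": 0.62,
        "day_propensity_scale": 1.0,  # engaged users also log more days/session
        "first_week_boost": 3.2,  # novelty effect: almost everyone tries the diary
    },
    "MNAR_amount": {
        "week_intercept": 0.3,
        "time_slope": -7.0,  # mean week-presence decay per unit normalized time
        "time_slope_sd": 9.5,  # per-participant decay heterogeneity
        "propensity_sd": 1.2,
        "day_intercept": -0.5,
        "slope": 0.05,  # per standard drink, day-level
        "day_propensity_scale": 1.0,  # engaged users also log more days/session
        "first_week_boost": 3.2,  # novelty effect: almost everyone tries the diary
    },
}

_ANCHOR = pd.Timestamp("2018-01-01")
_ENROLLMENT_SPAN_DAYS = 730  # recruitment over two years


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with study-calibrated defaults.

    Defaults emulate the descriptives of a low-intensity internet
    intervention cohort of diary users: baseline weekly consumption
    28.1 (SD 18.66) standard drinks, a drop to roughly 16 drinks/week by
    week one, a small linear decline after that, an intended duration of
    70 days with up to ~5.5 weeks of extra time to follow-up, and AUDIT
    inclusion thresholds of >=6 for women and >=8 for men.
    """

    n_participants: int = 607
    prop_female: float = 0.5
    baseline_mean_drinks: float = 28.1
    baseline_sd_drinks: float = 18.66
    week1_mean_drinks: float = 16.0
    linear_weekly_decline: float = 1.5
    intended_duration_days: int = 70
    followup_jitter_days: int = 39
    entry_mechanism: Mechanism = "MNAR_amount"
    entry_prob_params: dict = field(default_factory=dict)
    audit_baseline_range: tuple[int, int] = (6, 40)
    seed: int = 0
    # secondary shape parameters
    day_dispersion: float = 1.5  # negative-binomial size; smaller = burstier days
    drop_ratio_log_sd: float = 0.10  # heterogeneity of the enrollment step drop
    week1_coupling: float = 0.0  # 0: all drop to a common week-1 level; 1: drop proportional to baseline
    disengaged_extra_sd: float = 0.0  # extra outcome heterogeneity for diary-disengaged participants
    female_male_ratio: float = 1.0  # women's latent rates relative to men's (mean-preserving)
    zero_drink_entries: bool = True  # may a fired entry report 0 drinks?

    def __post_init__(self):
        self.validate()
        merged = dict(DEFAULT_ENTRY_PARAMS.get(self.entry_mechanism, {}))
        merged.update(self.entry_prob_params or {})
        self.entry_prob_params = merged

    def validate(self) -> None:
        if not (isinstance(self.n_participants, (int, np.integer)) and self.n_participants >= 1):
            raise ConfigurationError("n_participants must be a positive integer")
        if not (0.0 <= self.prop_female <= 1.0):
            raise ConfigurationError("prop_female must be in [0, 1]")
        for name in ("baseline_mean_drinks", "baseline_sd_drinks", "week1_mean_drinks"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.intended_duration_days < 7:
            raise ConfigurationError("intended_duration_days must be >= 7")
        if self.followup_jitter_days < 0:
            raise ConfigurationError("followup_jitter_days must be >= 0")
        if self.entry_mechanism not in ("MCAR", "MNAR_amount", "MNAR_time", "full"):
            raise ConfigurationError(
                f"entry_mechanism must be one of MCAR/MNAR_amount/MNAR_time/full, "
                f"got {self.entry_mechanism!r}"
            )
        lo, hi = self.audit_baseline_range
        if not (0 <= lo <= hi <= 40):
            raise ConfigurationError("audit_baseline_range must satisfy 0 <= lo <= hi <= 40")
        if self.day_dispersion <= 0:
            raise ConfigurationError("day_dispersion must be > 0")
        if self.female_male_ratio <= 0:
            raise ConfigurationError("female_male_ratio must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["audit_baseline_range"] = list(self.audit_baseline_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "audit_baseline_range" in d:
            d["audit_baseline_range"] = tuple(d["audit_baseline_range"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown generator config fields: {sorted(unknown)}")
        return cls(**d)


def entry_probability(day_drinks, day_index, total_days, mechanism: str, params: dict):
    """Probability that a diary entry is made on a given day.

    Pure per-day form of the missingness menu (no participant
    heterogeneity):

    - ``full``: always 1.
    - ``MCAR``: constant ``params["p"]`` — ignores drinks and day.
    - ``MNAR_amount``: logistic in that day's drinks,
      ``sigmoid(intercept + slope * drinks)``.
    - ``MNAR_time``: logistic in normalized day position,
      ``sigmoid(intercept + slope * day_index / total_days)``.
    """
    day_index = np.asarray(day_index)
    if np.any(day_index >= total_days):
        raise ValueError("day_index must be < total_days")
    if mechanism == "full":
        return np.ones_like(np.asarray(day_drinks, dtype=float))
    if mechanism == "MCAR":
        p = float(params["p"])
        if not (0.0 <= p <= 1.0):
            raise ConfigurationError("MCAR p must be in [0, 1]")
        return np.full_like(np.asarray(day_drinks, dtype=float), p)
    if mechanism == "MNAR_amount":
        return sigmoid(params["intercept"] + params["slope"] * np.asarray(day_drinks, dtype=float))
    if mechanism == "MNAR_time":
        tau = day_index / float(total_days)
        return sigmoid(params["intercept"] + params["slope"] * tau)
    raise ConfigurationError(f"unknown entry mechanism: {mechanism!r}")


def _draw_daily_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial daily drink counts with mean ``mean``."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (participants, diary, latent) tables for one cohort.

    Returns
    -------
    participants : DataFrame
        One row per participant: ``participant_id, sex, baseline_date,
        followup_date, baseline_tlfb, followup_tlfb, audit_baseline,
        audit_followup``. TLFB totals are the latent sums over the seven
        days preceding the respective assessment, so the follow-up TLFB
        is a gold standard by construction.
    diary : DataFrame
        ``participant_id, date, drinks`` — at most one entry per
        participant-day; drinks equal the latent value for that day.
    latent : DataFrame
        ``participant_id, date, true_drinks`` for every day from baseline
        (inclusive) to follow-up (exclusive); retained for oracle tests.
    """
    cfg = config
    rng = np.random.default_rng(stage_seed(cfg.seed, "generate"))
    n = cfg.n_participants

    pid = np.array([f"p{i:04d}" for i in range(1, n + 1)])
    sex = np.where(rng.random(n) < cfg.prop_female, "female", "male")
    baseline = _ANCHOR + pd.to_timedelta(rng.integers(0, _ENROLLMENT_SPAN_DAYS, n), unit="D")
    jitter = rng.integers(0, cfg.followup_jitter_days + 1, n)
    duration = cfg.intended_duration_days + jitter
    followup = baseline + pd.to_timedelta(duration, unit="D")

    # participant-level baseline weekly rate (gamma: non-negative, right-skewed)
    if cfg.baseline_sd_drinks > 0:
        shape = (cfg.baseline_mean_drinks / cfg.baseline_sd_drinks) ** 2
        scale = cfg.baseline_sd_drinks**2 / cfg.baseline_mean_drinks
        weekly_base = rng.gamma(shape, scale, n)
    else:
        weekly_base = np.full(n, cfg.baseline_mean_drinks)

    # sex-specific consumption levels, normalized so the cohort mean is kept
    r_fm = cfg.female_male_ratio
    denom = cfg.prop_female * r_fm + (1.0 - cfg.prop_female)
    sex_mult = np.where(sex == "female", r_fm / denom, 1.0 / denom)

    # participant effects of the diary-use process, drawn up front because
    # treatment response is allowed to covary with engagement
    params = cfg.entry_prob_params
    mech = cfg.entry_mechanism
    prop_sd = float(params.get("propensity_sd", 0.0))
    propensity = rng.normal(0.0, prop_sd, n) if prop_sd > 0 else np.zeros(n)
    if mech == "MNAR_time":
        mean_decay = float(params["slope"])
    elif mech == "MNAR_amount":
        mean_decay = float(params.get("time_slope", 0.0))
    else:
        mean_decay = 0.0
    sd_ts = float(params.get("time_slope_sd", 0.0))
    decay = (
        np.minimum(rng.normal(mean_decay, sd_ts, n), 0.0) if sd_ts > 0 else np.full(n, mean_decay)
    )
    # week-level diary presence at end of treatment: the "engagement" index
    if mech == "full":
        p_end = np.ones(n)
    elif mech == "MCAR":
        base = float(params["p_week"])
        logit0 = math.log(base / (1.0 - base)) if 0.0 < base < 1.0 else (500.0 if base >= 1 else -500.0)
        p_end = sigmoid(logit0 + propensity)
    else:
        p_end = sigmoid(float(params["week_intercept"]) + propensity + decay)

    # step drop at enrollment: participants converge toward the common
    # week-one level, retaining a partial (power-law) imprint of their
    # baseline rate, with lognormal heterogeneity in the drop itself.
    # Participants who disengage from the diary get additional symmetric
    # outcome heterogeneity — among the disengaged, outcomes range from
    # full remission to none (missingness is not at random), while
    # persistent users cluster near the common moderated level.
    s = cfg.drop_ratio_log_sd
    drop_mult = np.exp(rng.normal(-0.5 * s * s, s, n)) if s > 0 else np.ones(n)
    extra_sd = cfg.disengaged_extra_sd * (1.0 - p_end)
    drop_mult = drop_mult * np.maximum(1.0 + rng.normal(0.0, 1.0, n) * extra_sd, 0.05)
    rel_base = np.maximum(weekly_base / max(cfg.baseline_mean_drinks, 1e-9), 1e-9)
    weekly_week1 = cfg.week1_mean_drinks * rel_base**cfg.week1_coupling * drop_mult * sex_mult
    weekly_base = weekly_base * sex_mult

    # latent daily counts, all participants concatenated
    day_index = np.concatenate([np.arange(d) for d in duration])
    row_pid = np.repeat(np.arange(n), duration)
    tau = day_index / duration[row_pid].astype(float)
    weekly_mu = np.maximum(weekly_week1[row_pid] - cfg.linear_weekly_decline * tau, 0.25)
    daily_mu = weekly_mu / 7.0
    true_drinks = _draw_daily_counts(rng, daily_mu, cfg.day_dispersion)

    latent = pd.DataFrame(
        {
            "participant_id": pid[row_pid],
            "date": baseline[row_pid] + pd.to_timedelta(day_index, unit="D"),
            "true_drinks": true_drinks.astype(int),
        }
    )

    # baseline TLFB: seven pre-enrollment days at the baseline rate
    pre = _draw_daily_counts(rng, np.repeat(weekly_base / 7.0, 7), cfg.day_dispersion)
    baseline_tlfb = pre.reshape(n, 7).sum(axis=1)

    # follow-up TLFB: latent sum over [followup-7, followup-1]
    in_window = day_index >= (duration[row_pid] - 7)
    followup_tlfb = np.bincount(row_pid[in_window], weights=true_drinks[in_window], minlength=n)

    # AUDIT: baseline from a truncated normal respecting inclusion floors;
    # follow-up = baseline minus a change score tracking true reduction.
    lo, hi = cfg.audit_baseline_range
    floor = np.where(sex == "female", max(lo, 6), max(lo, 8))
    audit_base = np.clip(np.round(rng.normal(16.0, 6.0, n)), floor, hi).astype(int)
    reduction = baseline_tlfb - followup_tlfb
    red_sd = reduction.std() if reduction.std() > 0 else 1.0
    red_z = (reduction - reduction.mean()) / red_sd
    change = np.round(3.2 + 2.5 * red_z + rng.normal(0.0, 3.0, n))
    audit_fu = np.clip(audit_base - change, 0, 40).astype(int)

    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "sex": sex,
            "baseline_date": baseline,
            "followup_date": followup,
            "baseline_tlfb": baseline_tlfb.astype(float),
            "followup_tlfb": followup_tlfb.astype(float),
            "audit_baseline": audit_base,
            "audit_followup": audit_fu,
        }
    )

    # diary sampling: weekly session presence times day-level selection,
    # reusing the participant effects drawn above
    week_of_day = day_index // 7
    # normalized time of each week's midpoint, per participant-week
    tau_week = (week_of_day * 7 + 3) / duration[row_pid].astype(float)

    if mech == "full":
        p_week = np.ones(len(latent))
        p_day = np.ones(len(latent))
    elif mech == "MCAR":
        base = float(params["p_week"])
        logit0 = math.log(base / (1.0 - base)) if 0.0 < base < 1.0 else (500.0 if base >= 1 else -500.0)
        p_week = sigmoid(logit0 + propensity[row_pid])
        p_day = np.full(len(latent), float(params["p_day"]))
    elif mech == "MNAR_time":
        boost = float(params.get("first_week_boost", 0.0)) * (week_of_day == 0)
        p_week = sigmoid(
            float(params["week_intercept"]) + propensity[row_pid] + decay[row_pid] * tau_week + boost
        )
        day_prop = float(params.get("day_propensity_scale", 0.0)) * propensity
        base_day = float(params["p_day"])
        logit_day = math.log(base_day / (1.0 - base_day))
        p_day = sigmoid(logit_day + day_prop[row_pid])
    elif mech == "MNAR_amount":
        boost = float(params.get("first_week_boost", 0.0)) * (week_of_day == 0)
        p_week = sigmoid(
            float(params["week_intercept"]) + propensity[row_pid] + decay[row_pid] * tau_week + boost
        )
        day_prop = float(params.get("day_propensity_scale", 0.0)) * propensity
        p_day = sigmoid(
            float(params["day_intercept"]) + day_prop[row_pid] + float(params["slope"]) * true_drinks
        )
    else:  # pragma: no cover - guarded by config validation
        raise ConfigurationError(f"unknown entry mechanism: {mech!r}")

    # one presence draw per participant-week, shared by its days
    week_key = row_pid * 16 + week_of_day  # max 16 weeks per participant
    uniq, inv = np.unique(week_key, return_inverse=True)
    week_draw = rng.random(len(uniq))[inv]
    fired = (week_draw < p_week) & (rng.random(len(latent)) < p_day)
    if not cfg.zero_drink_entries:
        fired &= true_drinks > 0
    diary = latent.loc[fired, ["participant_id", "date", "true_drinks"]].rename(
        columns={"true_drinks": "drinks"}
    )
    diary = diary.reset_index(drop=True)
    diary["drinks"] = diary["drinks"].astype(float)

    return participants, diary, latent


def plant_outcome_signal(
    latent: pd.DataFrame, effect_size: float, seed: int
) -> pd.DataFrame:
    """Attach a binary outcome carrying a tunable first-half signal.

    The per-participant score is the standardized *negative* mean of
    latent daily drinks over the first half of treatment: participants who
    reach low consumption early are the "improvers". Labels are Bernoulli
    with ``P(improved) = sigmoid(effect_size * score)``; ``effect_size=0``
    gives labels independent of the data, ``effect_size=inf`` gives the
    deterministic rule "improved iff first-half mean below the cohort
    median", which first-half diary summaries can recover exactly under
    full observation.

    Returns a table ``participant_id, planted_outcome``.
    """
    lat = latent.copy()
    lat["date"] = pd.to_datetime(lat["date"])
    grp = lat.groupby("participant_id", sort=True)
    start = grp["date"].transform("min")
    n_days = grp["date"].transform("size")
    day = (lat["date"] - start).dt.days
    first_half = lat.loc[(day / n_days) < 0.5]
    means = first_half.groupby("participant_id", sort=True)["true_drinks"].mean()

    rng = np.random.default_rng(stage_seed(seed, "plant_outcome"))
    sd = means.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        score = pd.Series(0.0, index=means.index)
    else:
        score = -(means - means.median()) / sd
    if np.isinf(effect_size):
        labels = (score > 0).astype(bool)
    else:
        p = sigmoid(float(effect_size) * score.to_numpy())
        labels = pd.Series(rng.random(len(score)) < p, index=score.index)
    return pd.DataFrame(
        {"participant_id": score.index.to_numpy(), "planted_outcome": np.asarray(labels, dtype=bool)}
    )
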