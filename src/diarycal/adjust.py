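"""Missing-entry adjustment derived from the follow-up overlap subset.

Participants whose diary use happens to overlap the seven-day TLFB
recall window at follow-up provide a natural calibration set: for them
both the diary-reported drinks in that window and the gold-standard TLFB
total are observed. Regressing the TLFB total on (diary drinks in
window, number of window days with no entry) yields two scaling
coefficients — predicted drinks per reported drink, and drinks per
missing day per week — which are then applied to every participant-week
(the intercept is estimated but never applied). Coefficient stability is
assessed with a case bootstrap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import EstimationError, ValidationError, stage_seed

__all__ = [
    "find_overlap_subset",
    "fit_adjustment",
    "bootstrap_adjustment",
    "apply_adjustment",
    "compare_subsets",
    "AdjustmentModel",
    "EffectSize",
]

logger = logging.getLogger(__name__)


@dataclass
class AdjustmentModel:
    """Fitted calibration coefficients plus bootstrap replicates.

    ``beta_drinks`` — predicted drinks per reported drink;
    ``beta_missing`` — drinks per missing day per week. The intercept is
    retained for diagnostics but excluded from any scaling.
    """

    beta_missing: float
    beta_drinks: float
    intercept: float
    n_rows: int
    r_squared: float
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None
    bootstrap_betas: np.ndarray | None = None  # (B, 2): columns (beta_drinks, beta_missing)
    bootstrap_seed: int | None = None

    def percentile_interval(self, which: str, level: float = 0.95) -> tuple[float, float]:
        if self.bootstrap_betas is None:
            raise EstimationError("no bootstrap replicates available")
        col = {"beta_drinks": 0, "beta_missing": 1}[which]
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.bootstrap_betas[:, col], [alpha, 1.0 - alpha])
        return float(lo), float(hi)

    def to_json(self) -> str:
        doc = {
            "beta_missing": self.beta_missing,
            "beta_drinks": self.beta_drinks,
            "intercept": self.intercept,
            "n_rows": self.n_rows,
            "r_squared": self.r_squared,
        }
        if self.bootstrap_betas is not None:
            doc["bootstrap"] = {
                "B": int(self.bootstrap_betas.shape[0]),
                "seed": self.bootstrap_seed,
                "beta_drinks_ci95": list(self.percentile_interval("beta_drinks")),
                "beta_missing_ci95": list(self.percentile_interval("beta_missing")),
            }
        return json.dumps(doc, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AdjustmentModel":
        doc = json.loads(text)
        return cls(
            beta_missing=doc["beta_missing"],
            beta_drinks=doc["beta_drinks"],
            intercept=doc["intercept"],
            n_rows=doc["n_rows"],
            r_squared=doc.get("r_squared", float("nan")),
        )


@dataclass
class EffectSize:
    """Standardized between-group difference with a normal 95% CI."""

    variable: str
    cohens_d: float
    ci_low: float
    ci_high: float
    group_means: tuple[float, float]


def find_overlap_subset(entries: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Build the calibration table from the follow-up TLFB window.

    One row per participant with at least one diary entry dated in
    ``[followup - 7, followup - 1]``: ``participant_id, tlfb_total,
    calendar_drinks, days_missing, n_entries``.
    """
    merged = entries.merge(
        participants[["participant_id", "followup_date", "followup_tlfb"]],
        on="participant_id",
        how="left",
    )
    lag = (merged["followup_date"] - merged["date"]).dt.days
    window = merged.loc[(lag >= 1) & (lag <= 7)]
    if len(window) == 0:
        return pd.DataFrame(
            columns=["participant_id", "tlfb_total", "calendar_drinks", "days_missing", "n_entries"]
        )
    rows = (
        window.groupby("participant_id", as_index=False, sort=True)
        .agg(
            tlfb_total=("followup_tlfb", "first"),
            calendar_drinks=("drinks", "sum"),
            days_observed=("date", "nunique"),
            n_entries=("date", "size"),
        )
    )
    rows["days_missing"] = 7 - rows["days_observed"]
    logger.info(
        "overlap subset: n=%d participants, k=%d underlying entries",
        len(rows),
        int(rows["n_entries"].sum()),
    )
    return rows[["participant_id", "tlfb_total", "calendar_drinks", "days_missing", "n_entries"]]


def _check_design(overlap: pd.DataFrame) -> None:
    if len(overlap) < 3:
        raise EstimationError(f"need >= 3 overlap rows to fit the adjustment, got {len(overlap)}")
    for col in ("calendar_drinks", "days_missing"):
        if overlap[col].nunique() < 2:
            raise EstimationError(
                f"degenerate predictor {col!r}: constant across the overlap subset"
            )


def fit_adjustment(overlap: pd.DataFrame) -> AdjustmentModel:
    """OLS of the TLFB total on (calendar drinks, missing days) + intercept."""
    _check_design(overlap)
    X = sm.add_constant(overlap[["calendar_drinks", "days_missing"]].to_numpy(dtype=float))
    y = overlap["tlfb_total"].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    return AdjustmentModel(
        beta_missing=float(res.params[2]),
        beta_drinks=float(res.params[1]),
        intercept=float(res.params[0]),
        n_rows=len(overlap),
        r_squared=float(res.rsquared),
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
    )


def bootstrap_adjustment(
    overlap: pd.DataFrame, B: int, seed: int, max_retries_per_draw: int = 100
) -> np.ndarray:
    """Case-bootstrap replicates of (beta_drinks, beta_missing).

    Rows are resampled with replacement (size n). A resample with a
    rank-deficient design (e.g. days_missing constant) is redrawn, up to
    ``max_retries_per_draw`` attempts, then an error is raised.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    _check_design(overlap)
    rng = np.random.default_rng(stage_seed(seed, "bootstrap_adjustment"))
    n = len(overlap)
    cal = overlap["calendar_drinks"].to_numpy(dtype=float)
    mis = overlap["days_missing"].to_numpy(dtype=float)
    y = overlap["tlfb_total"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), cal, mis])

    out = np.empty((B, 2))
    redraws = 0
    for b in range(B):
        for _ in range(max_retries_per_draw):
            idx = rng.integers(0, n, n)
            Xb = X[idx]
            # degenerate when either predictor is constant in the resample
            if np.ptp(Xb[:, 1]) == 0.0 or np.ptp(Xb[:, 2]) == 0.0:
                redraws += 1
                continue
            beta, *_ = np.linalg.lstsq(Xb, y[idx], rcond=None)
            out[b] = beta[1], beta[2]
            break
        else:
            raise EstimationError(
                f"bootstrap resample {b} rank-deficient after {max_retries_per_draw} redraws"
            )
    if redraws:
        logger.info("bootstrap_adjustment: %d rank-deficient resamples redrawn", redraws)
    return out


def apply_adjustment(weeks: pd.DataFrame, model: AdjustmentModel) -> pd.DataFrame:
    """Scale participant-weeks: ``adjusted = b_drinks*raw + b_missing*(7 - days_present)``.

    No intercept term is applied. Negative results (possible only with a
    negative fitted coefficient) are floored at zero and logged.
    """
    if model is None or not np.isfinite(model.beta_drinks):
        raise EstimationError("adjustment model is not fitted")
    bad = ~weeks["days_present"].between(1, 7)
    if bad.any():
        raise ValidationError("days_present must be in 1..7 for every week row")
    out = weeks.copy()
    adj = model.beta_drinks * out["raw_drinks"] + model.beta_missing * (7 - out["days_present"])
    n_neg = int((adj < 0).sum())
    if n_neg:
        logger.info("apply_adjustment: %d adjusted values floored at 0", n_neg)
    out["adjusted_drinks"] = np.maximum(adj, 0.0)
    return out


def _cohens_d(a: np.ndarray, b: np.ndarray, name: str) -> EffectSize:
    n1, n2 = len(a), len(b)
    m1, m2 = float(np.mean(a)), float(np.mean(b))
    s1 = np.var(a, ddof=1) if n1 > 1 else 0.0
    s2 = np.var(b, ddof=1) if n2 > 1 else 0.0
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0:
        if m1 == m2:
            return EffectSize(name, 0.0, 0.0, 0.0, (m1, m2))
        raise EstimationError(f"pooled SD is zero but means differ for {name!r}")
    d = (m1 - m2) / pooled
    se = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2)))
    return EffectSize(name, float(d), float(d - 1.96 * se), float(d + 1.96 * se), (m1, m2))


def compare_subsets(
    overlap_ids, participants: pd.DataFrame, weeks: pd.DataFrame
) -> list[EffectSize]:
    """Overlap subset vs remainder on four per-participant variables:
    weeks of data, entry counts, average weekly drinks, maximum weekly
    drinks (pooled-SD Cohen's d with normal 95% CI).
    """
    per = weeks.groupby("participant_id").agg(
        n_weeks=("week_index", "size"),
        n_entries=("n_entries", "sum"),
        avg_drinks=("raw_drinks", "mean"),
        max_drinks=("raw_drinks", "max"),
    )
    overlap_ids = set(overlap_ids)
    in_sub = per.index.isin(overlap_ids)
    if in_sub.sum() == 0 or (~in_sub).sum() == 0:
        raise EstimationError("both the overlap subset and the remainder must be non-empty")
    results = []
    for col in ("n_weeks", "n_entries", "avg_drinks", "max_drinks"):
        results.append(
            _cohens_d(per.loc[in_sub, col].to_numpy(float), per.loc[~in_sub, col].to_numpy(float), col)
        )
    return results
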