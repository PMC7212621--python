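"""Population-average drinking trajectories and the CI-overlap check.

A gaussian-family GEE with an exchangeable working correlation and
robust (sandwich) standard errors is fitted to weekly drinks on
*reversed* normalized time, ``t' = 1 - week / total_weeks``. Under this
coding the model intercept is the predicted drinks/week at the end of
treatment (normalized time 1) — the end-point estimate — with a robust
SE directly available; the time coefficient is the same linear trend as
under forward coding, up to sign. The end-point interval is compared to
the 95% CI of the TLFB-derived follow-up mean: overlap is read as good
estimation, disjoint intervals as over-/under-estimation by sign.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import EstimationError
from .adjust import AdjustmentModel, apply_adjustment

__all__ = [
    "TrajectoryFit",
    "IntervalEstimate",
    "Verdict",
    "fit_gee",
    "followup_mean",
    "ci_overlap",
    "validate",
    "ValidationReport",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class TrajectoryFit:
    """GEE trajectory summary.

    ``slope_B`` is the drinks change over the full normalized duration
    (forward-time coefficient; negative = decline). ``endpoint_B`` is the
    predicted drinks/week at normalized time 1 (the reversed-time
    intercept). SEs are robust (sandwich).
    """

    response: str
    slope_B: float
    slope_SE: float
    endpoint_B: float
    endpoint_SE: float
    working_correlation: float
    n_clusters: int
    n_obs: int

    @property
    def endpoint_interval(self) -> "IntervalEstimate":
        return IntervalEstimate(
            point=self.endpoint_B,
            ci_low=self.endpoint_B - Z95 * self.endpoint_SE,
            ci_high=self.endpoint_B + Z95 * self.endpoint_SE,
        )

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "slope_B": self.slope_B,
            "slope_SE": self.slope_SE,
            "endpoint_B": self.endpoint_B,
            "endpoint_SE": self.endpoint_SE,
            "working_correlation": self.working_correlation,
            "n_clusters": self.n_clusters,
            "n_obs": self.n_obs,
        }


@dataclass
class IntervalEstimate:
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self):
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("interval must satisfy ci_low <= point <= ci_high")

    def to_dict(self) -> dict:
        return {"point": self.point, "ci_low": self.ci_low, "ci_high": self.ci_high, "level": self.level}


class Verdict(str, Enum):
    GOOD = "good_estimation"
    OVER = "overestimation"
    UNDER = "underestimation"


def fit_gee(weeks: pd.DataFrame, response: str = "raw") -> TrajectoryFit:
    """Fit the marginal linear trajectory for ``raw`` or ``adjusted`` drinks.

    Clusters are participants; working correlation exchangeable;
    covariance robust. Requires at least two clusters.
    """
    col = {"raw": "raw_drinks", "adjusted": "adjusted_drinks"}[response]
    if col not in weeks.columns:
        raise EstimationError(f"week table has no column {col!r}")
    y = weeks[col].to_numpy(dtype=float)
    groups = weeks["participant_id"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise EstimationError("GEE requires at least 2 participant clusters")
    rev_time = 1.0 - weeks["normalized_time"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(rev_time), rev_time])
    if np.ptp(y) == 0.0:
        warnings.warn("response is constant; slope is 0 by construction")
        return TrajectoryFit(
            response=response,
            slope_B=0.0,
            slope_SE=1e-12,  # degenerate fit: no residual variance
            endpoint_B=float(y[0]),
            endpoint_SE=1e-12,
            working_correlation=0.0,
            n_clusters=int(len(np.unique(groups))),
            n_obs=int(len(y)),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels emits convergence chatter on clean fits
        model = sm.GEE(
            y,
            X,
            groups=groups,
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        res = model.fit()
    # reversed-time coefficient b means forward-time slope -b
    return TrajectoryFit(
        response=response,
        slope_B=float(-res.params[1]),
        slope_SE=float(res.bse[1]),
        endpoint_B=float(res.params[0]),
        endpoint_SE=float(res.bse[0]),
        working_correlation=float(model.cov_struct.dep_params),
        n_clusters=int(len(np.unique(groups))),
        n_obs=int(len(y)),
    )


def followup_mean(participants: pd.DataFrame) -> IntervalEstimate:
    """Sample mean of follow-up TLFB totals with a normal 95% CI."""
    vals = participants["followup_tlfb"].dropna().to_numpy(dtype=float)
    if len(vals) < 2:
        raise EstimationError("need >= 2 follow-up TLFB values")
    m = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return IntervalEstimate(point=m, ci_low=m - Z95 * se, ci_high=m + Z95 * se)


def ci_overlap(a: IntervalEstimate, b: IntervalEstimate) -> Verdict:
    """Classify interval ``a`` against reference interval ``b``.

    Overlapping intervals count as good estimation; otherwise the sign of
    the point difference decides over- vs under-estimation.
    """
    if a.ci_low <= b.ci_high and b.ci_low <= a.ci_high:
        return Verdict.GOOD
    return Verdict.OVER if a.point > b.point else Verdict.UNDER


@dataclass
class ValidationReport:
    raw_fit: TrajectoryFit
    adjusted_fit: TrajectoryFit
    followup: IntervalEstimate
    raw_verdict: Verdict
    adjusted_verdict: Verdict

    def to_dict(self) -> dict:
        return {
            "raw_fit": self.raw_fit.to_dict(),
            "adjusted_fit": self.adjusted_fit.to_dict(),
            "followup": self.followup.to_dict(),
            "raw_verdict": self.raw_verdict.value,
            "adjusted_verdict": self.adjusted_verdict.value,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def to_text(self) -> str:
        lines = ["Trajectory validation", "====================="]
        for fit, verdict in ((self.raw_fit, self.raw_verdict), (self.adjusted_fit, self.adjusted_verdict)):
            iv = fit.endpoint_interval
            lines.append(
                f"{fit.response:>8s}: end-point B = {fit.endpoint_B:.2f} "
                f"(SE = {fit.endpoint_SE:.2f}, 95% CI {iv.ci_low:.2f}..{iv.ci_high:.2f}), "
                f"time effect = {fit.slope_B:+.2f} drinks over duration "
                f"(SE = {fit.slope_SE:.2f}) -> {verdict.value}"
            )
        lines.append(
            f"follow-up TLFB mean = {self.followup.point:.2f} "
            f"(95% CI {self.followup.ci_low:.2f}..{self.followup.ci_high:.2f})"
        )
        return "\n".join(lines)


def validate(
    weeks: pd.DataFrame, participants: pd.DataFrame, model: AdjustmentModel
) -> ValidationReport:
    """Full validation: raw and adjusted GEE end-points vs follow-up TLFB."""
    weeks_adj = apply_adjustment(weeks, model) if "adjusted_drinks" not in weeks.columns else weeks
    raw_fit = fit_gee(weeks_adj, "raw")
    adj_fit = fit_gee(weeks_adj, "adjusted")
    fu = followup_mean(participants)
    return ValidationReport(
        raw_fit=raw_fit,
        adjusted_fit=adj_fit,
        followup=fu,
        raw_verdict=ci_overlap(raw_fit.endpoint_interval, fu),
        adjusted_verdict=ci_overlap(adj_fit.endpoint_interval, fu),
    )
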