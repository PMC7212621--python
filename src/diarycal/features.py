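"""First-half diary features and binary outcome labels.

Eighteen per-participant predictors are engineered from diary entries
made during the first half of treatment (normalized day position < 0.5):
sixteen order/summary statistics of the entry-level drink amounts plus
the participant-specific random intercept and slope (conditional modes)
of a Poisson mixed model of drinks on normalized entry time. Two binary
treatment-success labels are derived from the follow-up assessment:
non-hazardous drinking (follow-up TLFB total <= 14 standard drinks for
men, <= 9 for women) and a drop in AUDIT risk zone.

Entry-level drinking categories (used by the count/percentage features):
women — light <= 3, heavy 4-6, binge >= 7 drinks; men — light <= 4,
heavy 5-8, binge >= 9. Non-integer amounts falling between categories
are resolved with precedence binge > heavy > light and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import EstimationError, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "first_half_filter",
    "classify_entry",
    "summarize_features",
    "fit_poisson_trajectory",
    "build_feature_matrix",
    "define_outcomes",
    "PoissonMixedFit",
]

logger = logging.getLogger(__name__)

#: Canonical predictor names, also used as CSV headers.
FEATURE_NAMES = [
    "Abs.diff",
    "Avg.drinks",
    "Entries",
    "intercept",
    "IQR.drinks",
    "Max.drinks",
    "Median.drinks",
    "Min.drinks",
    "n.binge",
    "n.heavy",
    "n.light",
    "Perc.binge",
    "Perc.heavy",
    "Perc.light",
    "Range.drinks",
    "Rel.diff",
    "slope",
    "Sum.drinks",
]

_BINGE_ABOVE = {"female": 6.0, "male": 8.0}
_HEAVY_ABOVE = {"female": 3.0, "male": 4.0}


def first_half_filter(
    entries: pd.DataFrame,
    participants: pd.DataFrame,
    intended_duration_days: int = 70,
    max_extra_days: int = 35,
) -> pd.DataFrame:
    """Retain first-half entries of on-time participants.

    Keeps entries with normalized day position strictly below 0.5 of the
    participant's actual duration, excludes participants whose follow-up
    came more than ``max_extra_days`` after the intended duration, and
    drops participants left with no first-half entries. Adds a
    ``norm_time`` column (day / duration, in [0, 0.5)).
    """
    merged = entries.merge(
        participants[["participant_id", "baseline_date", "followup_date"]],
        on="participant_id",
        how="left",
    )
    duration = (merged["followup_date"] - merged["baseline_date"]).dt.days
    on_time = duration <= intended_duration_days + max_extra_days
    n_late = merged.loc[~on_time, "participant_id"].nunique()
    if n_late:
        logger.info("first_half_filter: excluded %d participants with > %d extra days", n_late, max_extra_days)
    day = (merged["date"] - merged["baseline_date"]).dt.days
    norm = day / duration
    keep = on_time & (norm < 0.5)
    out = entries.loc[keep.to_numpy()].copy()
    out["norm_time"] = norm[keep].to_numpy()
    logger.info(
        "first_half_filter: retained k=%d entries from %d participants",
        len(out),
        out["participant_id"].nunique(),
    )
    return out.reset_index(drop=True)


def classify_entry(drinks: float, sex: str) -> str:
    """Classify one entry as ``light``, ``heavy`` or ``binge``.

    Thresholds are sex-specific (see module docstring). For non-integer
    amounts the category boundaries are applied to the raw value with
    precedence binge > heavy > light.
    """
    if drinks < 0:
        raise ValidationError("drinks must be >= 0")
    if sex not in _BINGE_ABOVE:
        raise ValidationError(f"unknown sex {sex!r}")
    if float(drinks) != int(drinks):
        logger.debug("classify_entry: non-integer drinks %s resolved by precedence", drinks)
    if drinks > _BINGE_ABOVE[sex]:
        return "binge"
    if drinks > _HEAVY_ABOVE[sex]:
        return "heavy"
    return "light"


def summarize_features(entries: pd.DataFrame, sex: str) -> dict:
    """The sixteen summary features for one participant's first-half entries.

    Entries are ordered by date; ``Abs.diff`` is the signed last-minus-
    first difference, ``Rel.diff`` the same divided by the first entry's
    drinks (0 when the first entry is 0). Quantiles use the linear-
    interpolation convention, so ``IQR.drinks`` and ``Median.drinks``
    are bit-reproducible.
    """
    if len(entries) == 0:
        raise ValidationError("summarize_features needs >= 1 entry")
    ordered = entries.sort_values("date")
    drinks = ordered["drinks"].to_numpy(dtype=float)
    first, last = drinks[0], drinks[-1]
    cats = np.array([classify_entry(d, sex) for d in drinks])
    n = len(drinks)
    n_binge = int((cats == "binge").sum())
    n_heavy = int((cats == "heavy").sum())
    n_light = int((cats == "light").sum())
    q25, q75 = np.percentile(drinks, [25, 75])
    return {
        "Abs.diff": float(last - first),
        "Avg.drinks": float(drinks.mean()),
        "Entries": float(n),
        "IQR.drinks": float(q75 - q25),
        "Max.drinks": float(drinks.max()),
        "Median.drinks": float(np.percentile(drinks, 50)),
        "Min.drinks": float(drinks.min()),
        "n.binge": float(n_binge),
        "n.heavy": float(n_heavy),
        "n.light": float(n_light),
        "Perc.binge": n_binge / n,
        "Perc.heavy": n_heavy / n,
        "Perc.light": n_light / n,
        "Range.drinks": float(drinks.max() - drinks.min()),
        "Rel.diff": float((last - first) / first) if first > 0 else 0.0,
        "Sum.drinks": float(drinks.sum()),
    }


@dataclass
class PoissonMixedFit:
    """Fitted Poisson mixed model: fixed effects, random-effect covariance
    and per-participant conditional modes."""

    beta: np.ndarray  # (2,) fixed intercept and time slope (log scale)
    cov_re: np.ndarray  # (2, 2) random-effect covariance
    modes: pd.DataFrame  # participant_id, intercept, slope
    converged: bool
    n_iter: int


def _participant_modes(y, t, beta, D_inv, u0=None, max_newton: int = 50):
    """Conditional mode and Hessian of (u0, u1) for one participant.

    Maximizes the Poisson log-likelihood with Gaussian prior penalty via
    damped Newton steps; eta is clipped for overflow safety.
    """
    Z = np.column_stack([np.ones_like(t), t])
    offset = beta[0] + beta[1] * t
    u = np.zeros(2) if u0 is None else u0.copy()

    def negloglik(u):
        eta = np.clip(offset + Z @ u, -30.0, 30.0)
        return -(y @ eta - np.exp(eta).sum()) + 0.5 * u @ D_inv @ u

    f = negloglik(u)
    H = None
    for _ in range(max_newton):
        eta = np.clip(offset + Z @ u, -30.0, 30.0)
        mu = np.exp(eta)
        grad = Z.T @ (y - mu) - D_inv @ u
        H = Z.T @ (Z * mu[:, None]) + D_inv
        step = np.linalg.solve(H, grad)
        if not np.all(np.isfinite(step)):
            break
        # backtracking line search
        alpha = 1.0
        for _ in range(30):
            u_new = u + alpha * step
            f_new = negloglik(u_new)
            if f_new <= f + 1e-12:
                break
            alpha *= 0.5
        if f - f_new < 1e-10 and np.linalg.norm(alpha * step) < 1e-8:
            u, f = u_new, f_new
            break
        u, f = u_new, f_new
    eta = np.clip(offset + Z @ u, -30.0, 30.0)
    H = Z.T @ (Z * np.exp(eta)[:, None]) + D_inv
    return u, H


def fit_poisson_trajectory(
    entries: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> PoissonMixedFit:
    """Poisson mixed model of entry-level drinks on normalized entry time.

    ``log E[drinks] = (b0 + u0_i) + (b1 + u1_i) * t`` with correlated
    random intercept and slope, fitted by Laplace-approximate EM:
    conditional modes by per-participant Newton steps, the random-effect
    covariance from the moment update ``D = mean(u u' + H^{-1})``, and
    fixed effects by IRLS with the modes as offsets. The returned
    ``modes`` table holds the shrinkage estimates used as the
    ``intercept`` and ``slope`` features (centered near zero by
    construction).

    Non-integer drink amounts are rounded (logged); on non-convergence
    the last iterate is returned with ``converged=False``, which amounts
    to ridge-penalized per-participant fits at the final covariance.
    """
    if entries["participant_id"].nunique() < 2:
        raise EstimationError("Poisson mixed model needs >= 2 participants")
    if "norm_time" not in entries.columns:
        raise ValidationError("entries must carry norm_time (run first_half_filter)")
    work = entries.sort_values(["participant_id", "date"]).reset_index(drop=True)
    y_raw = work["drinks"].to_numpy(dtype=float)
    y = np.rint(y_raw)
    n_round = int((y != y_raw).sum())
    if n_round:
        logger.info("fit_poisson_trajectory: rounded %d non-integer drink values", n_round)
    t = work["norm_time"].to_numpy(dtype=float)
    pids, idx = np.unique(work["participant_id"].to_numpy(), return_inverse=True)
    groups = [np.flatnonzero(idx == g) for g in range(len(pids))]

    # init: pooled Poisson fit via IRLS
    X = np.column_stack([np.ones_like(t), t])
    beta = np.array([np.log(max(y.mean(), 1e-6)), 0.0])
    for _ in range(25):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        H = X.T @ (X * mu[:, None])
        beta = beta + np.linalg.solve(H, grad)
        if np.linalg.norm(grad) < 1e-8:
            break

    D = np.diag([0.5, 0.5])
    U = np.zeros((len(pids), 2))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        D_reg = D + 1e-8 * np.eye(2)
        D_inv = np.linalg.inv(D_reg)
        S = np.zeros((2, 2))
        for g, rows in enumerate(groups):
            u, H = _participant_modes(y[rows], t[rows], beta, D_inv, U[g])
            U[g] = u
            S += np.outer(u, u) + np.linalg.inv(H)
        D_new = S / len(pids)
        # floor tiny variances so D stays invertible
        D_new[0, 0] = max(D_new[0, 0], 1e-6)
        D_new[1, 1] = max(D_new[1, 1], 1e-6)

        # fixed-effect IRLS step with random effects as offset
        off = U[idx, 0] + U[idx, 1] * t
        beta_new = beta.copy()
        for _ in range(5):
            eta = np.clip(X @ beta_new + off, -30.0, 30.0)
            mu = np.exp(eta)
            H = X.T @ (X * mu[:, None])
            beta_new = beta_new + np.linalg.solve(H, X.T @ (y - mu))
        delta = max(np.abs(D_new - D).max(), np.abs(beta_new - beta).max())
        D, beta = D_new, beta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_poisson_trajectory: EM did not converge in %d iterations", max_iter)

    modes = pd.DataFrame({"participant_id": pids, "intercept": U[:, 0], "slope": U[:, 1]})
    return PoissonMixedFit(beta=beta, cov_re=D, modes=modes, converged=converged, n_iter=it)


def build_feature_matrix(
    first_half_entries: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the full 18-column feature matrix, indexed by participant.

    Combines the per-participant summary statistics with the Poisson
    mixed-model intercept/slope modes. Column order follows
    ``FEATURE_NAMES``.
    """
    sex_map = participants.set_index("participant_id")["sex"]
    rows = {}
    for pid, grp in first_half_entries.groupby("participant_id", sort=True):
        rows[pid] = summarize_features(grp, sex_map[pid])
    summary = pd.DataFrame.from_dict(rows, orient="index")
    glmm = fit_poisson_trajectory(first_half_entries, participants).modes.set_index("participant_id")
    mat = summary.join(glmm)
    mat.index.name = "participant_id"
    return mat[FEATURE_NAMES]


# AUDIT risk zones: low (0-7), hazardous (8-15), harmful (16-19),
# probable dependence (20-40)
_AUDIT_ZONE_BOUNDS = (7, 15, 19)


def audit_zone(score: int) -> int:
    z = 0
    for bound in _AUDIT_ZONE_BOUNDS:
        if score > bound:
            z += 1
    return z


def define_outcomes(participants: pd.DataFrame) -> pd.DataFrame:
    """Binary treatment-success labels per participant.

    ``non_hazardous``: follow-up TLFB total <= 14 (men) / <= 9 (women).
    ``audit_improved``: follow-up AUDIT risk zone strictly below the
    baseline zone. Participants missing any required field are excluded
    (logged).
    """
    required = ["followup_tlfb", "audit_baseline", "audit_followup", "sex"]
    ok = participants[required].notna().all(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("define_outcomes: excluded %d participants with missing follow-up fields", n_drop)
    sub = participants.loc[ok]
    limit = np.where(sub["sex"] == "male", 14.0, 9.0)
    non_haz = sub["followup_tlfb"].to_numpy(dtype=float) <= limit
    zones_base = sub["audit_baseline"].map(audit_zone)
    zones_fu = sub["audit_followup"].map(audit_zone)
    return pd.DataFrame(
        {
            "participant_id": sub["participant_id"].to_numpy(),
            "non_hazardous": non_haz,
            "audit_improved": (zones_fu < zones_base).to_numpy(),
        }
    )
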