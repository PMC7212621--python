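"""Random-forest outcome prediction with repeated and nested CV.

Two evaluation routes, mirroring how clinical ML analyses are usually
reported:

- *Repeated cross-validation (RCV)*: a grid search over ``mtry`` (the
  number of candidate features per split) scored by out-of-fold ROC AUC;
  the optimal model is refit on the full data and summarized by
  sensitivity/specificity at the classification cutoff, a decile
  calibration curve, and variable importances scaled 0-100.
- *Nested cross-validation (NCV)*: outer folds are held out entirely
  while inner folds pick ``mtry``, giving honest generalization accuracy
  and ROC estimates. Scaling/centering is fitted inside each training
  fold only.

The positive class is always "improved", so sensitivity is the rate at
which true improvers are recognized.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from ._util import EstimationError, ValidationError, stage_seed

__all__ = ["RFConfig", "EvalResult", "train_rf_rcv", "nested_cv", "outcome_agreement"]

logger = logging.getLogger(__name__)


@dataclass
class RFConfig:
    """Random-forest and cross-validation settings."""

    n_trees: int = 500
    mtry_grid: tuple[int, ...] = tuple(range(1, 18))
    rcv_folds: int = 10
    rcv_repeats: int = 3
    ncv_outer: int = 10
    ncv_inner: int = 10
    classification_cutoff: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.classification_cutoff < 1.0):
            raise ValueError("classification_cutoff must be in (0, 1)")
        if min(self.mtry_grid) < 1:
            raise ValueError("mtry values must be >= 1")


@dataclass
class EvalResult:
    """Evaluation metrics for one outcome."""

    outcome: str
    ncv_accuracy: float | None = None
    ncv_roc: float | None = None
    rcv_sensitivity: float | None = None
    rcv_specificity: float | None = None
    chosen_mtry: int | None = None
    importance: dict[str, float] = field(default_factory=dict)
    calibration: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "ncv_accuracy": self.ncv_accuracy,
            "ncv_roc": self.ncv_roc,
            "rcv_sensitivity": self.rcv_sensitivity,
            "rcv_specificity": self.rcv_specificity,
            "chosen_mtry": self.chosen_mtry,
            "importance": self.importance,
            "calibration": [list(pair) for pair in self.calibration],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _as_xy(features: pd.DataFrame, labels) -> tuple[np.ndarray, np.ndarray]:
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(y) != len(X):
        raise ValidationError("features and labels differ in length")
    if np.unique(y).size < 2:
        raise EstimationError("labels contain a single class; nothing to learn")
    if np.isnan(X).any():
        raise ValidationError("feature matrix contains missing values")
    return X, y


def _make_model(mtry: int, config: RFConfig, seed: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "rf",
                RandomForestClassifier(
                    n_estimators=config.n_trees,
                    max_features=mtry,
                    random_state=seed,
                    n_jobs=1,
                ),
            ),
        ]
    )


def _oof_probabilities(X, y, mtry, splitter, config, seed) -> np.ndarray:
    """Out-of-fold P(improved) over all (fold, repeat) test sets, pooled."""
    prob = np.full(len(y), np.nan)
    pooled = []
    for k, (tr, te) in enumerate(splitter.split(X, y)):
        model = _make_model(mtry, config, seed + k)
        model.fit(X[tr], y[tr])
        p = model.predict_proba(X[te])[:, list(model.classes_).index(True)]
        prob = prob.copy()
        prob[te] = p
        if np.all(np.isfinite(prob)):
            pooled.append(prob)
            prob = np.full(len(y), np.nan)
    return np.vstack(pooled) if pooled else prob[None, :]


def _effective_folds(y, requested: int, what: str) -> int:
    smallest = int(min(np.sum(y), np.sum(~y)))
    k = min(requested, smallest)
    if k < requested:
        logger.info("%s: folds reduced from %d to %d (smallest class %d)", what, requested, k, smallest)
    if k < 2:
        raise EstimationError(f"{what}: cannot form >= 2 stratified folds")
    return k


def _sens_spec(y, prob, cutoff) -> tuple[float, float]:
    pred = prob >= cutoff
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def _calibration_curve(y, prob, n_bins: int = 10) -> list[tuple[float, float]]:
    """Fixed-width probability deciles -> (bin midpoint, observed fraction)."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (prob >= lo) & (prob < hi) if hi < 1.0 else (prob >= lo) & (prob <= hi)
        if mask.sum() > 0:
            out.append((float((lo + hi) / 2.0), float(np.mean(y[mask]))))
    return out


def train_rf_rcv(
    features: pd.DataFrame, labels, config: RFConfig, outcome: str = "outcome"
) -> tuple[Pipeline, EvalResult]:
    """Grid-search ``mtry`` by repeated CV ROC; refit and summarize.

    Returns the final model fitted on all data at the chosen ``mtry``
    (predictors scaled and centered) and an :class:`EvalResult` with the
    RCV sensitivity/specificity (from pooled out-of-fold predictions at
    the cutoff), the calibration curve, and 0-100-scaled importances.
    """
    X, y = _as_xy(features, labels)
    grid = [m for m in config.mtry_grid if m <= X.shape[1]]
    if not grid:
        raise ValueError("mtry_grid has no value <= number of features")
    k = _effective_folds(y, config.rcv_folds, "train_rf_rcv")
    seed0 = stage_seed(config.seed, f"rcv:{outcome}")
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=config.rcv_repeats, random_state=seed0)

    best_mtry, best_auc, best_oof = None, -np.inf, None
    for mtry in grid:
        oof = _oof_probabilities(X, y, mtry, splitter, config, stage_seed(seed0, f"m{mtry}"))
        auc = float(np.mean([roc_auc_score(y, row) for row in oof]))
        if auc > best_auc + 1e-12:
            best_mtry, best_auc, best_oof = mtry, auc, oof
    logger.info("train_rf_rcv[%s]: chosen mtry=%d (mean CV ROC %.3f)", outcome, best_mtry, best_auc)

    pooled_prob = best_oof.mean(axis=0)
    sens, spec = _sens_spec(y, pooled_prob, config.classification_cutoff)

    final = _make_model(best_mtry, config, stage_seed(seed0, "final"))
    final.fit(X, y)
    raw_imp = final.named_steps["rf"].feature_importances_
    top = raw_imp.max()
    scaled = 100.0 * raw_imp / top if top > 0 else raw_imp
    result = EvalResult(
        outcome=outcome,
        rcv_sensitivity=sens,
        rcv_specificity=spec,
        chosen_mtry=int(best_mtry),
        importance={name: float(v) for name, v in zip(features.columns, scaled)},
        calibration=_calibration_curve(y, pooled_prob),
    )
    return final, result


def nested_cv(
    features: pd.DataFrame, labels, config: RFConfig, outcome: str = "outcome"
) -> EvalResult:
    """Nested cross-validation: inner folds tune ``mtry``, outer folds
    measure accuracy and ROC on never-touched data."""
    X, y = _as_xy(features, labels)
    grid = [m for m in config.mtry_grid if m <= X.shape[1]]
    k_outer = _effective_folds(y, config.ncv_outer, "nested_cv outer")
    seed0 = stage_seed(config.seed, f"ncv:{outcome}")
    outer = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed0)

    accs, rocs = [], []
    for i, (tr, te) in enumerate(outer.split(X, y)):
        y_tr = y[tr]
        k_inner = _effective_folds(y_tr, config.ncv_inner, "nested_cv inner")
        inner = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=stage_seed(seed0, f"in{i}"))
        best_mtry, best_auc = grid[0], -np.inf
        for mtry in grid:
            probs = np.full(len(y_tr), np.nan)
            for j, (itr, ite) in enumerate(inner.split(X[tr], y_tr)):
                model = _make_model(mtry, config, stage_seed(seed0, f"o{i}m{mtry}f{j}"))
                model.fit(X[tr][itr], y_tr[itr])
                probs[ite] = model.predict_proba(X[tr][ite])[:, list(model.classes_).index(True)]
            auc = roc_auc_score(y_tr, probs)
            if auc > best_auc + 1e-12:
                best_mtry, best_auc = mtry, auc
        model = _make_model(best_mtry, config, stage_seed(seed0, f"o{i}final"))
        model.fit(X[tr], y_tr)
        p = model.predict_proba(X[te])[:, list(model.classes_).index(True)]
        pred = p >= config.classification_cutoff
        accs.append(float(np.mean(pred == y[te])))
        if np.unique(y[te]).size == 2:
            rocs.append(float(roc_auc_score(y[te], p)))
    return EvalResult(
        outcome=outcome,
        ncv_accuracy=float(np.mean(accs)),
        ncv_roc=float(np.mean(rocs)) if rocs else float("nan"),
    )


def outcome_agreement(labels_a, labels_b) -> float:
    """Proportion of participants with identical boolean labels."""
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if len(a) != len(b):
        raise ValidationError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValidationError("label vectors are empty")
    return float(np.mean(a == b))
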