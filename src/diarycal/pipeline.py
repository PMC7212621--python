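"""End-to-end pipeline: generate -> preprocess -> adjust -> validate ->
featurize -> predict, with machine- and human-readable artifacts.

Every stochastic stage derives its own seed from the single pipeline
seed (stage-name hashing), so reruns with the same configuration are
byte-identical while stages stay statistically independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import ConfigurationError, stage_seed
from . import adjust as adj
from . import features as feat
from . import predict as pred
from . import preprocess as prep
from . import trajectory as traj
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "render_report", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ["generate", "preprocess", "adjust", "validate", "featurize", "predict"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "diarycal_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    generator: dict | None = field(default_factory=dict)  # None => read CSVs
    participants_path: str | None = None
    diary_path: str | None = None
    bootstrap_B: int = 5000
    intended_duration_days: int = 70
    max_extra_days: int = 35
    rf: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if self.generator is None and "generate" in self.stages:
            self.stages = [s for s in self.stages if s != "generate"]
        if "generate" not in self.stages and self.generator is not None and not self.generator:
            pass
        if "generate" not in self.stages or self.generator is None:
            if "preprocess" in self.stages and not (self.participants_path and self.diary_path):
                raise ConfigurationError(
                    "generator disabled: participants_path and diary_path are required"
                )
            for p in (self.participants_path, self.diary_path):
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"input file does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**doc)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, default=float) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; write artifacts under ``config.outdir``.

    Returns the report bundle: a dict with one entry per completed stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": config.seed, "stages": list(config.stages)}
    stage = "setup"
    try:
        participants = diary = weeks = weeks_adj = model = None

        if "generate" in config.stages and config.generator is not None:
            stage = "generate"
            gcfg = GeneratorConfig.from_dict(
                {"seed": stage_seed(config.seed, "generator"), **(config.generator or {})}
            )
            participants, diary, latent = generate_cohort(gcfg)
            prep.write_table(participants, outdir / "participants.csv")
            prep.write_table(diary, outdir / "diary.csv")
            prep.write_table(latent, outdir / "latent.csv")
            bundle["generate"] = {
                "n_participants": int(len(participants)),
                "n_diary_entries": int(len(diary)),
                "config": gcfg.to_dict(),
            }
        else:
            stage = "load"
            participants = prep.read_participants(config.participants_path)
            diary = prep.read_diary(config.diary_path)

        if "preprocess" in config.stages:
            stage = "preprocess"
            n0 = len(diary)
            entries = prep.deduplicate(diary)
            n_dedup = len(entries)
            entries = prep.window_entries(entries, participants)
            n_windowed = len(entries)
            weeks = prep.collapse_weeks(entries, participants)
            summary = prep.weekly_summary_stats(weeks)
            prep.write_table(weeks, outdir / "weeks.csv")
            bundle["preprocess"] = {
                "entries_in": n0,
                "entries_after_dedup": n_dedup,
                "entries_after_window": n_windowed,
                "participant_weeks": int(len(weeks)),
                "summary": summary.to_dict(),
            }
            _dump_json(bundle["preprocess"], outdir / "preprocess_summary.json")
            bundle["_entries"] = entries

        if "adjust" in config.stages:
            stage = "adjust"
            entries = bundle["_entries"]
            overlap = adj.find_overlap_subset(entries, participants)
            model = adj.fit_adjustment(overlap)
            model.bootstrap_betas = adj.bootstrap_adjustment(
                overlap, config.bootstrap_B, stage_seed(config.seed, "bootstrap")
            )
            model.bootstrap_seed = stage_seed(config.seed, "bootstrap")
            (outdir / "adjustment.json").write_text(model.to_json() + "\n")
            weeks_adj = adj.apply_adjustment(weeks, model)
            prep.write_table(weeks_adj, outdir / "weeks_adjusted.csv")
            comparisons = adj.compare_subsets(overlap["participant_id"], participants, weeks)
            comp_df = pd.DataFrame(
                [
                    {
                        "variable": e.variable,
                        "mean_overlap": e.group_means[0],
                        "mean_rest": e.group_means[1],
                        "cohens_d": e.cohens_d,
                        "ci_low": e.ci_low,
                        "ci_high": e.ci_high,
                    }
                    for e in comparisons
                ]
            )
            prep.write_table(comp_df, outdir / "subset_comparison.csv")
            bundle["adjust"] = {
                "overlap_n": int(len(overlap)),
                "overlap_entries": int(overlap["n_entries"].sum()) if len(overlap) else 0,
                "beta_missing": model.beta_missing,
                "beta_drinks": model.beta_drinks,
                "intercept": model.intercept,
                "beta_drinks_ci95": list(model.percentile_interval("beta_drinks")),
                "beta_missing_ci95": list(model.percentile_interval("beta_missing")),
            }

        if "validate" in config.stages:
            stage = "validate"
            report = traj.validate(weeks_adj, participants, model)
            (outdir / "validation.json").write_text(report.to_json() + "\n")
            (outdir / "validation.txt").write_text(report.to_text() + "\n")
            bundle["validate"] = report.to_dict()

        if "featurize" in config.stages:
            stage = "featurize"
            entries = bundle["_entries"]
            fh = feat.first_half_filter(
                entries,
                participants,
                intended_duration_days=config.intended_duration_days,
                max_extra_days=config.max_extra_days,
            )
            X = feat.build_feature_matrix(fh, participants)
            labels = feat.define_outcomes(participants).set_index("participant_id")
            labels = labels.loc[labels.index.intersection(X.index)]
            X = X.loc[labels.index]
            prep.write_table(X.reset_index(), outdir / "features.csv")
            prep.write_table(labels.reset_index(), outdir / "labels.csv")
            bundle["featurize"] = {
                "n_participants": int(len(X)),
                "k_first_half_entries": int(len(fh)),
                "n_features": int(X.shape[1]),
            }
            bundle["_X"] = X
            bundle["_labels"] = labels

        if "predict" in config.stages:
            stage = "predict"
            X, labels = bundle["_X"], bundle["_labels"]
            rf_cfg = pred.RFConfig(seed=stage_seed(config.seed, "predict"), **config.rf)
            results = {}
            for outcome in ("non_hazardous", "audit_improved"):
                y = labels[outcome].to_numpy()
                _, rcv = pred.train_rf_rcv(X, y, rf_cfg, outcome=outcome)
                ncv = pred.nested_cv(X, y, rf_cfg, outcome=outcome)
                rcv.ncv_accuracy, rcv.ncv_roc = ncv.ncv_accuracy, ncv.ncv_roc
                results[outcome] = rcv.to_dict()
                (outdir / f"prediction_{outcome}.json").write_text(rcv.to_json() + "\n")
                imp = pd.DataFrame(
                    sorted(rcv.importance.items(), key=lambda kv: -kv[1]),
                    columns=["feature", "importance"],
                )
                prep.write_table(imp, outdir / f"importance_{outcome}.csv")
            agreement = pred.outcome_agreement(
                labels["non_hazardous"].to_numpy(), labels["audit_improved"].to_numpy()
            )
            bundle["predict"] = {"results": results, "outcome_agreement": agreement}
            _dump_json(bundle["predict"], outdir / "prediction_summary.json")

    except Exception as exc:  # noqa: BLE001 - re-raise tagged with the stage
        raise PipelineError(stage, exc) from exc

    bundle = {k: v for k, v in bundle.items() if not k.startswith("_")}
    (outdir / "report.txt").write_text(render_report(bundle) + "\n")
    _dump_json(bundle, outdir / "bundle.json")
    return bundle


def _fmt(x, nd=2) -> str:
    return "n/a" if x is None else f"{x:.{nd}f}"


def render_report(bundle: dict) -> str:
    """One-page human-readable summary of a report bundle."""
    if not bundle or not any(k in bundle for k in ALL_STAGES):
        raise ValueError(f"empty bundle: expected sections among {ALL_STAGES}")
    lines = ["diarycal pipeline report", "========================", f"seed: {bundle.get('seed')}"]

    if "generate" in bundle:
        g = bundle["generate"]
        lines.append(f"cohort: {g['n_participants']} participants, {g['n_diary_entries']} raw diary entries")
    if "preprocess" in bundle:
        p = bundle["preprocess"]
        s = p["summary"]
        lines.append(
            f"preprocess: {p['entries_after_dedup']} entries after dedup, "
            f"{p['entries_after_window']} in window, {p['participant_weeks']} participant-weeks "
            f"(M = {s['mean_weeks']:.2f}, SD = {s['sd_weeks']:.2f} weeks/participant)"
        )
    if "adjust" in bundle:
        a = bundle["adjust"]
        lines.append(
            f"adjustment (overlap n = {a['overlap_n']}, k = {a['overlap_entries']} entries): "
            f"{a['beta_missing']:.3f} drinks per missing day, "
            f"{a['beta_drinks']:.3f} drinks per reported drink"
        )
    if "validate" in bundle:
        v = bundle["validate"]
        for key in ("raw", "adjusted"):
            fit = v[f"{key}_fit"]
            lines.append(
                f"{key} end-point: B = {fit['endpoint_B']:.2f} (SE = {fit['endpoint_SE']:.2f})"
                f" -> {v[f'{key}_verdict']}"
            )
        fu = v["followup"]
        lines.append(f"follow-up TLFB mean: {fu['point']:.2f} [{fu['ci_low']:.2f}, {fu['ci_high']:.2f}]")
    else:
        lines.append("validation: not run")

    if "predict" in bundle:
        pr = bundle["predict"]
        lines.append(f"outcome agreement: {100 * pr['outcome_agreement']:.0f}%")
        for outcome, res in pr["results"].items():
            lines.append(
                f"{outcome}: NCV accuracy {_fmt(res['ncv_accuracy'])}, NCV ROC {_fmt(res['ncv_roc'])}, "
                f"RCV sensitivity {_fmt(res['rcv_sensitivity'])}, RCV specificity {_fmt(res['rcv_specificity'])}"
            )
            top5 = sorted(res["importance"].items(), key=lambda kv: -kv[1])[:5]
            lines.append("  top importance: " + ", ".join(f"{k}={v:.0f}" for k, v in top5))
    else:
        lines.append("prediction: not run")
    return "\n".join(lines)
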