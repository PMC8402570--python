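"""End-to-end orchestration: simulate -> score -> label -> features ->
cross-validate -> report.

Every stage draws from a generator seeded by ``(run seed, stage offset)``,
so a run is reproducible from its seed alone, and each artifact directory
carries a JSON summary with a hash of the full configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vigil.config import (
    AEConfig,
    BandDef,
    MLPConfig,
    SimConfig,
    TCNConfig,
    TaskSpec,
    desk_scale_config,
)
from vigil.cv import CVResult, fold_accounting, make_folds, run_cv
from vigil.data import EpochSet, write_dataset
from vigil.scoring import label_epochs, score_trials, trends_table
from vigil.synthetic import participant_ids, simulate_behavior, simulate_eeg


@dataclass
class RunConfig:
    """One pipeline run: a simulation configuration, a model family and a
    master seed."""

    sim: SimConfig
    model_kind: str = "mlpnn"
    model_config: object | None = None
    seed: int = 0
    #: generate EEG for labeled trials only (bins 1 and 4); the middle
    #: bins never reach training or validation, so this saves half the
    #: synthesis work without changing any result
    labeled_only: bool = True


class ConfigError(ValueError):
    """A run configuration file fails validation before any compute."""


_MODEL_CONFIGS = {"mlpnn": MLPConfig, "tcn": TCNConfig, "tcn_ae": AEConfig}


def load_run_config(path) -> RunConfig:
    """Parse a YAML run configuration.

    Expected keys: ``seed`` (int), ``model_kind`` (mlpnn/tcn/tcn_ae),
    ``model`` (mapping of that model's config fields; required, may be
    empty for defaults), ``sim`` (mapping of :class:`SimConfig` fields;
    ``tasks`` as lists of task fields), ``labeled_only`` (bool).
    Validation happens here, before any compute.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"run config {path} is not a mapping")
    kind = raw.get("model_kind", "mlpnn")
    if kind not in _MODEL_CONFIGS:
        raise ConfigError(f"unknown model_kind {kind!r}")
    if "model" not in raw:
        raise ConfigError("run config is missing the 'model' section")
    model_raw = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in (raw["model"] or {}).items()
    }
    try:
        model_config = _MODEL_CONFIGS[kind](**model_raw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid 'model' section: {e}") from None

    sim_raw = dict(raw.get("sim") or {})
    if "tasks" in sim_raw:
        sim_raw["tasks"] = tuple(
            TaskSpec(**{**t, "iti_range_s": tuple(t.get("iti_range_s", (2.0, 2.0)))})
            for t in sim_raw["tasks"]
        )
    if "bands" in sim_raw:
        sim_raw["bands"] = tuple(BandDef(**b) for b in sim_raw["bands"])
    try:
        sim = SimConfig(**sim_raw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid 'sim' section: {e}") from None
    seed = int(raw.get("seed", sim.seed))
    return RunConfig(
        sim=sim.replace(seed=seed),
        model_kind=kind,
        model_config=model_config,
        seed=seed,
        labeled_only=bool(raw.get("labeled_only", True)),
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(run_cfg: RunConfig) -> str:
    """Stable short hash of the full run configuration."""
    payload = json.dumps(
        {
            "sim": _jsonable(run_cfg.sim),
            "model_kind": run_cfg.model_kind,
            "model_config": _jsonable(run_cfg.model_config),
            "seed": run_cfg.seed,
            "labeled_only": run_cfg.labeled_only,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages

def simulate_stage(
    run_cfg: RunConfig,
) -> tuple[pd.DataFrame, EpochSet]:
    """Behavior + EEG + labels for one run. With ``labeled_only`` the
    EEG array covers only the epochs of bins 1 and 4."""
    cfg = run_cfg.sim.replace(seed=run_cfg.seed)
    trials = simulate_behavior(cfg)
    if run_cfg.labeled_only:
        from vigil.scoring import bin_assignments

        per_task = {t.name: bin_assignments(t.n_trials, 4) for t in cfg.tasks}
        bins = np.array(
            [
                per_task[t][i]
                for t, i in zip(trials["task_id"], trials["trial_index"])
            ]
        )
        mask = np.isin(bins, [1, 4])
    else:
        mask = None
    epochs = simulate_eeg(cfg, trials, trial_mask=mask)
    return trials, label_epochs(epochs)


def run_pipeline(run_cfg: RunConfig, out_dir=None) -> dict:
    """Run the full analysis and return a results dictionary.

    With ``out_dir`` the behavioral score table, per-participant trend
    table, per-participant accuracy table and a JSON summary (with config
    hash) are written there.
    """
    cfg = run_cfg.sim.replace(seed=run_cfg.seed)
    trials, epochs = simulate_stage(run_cfg)
    scores = score_trials(trials)
    trends = trends_table(scores)
    cv_result = run_cv(
        cfg,
        epochs,
        model_kind=run_cfg.model_kind,
        model_config=run_cfg.model_config,
        seed=run_cfg.seed,
    )
    folds = make_folds(participant_ids(cfg, 1), run_cfg.seed)
    accounting = fold_accounting(cfg, folds[0])

    summary = {
        "config_hash": config_hash(run_cfg),
        "seed": run_cfg.seed,
        "model_kind": run_cfg.model_kind,
        "n_folds": len(folds),
        "fold_accounting": accounting,
        "pooled_accuracy": cv_result.pooled_accuracy,
        "pooled_balanced_accuracy": cv_result.pooled_balanced_accuracy,
        "pooled_auroc": cv_result.pooled_auroc,
        "pooled_ci": list(cv_result.pooled_ci),
        "pooled_n": cv_result.pooled_n,
        "fraction_negative_bis_slope": float(
            (trends["slope"] < 0).mean()
        ),
    }
    result = {
        "trials": trials,
        "epochs": epochs,
        "scores": scores,
        "trends": trends,
        "cv": cv_result,
        "summary": summary,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        h = summary["config_hash"]
        scores.assign(config_hash=h).to_csv(
            out / "bin_scores.csv", index=False
        )
        trends.assign(config_hash=h).to_csv(out / "trends.csv", index=False)
        cv_result.participant_table.assign(config_hash=h).to_csv(
            out / "accuracy_table.csv", index=False
        )
        pred = pd.DataFrame(
            {
                "participant_id": np.concatenate(
                    [f.val_participants for f in cv_result.folds]
                ),
                "y_true": cv_result.y_true,
                "y_pred": cv_result.y_pred,
                "score": cv_result.scores,
            }
        )
        pred.assign(config_hash=h).to_csv(
            out / "predictions.csv", index=False
        )
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return result


def desk_scale_run(
    seed: int,
    model_kind: str = "mlpnn",
    model_config=None,
    alpha_fatigue_gain: float | None = None,
    out_dir=None,
) -> dict:
    """One pipeline run at the reduced desk scale (single-CPU sized)."""
    overrides = {}
    if alpha_fatigue_gain is not None:
        overrides["alpha_fatigue_gain"] = alpha_fatigue_gain
    sim = desk_scale_config(seed=seed, **overrides)
    run_cfg = RunConfig(
        sim=sim, model_kind=model_kind, model_config=model_config, seed=seed
    )
    return run_pipeline(run_cfg, out_dir=out_dir)


def write_simulated_dataset(run_cfg: RunConfig, out_dir) -> Path:
    """Simulate and persist a dataset (trials + labeled epochs)."""
    trials, epochs = simulate_stage(run_cfg)
    return write_dataset(trials, epochs, out_dir)
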