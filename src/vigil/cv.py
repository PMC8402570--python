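"""Leave-2-participants-out cross-task cross-validation.

The experiment-1 pool (14 participants by default) is partitioned into
disjoint validation pairs, one fold per pair. Each fold trains on the
remaining experiment-1 participants' ATC epochs plus every experiment-2
participant's line-task epochs, and validates on the held-out pair's
oddball epochs -- so the validation task is never seen in training and the
validation participants contribute no epochs to training. Feature
standardization is fitted on the fold's training epochs only.

At full scale this accounting gives 53,600 labeled training epochs and 360
labeled validation epochs per fold (12 x 800 ATC + 26 x 1,600 + 3 x 800
line; 2 x 180 oddball).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from vigil.config import AEConfig, MLPConfig, SimConfig, TCNConfig
from vigil.data import LABEL_UNLABELED, EpochSet
from vigil.scoring import bin_sizes
from vigil.spectral import morlet_band_power, log_and_standardize
from vigil.stats import agresti_coull_ci, report_table
from vigil.synthetic import _sessions_for, participant_ids
from vigil import models as M

TRAIN_TASKS = ("atc", "line")
VAL_TASK = "oddball"


class CVError(ValueError):
    pass


# ---------------------------------------------------------------------------
# folds

@dataclass(frozen=True)
class FoldSpec:
    fold_index: int
    val_pair: tuple[str, str]
    train_participants: tuple[str, ...]


def make_folds(ids: list[str], seed: int = 0) -> list[FoldSpec]:
    """Seeded random partition of an even participant pool into disjoint
    validation pairs; every participant is validated on exactly once."""
    ids = list(ids)
    if len(ids) < 4 or len(ids) % 2:
        raise CVError(
            f"need an even pool of >= 4 participants, got {len(ids)}"
        )
    rng = np.random.default_rng([seed, 30])
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds = []
    for j in range(0, len(order), 2):
        pair = (order[j], order[j + 1])
        train = tuple(sorted(set(ids) - set(pair)))
        folds.append(FoldSpec(j // 2, tuple(sorted(pair)), train))
    return folds


# ---------------------------------------------------------------------------
# epoch accounting (no EEG required)

def labeled_per_session(n_trials: int) -> int:
    """Labeled epochs in one session: bins 1 and 4 of the four-bin split."""
    sizes = bin_sizes(n_trials, 4)
    return sizes[0] + sizes[-1]


def fold_accounting(cfg: SimConfig, fold: FoldSpec) -> dict[str, int]:
    """Labeled train/validation epoch counts of one fold, from the
    configuration alone."""
    atc = cfg.task("atc")
    line = cfg.task("line")
    odd = cfg.task(VAL_TASK)
    n_train = len(fold.train_participants) * labeled_per_session(atc.n_trials)
    pool2 = participant_ids(cfg, 2)
    for rank in range(len(pool2)):
        n_sess = _sessions_for(cfg, line, rank, len(pool2))
        n_train += n_sess * labeled_per_session(line.n_trials)
    n_val = len(fold.val_pair) * labeled_per_session(odd.n_trials)
    return {"n_train": n_train, "n_val": n_val}


# ---------------------------------------------------------------------------
# metrics

def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class recalls."""
    return float(skm.balanced_accuracy_score(y_true, y_pred))


def auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve of continuous scores."""
    return float(skm.roc_auc_score(y_true, scores))


# ---------------------------------------------------------------------------
# running the CV

@dataclass
class FoldResult:
    spec: FoldSpec
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    val_participants: np.ndarray
    n_train: int
    history: list[float] = field(default_factory=list)


@dataclass
class CVResult:
    model_kind: str
    folds: list[FoldResult]
    participant_table: pd.DataFrame
    pooled_accuracy: float
    pooled_balanced_accuracy: float
    pooled_auroc: float
    pooled_ci: tuple[float, float]
    pooled_n: int

    @property
    def y_true(self) -> np.ndarray:
        return np.concatenate([f.y_true for f in self.folds])

    @property
    def y_pred(self) -> np.ndarray:
        return np.concatenate([f.y_pred for f in self.folds])

    @property
    def scores(self) -> np.ndarray:
        return np.concatenate([f.scores for f in self.folds])


def _experiment_of(pid: str) -> int:
    return int(pid.split("_")[0][1:])


def _fold_masks(
    meta: pd.DataFrame, fold: FoldSpec
) -> tuple[np.ndarray, np.ndarray]:
    pids = meta["participant_id"].to_numpy()
    tasks = meta["task_id"].to_numpy()
    labeled = meta["label"].to_numpy() != LABEL_UNLABELED
    in_pair = np.isin(pids, list(fold.val_pair))
    train = labeled & (
        ((tasks == "atc") & np.isin(pids, list(fold.train_participants)))
        | (tasks == "line")
    )
    val = labeled & (tasks == VAL_TASK) & in_pair
    # leakage aborts: validation participants and task must be absent from
    # the training selection, and no epoch may appear on both sides
    if np.any(train & in_pair):
        raise CVError(
            f"fold {fold.fold_index}: validation participants appear in "
            "training epochs"
        )
    if np.any(tasks[train] == VAL_TASK):
        raise CVError(
            f"fold {fold.fold_index}: validation task present in training"
        )
    if np.any(train & val):
        raise CVError(f"fold {fold.fold_index}: train/val epochs overlap")
    return train, val


def _train_and_score(
    model_kind: str,
    model_config,
    epochs: EpochSet,
    raw_features,
    train: np.ndarray,
    val: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    y = epochs.meta["label"].to_numpy()
    if model_kind == "mlpnn":
        feats = log_and_standardize(raw_features, fit_on=train)
        X = feats.values.astype(np.float32)
        model = M.build_mlpnn(
            model_config, n_features=X.shape[1], seed=seed
        )
        model.transform = feats.transform
        M.train_classifier(model, X[train], y[train], seed=seed)
        scores = M.predict_proba(model, X[val])
        return scores, (scores >= 0.5).astype(int), model.history
    if model_kind == "tcn":
        state = M.fit_channel_state(epochs.data[train])
        model = M.build_tcn(
            model_config,
            n_channels=epochs.n_channels,
            seq_len=epochs.n_samples,
            seed=seed,
            rf_cap=epochs.n_samples,
        )
        Xtr = M.standardize_by_channel(epochs.data[train], state)
        M.train_classifier(model, Xtr, y[train], seed=seed)
        Xv = M.standardize_by_channel(epochs.data[val], state)
        scores = M.predict_proba(model, Xv)
        return scores, (scores >= 0.5).astype(int), model.history
    if model_kind == "tcn_ae":
        state = M.fit_channel_state(epochs.data[train])
        ae = M.build_tcn_ae(
            model_config,
            n_channels=epochs.n_channels,
            seq_len=epochs.n_samples,
            seed=seed,
        )
        ae.channel_state = state
        Xtr = M.standardize_by_channel(epochs.data[train], state)
        M.train_autoencoder(ae, Xtr, seed=seed)
        M.train_latent_classifier(ae, Xtr, y[train], seed=seed)
        Xv = M.standardize_by_channel(epochs.data[val], state)
        scores = M.predict_proba(ae, Xv)
        return scores, (scores >= 0.5).astype(int), ae.clf_history
    raise CVError(f"unknown model kind {model_kind!r}")


_DEFAULT_CONFIGS = {
    "mlpnn": MLPConfig,
    "tcn": TCNConfig,
    "tcn_ae": AEConfig,
}


def run_cv(
    cfg: SimConfig,
    epochs: EpochSet,
    model_kind: str = "mlpnn",
    model_config=None,
    seed: int = 0,
    folds: list[FoldSpec] | None = None,
) -> CVResult:
    """Run the leave-2-out cross-task CV on a labeled epoch set.

    ``epochs`` must carry labels (see :func:`vigil.scoring.label_epochs`)
    for all three tasks. Per fold, feature standardization (spectral
    z-scoring for the MLPNN, channel standardization for the raw-sequence
    models) is fitted on that fold's training epochs only.
    """
    if model_kind not in _DEFAULT_CONFIGS:
        raise CVError(f"unknown model kind {model_kind!r}")
    if model_config is None:
        model_config = _DEFAULT_CONFIGS[model_kind]()
    if folds is None:
        folds = make_folds(participant_ids(cfg, 1), seed)

    raw_features = None
    if model_kind == "mlpnn":
        raw_features = morlet_band_power(epochs, bands=cfg.bands)

    fold_results: list[FoldResult] = []
    for fold in folds:
        train, val = _fold_masks(epochs.meta, fold)
        if train.sum() == 0 or val.sum() == 0:
            raise CVError(
                f"fold {fold.fold_index}: empty train or validation set"
            )
        scores, y_pred, history = _train_and_score(
            model_kind, model_config, epochs, raw_features, train, val,
            seed=seed,
        )
        fold_results.append(
            FoldResult(
                spec=fold,
                y_true=epochs.meta["label"].to_numpy()[val],
                y_pred=y_pred,
                scores=scores,
                val_participants=epochs.meta["participant_id"].to_numpy()[val],
                n_train=int(train.sum()),
                history=history,
            )
        )

    return summarize_cv(model_kind, fold_results)


def summarize_cv(model_kind: str, fold_results: list[FoldResult]) -> CVResult:
    """Pool fold predictions and build the per-participant accuracy table."""
    y = np.concatenate([f.y_true for f in fold_results])
    yhat = np.concatenate([f.y_pred for f in fold_results])
    s = np.concatenate([f.scores for f in fold_results])
    pids = np.concatenate([f.val_participants for f in fold_results])

    rows = [
        dict(model=model_kind, unit="pooled",
             correct=int((y == yhat).sum()), n=len(y))
    ]
    for pid in sorted(set(pids)):
        m = pids == pid
        rows.append(
            dict(model=model_kind, unit=pid,
                 correct=int((y[m] == yhat[m]).sum()), n=int(m.sum()))
        )
    table = report_table(rows)

    ci = agresti_coull_ci(int((y == yhat).sum()), len(y))
    return CVResult(
        model_kind=model_kind,
        folds=fold_results,
        participant_table=table,
        pooled_accuracy=float((y == yhat).mean()),
        pooled_balanced_accuracy=balanced_accuracy(y, yhat),
        pooled_auroc=auroc(y, s),
        pooled_ci=(ci.lo, ci.hi),
        pooled_n=len(y),
    )
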