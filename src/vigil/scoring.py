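"""Behavioral performance scoring with the Balanced Integration Score (BIS).

Per participant and task, a session's trials are divided into four
contiguous time bins. Each bin gets a proportion correct (PC), a mean
correct response time (RT), z-scores of both across the bins, and

    BIS = z(PC) - z(RT)

so that fast, accurate bins score high. A least-squares slope of BIS over
bins summarizes the session: a negative slope is a vigilance decrement.
Epoch labels are derived from the first bin (attentive, 0) and the fourth
bin (decrement, 1); the middle bins stay unlabeled, which yields a
class-balanced labeled set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from vigil.data import (
    LABEL_ATTENTIVE,
    LABEL_DECREMENT,
    LABEL_UNLABELED,
    EpochSet,
)

N_BINS_DEFAULT = 4


class ScoringError(ValueError):
    pass


class ZeroVarianceWarning(UserWarning):
    """PC or RT is constant across bins; the corresponding z-term is set to 0."""


# ---------------------------------------------------------------------------
# binning

def bin_sizes(n_trials: int, n_bins: int = N_BINS_DEFAULT) -> list[int]:
    """Sizes of contiguous near-equal bins; the remainder goes to the
    earliest bins. ``sum(bin_sizes(n, k)) == n`` and sizes differ by <= 1."""
    if n_bins < 2:
        raise ScoringError(f"n_bins must be >= 2, got {n_bins}")
    if n_trials < n_bins:
        raise ScoringError(
            f"cannot divide {n_trials} trials into {n_bins} bins"
        )
    q, r = divmod(n_trials, n_bins)
    return [q + (1 if i < r else 0) for i in range(n_bins)]


def bin_assignments(n_trials: int, n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """1-based bin index for each of ``n_trials`` trials in order."""
    sizes = bin_sizes(n_trials, n_bins)
    return np.repeat(np.arange(1, n_bins + 1), sizes)


def bin_trials(trials: pd.DataFrame, n_bins: int = N_BINS_DEFAULT) -> list[pd.DataFrame]:
    """Split one participant-task-session trial log (sorted by trial_index)
    into ``n_bins`` contiguous, order-preserving groups."""
    trials = trials.sort_values("trial_index", kind="stable")
    sizes = bin_sizes(len(trials), n_bins)
    out, start = [], 0
    for s in sizes:
        out.append(trials.iloc[start : start + s])
        start += s
    return out


# ---------------------------------------------------------------------------
# per-bin scoring

def accuracy(hits: int, false_alarms: int, misses: int, correct_rejections: int) -> float:
    """(hits + correct rejections) / all trials."""
    counts = (hits, false_alarms, misses, correct_rejections)
    if any(c < 0 for c in counts):
        raise ScoringError("outcome counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ScoringError("accuracy is undefined for zero trials")
    return (hits + correct_rejections) / total


def _zscores(values: np.ndarray, what: str) -> np.ndarray:
    """Sample-SD (ddof=1) z-scores across bins; all-zero when constant."""
    mean = np.nanmean(values)
    sd = np.nanstd(values, ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        warnings.warn(
            f"{what} is constant across bins; its z-scores are set to 0",
            ZeroVarianceWarning,
            stacklevel=3,
        )
        return np.zeros_like(values)
    return (values - mean) / sd


@dataclass
class BinPerformance:
    participant_id: str
    task_id: str
    session_id: int
    bin_index: int
    n_trials: int
    pc: float
    rt: float
    zpc: float
    zrt: float
    bis: float


def bin_performance(
    groups: list[pd.DataFrame],
    participant_id: str = "",
    task_id: str = "",
    session_id: int = 0,
) -> list[BinPerformance]:
    """Score the bins of one participant-task-session.

    PC is go/no-go accuracy per bin; RT is the mean response time over
    correct responses (hits) in the bin; z-scores are taken across the bins
    of this session (per-individual standardization) with sample SD; and
    BIS = z(PC) - z(RT). A bin with no correct responses gets RT = NaN and
    is warned about; constant PC or RT across bins zeroes that z-term.
    """
    if not groups:
        raise ScoringError("no bins given")
    pcs, rts, ns = [], [], []
    for g in groups:
        counts = g["outcome"].value_counts()
        pc = accuracy(
            int(counts.get("hit", 0)),
            int(counts.get("false_alarm", 0)),
            int(counts.get("miss", 0)),
            int(counts.get("correct_rejection", 0)),
        )
        hit_rts = g.loc[g["outcome"] == "hit", "rt"].to_numpy(dtype=float)
        if hit_rts.size == 0:
            warnings.warn(
                f"bin with no correct responses for {participant_id}/{task_id}; "
                "RT undefined (NaN)",
                ZeroVarianceWarning,
                stacklevel=2,
            )
            rt = np.nan
        else:
            rt = float(np.mean(hit_rts))
        pcs.append(pc)
        rts.append(rt)
        ns.append(len(g))
    pcs_arr = np.asarray(pcs, dtype=float)
    rts_arr = np.asarray(rts, dtype=float)
    zpc = _zscores(pcs_arr, "PC")
    zrt = _zscores(rts_arr, "RT")
    bis = zpc - zrt
    return [
        BinPerformance(
            participant_id, task_id, session_id, j + 1, ns[j],
            float(pcs_arr[j]), float(rts_arr[j]),
            float(zpc[j]), float(zrt[j]), float(bis[j]),
        )
        for j in range(len(groups))
    ]


def score_trials(
    trials: pd.DataFrame, n_bins: int = N_BINS_DEFAULT
) -> pd.DataFrame:
    """Score every participant-task-session in a trial log.

    Returns a tidy frame with one row per (participant, task, session, bin)
    carrying PC, RT, z-scores and BIS.
    """
    rows = []
    for (pid, task, sess), g in trials.groupby(
        ["participant_id", "task_id", "session_id"], sort=True
    ):
        groups = bin_trials(g, n_bins)
        rows.extend(bin_performance(groups, str(pid), str(task), int(sess)))
    return pd.DataFrame([vars(r) for r in rows])


def group_standardized_bis(bins: pd.DataFrame) -> pd.DataFrame:
    """Group-level alternative: z-score PC and RT across *participants*
    within each (task, session, bin) cell rather than within individuals."""
    out = bins.copy()
    for (_, _, _), idx in out.groupby(["task_id", "session_id", "bin_index"]).groups.items():
        sub = out.loc[idx]
        out.loc[idx, "zpc"] = _zscores(sub["pc"].to_numpy(), "PC")
        out.loc[idx, "zrt"] = _zscores(sub["rt"].to_numpy(), "RT")
    out["bis"] = out["zpc"] - out["zrt"]
    return out


# ---------------------------------------------------------------------------
# trends

@dataclass
class ParticipantTrend:
    participant_id: str
    task_id: str
    session_id: int
    bis_by_bin: tuple[float, ...]
    slope: float
    bis_diff_1_4: float


def participant_trend(bps: list[BinPerformance]) -> ParticipantTrend:
    """Ordinary least-squares slope of BIS over bin index, and the
    first-minus-last BIS difference."""
    if len(bps) < 2:
        raise ScoringError("need at least 2 bins for a trend")
    bps = sorted(bps, key=lambda b: b.bin_index)
    x = np.array([b.bin_index for b in bps], dtype=float)
    y = np.array([b.bis for b in bps], dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise ScoringError("need at least 2 finite BIS values for a trend")
    slope = float(np.polyfit(x[ok], y[ok], 1)[0])
    return ParticipantTrend(
        bps[0].participant_id,
        bps[0].task_id,
        bps[0].session_id,
        tuple(y),
        slope,
        float(y[0] - y[-1]),
    )


def trends_table(bins: pd.DataFrame) -> pd.DataFrame:
    """Per participant-task-session BIS slope and first-last difference."""
    rows = []
    for (pid, task, sess), g in bins.groupby(
        ["participant_id", "task_id", "session_id"], sort=True
    ):
        bps = [
            BinPerformance(str(pid), str(task), int(sess), int(r.bin_index),
                           int(r.n_trials), r.pc, r.rt, r.zpc, r.zrt, r.bis)
            for r in g.itertuples()
        ]
        t = participant_trend(bps)
        rows.append(
            dict(
                participant_id=t.participant_id,
                task_id=t.task_id,
                session_id=t.session_id,
                slope=t.slope,
                bis_diff_1_4=t.bis_diff_1_4,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# labeling

def label_epochs(epochs: EpochSet, n_bins: int = N_BINS_DEFAULT) -> EpochSet:
    """Label epochs: bin 1 -> attentive (0), bin 4 -> decrement (1),
    bins 2-3 -> unlabeled. Defined only for four-bin scoring."""
    if n_bins != 4:
        raise ScoringError(
            "attentive/decrement labeling is defined for 4 bins only"
        )
    meta = epochs.meta.copy()
    if "bin_index" not in meta.columns or meta["bin_index"].isna().any():
        raise ScoringError("epochs are missing bin assignments")
    b = meta["bin_index"].to_numpy()
    label = np.full(len(meta), LABEL_UNLABELED, dtype=int)
    label[b == 1] = LABEL_ATTENTIVE
    label[b == 4] = LABEL_DECREMENT
    meta["label"] = label
    return EpochSet(epochs.data, meta, epochs.fs, epochs.channel_names)


# ---------------------------------------------------------------------------
# trend vs model-accuracy correlation

def correlate_trend_with_accuracy(
    trend_values: np.ndarray, accuracies: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (rho, two-sided p) between a per-participant
    behavioral trend statistic and per-participant validation accuracy."""
    trend_values = np.asarray(trend_values, dtype=float)
    accuracies = np.asarray(accuracies, dtype=float)
    if trend_values.shape != accuracies.shape or trend_values.size < 4:
        raise ScoringError("need paired values for at least 4 participants")
    if np.ptp(trend_values) == 0 or np.ptp(accuracies) == 0:
        raise ScoringError("correlation is undefined for a constant vector")
    r = sps.pearsonr(trend_values, accuracies)
    return float(r.statistic), float(r.pvalue)
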