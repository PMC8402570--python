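"""Seeded generator of behavioral trial logs and epoched EEG.

The generator emulates the two source experiments the analysis is built
for: an experiment-1 pool performing the air-traffic-controller (ATC) task
and a 3-stimulus oddball task, and an experiment-2 pool performing a line
discrimination task over one or two sessions.

Behavior
--------
Per session, expected accuracy declines and mean response time rises
linearly over the four time bins (``pc_start + b * pc_slope``,
``rt_start_s + b * rt_slope_s``), with per-participant jitter on all four
trajectory parameters. Critical events occur at the configured fraction.

EEG
---
Each 1 s epoch is a sum over the five clinical bands of band-limited
processes with controlled variance, plus white broadband noise. A band's
process is synthesized in the frequency domain as equal-power random-phase
harmonics on the 1 Hz bin grid inside the band (half-open ``[f_lo, f_hi)``),
which makes the per-band time-domain variance exact -- every band power has
a closed form usable as a test oracle. The alpha-band variance is scaled by
``1 + delta * f`` where ``f`` is the trial's elapsed fraction of its
session and ``delta = alpha_fatigue_gain``, emulating the rise of alpha
power with accumulating mental fatigue. Per-participant channel gains
(log-normal) and per-task band offsets (log-normal) add individual and task
differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from vigil.config import SimConfig, TaskSpec
from vigil.data import LABEL_UNLABELED, EpochSet, TRIAL_COLUMNS
from vigil.scoring import bin_assignments

_CHUNK = 256


# ---------------------------------------------------------------------------
# participant rosters

def participant_ids(cfg: SimConfig, experiment: int) -> list[str]:
    n = cfg.n_participants_exp1 if experiment == 1 else cfg.n_participants_exp2
    return [f"e{experiment}_{i:02d}" for i in range(n)]


def _sessions_for(cfg: SimConfig, task: TaskSpec, pid_rank: int, n_pool: int) -> int:
    """Experiment-2 participants at the end of the roster may lack the
    second session of a multi-session task."""
    if task.n_sessions > 1 and task.experiment == 2:
        if pid_rank >= n_pool - cfg.n_exp2_single_session:
            return task.n_sessions - 1
    return task.n_sessions


# ---------------------------------------------------------------------------
# behavior

def simulate_behavior(cfg: SimConfig) -> pd.DataFrame:
    """Generate the full behavioral trial log for every participant, task
    and session of ``cfg``. Deterministic under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    frames: list[pd.DataFrame] = []
    jitter: dict[str, tuple[float, float, float, float]] = {}

    for exp in (1, 2):
        for pid in participant_ids(cfg, exp):
            jitter[pid] = (
                rng.normal(0.0, cfg.pc_start_jitter_sd),
                rng.normal(0.0, cfg.pc_slope_jitter_sd),
                rng.normal(0.0, cfg.rt_start_jitter_sd),
                rng.normal(0.0, cfg.rt_slope_jitter_sd),
            )

    for task in cfg.tasks:
        pool = participant_ids(cfg, task.experiment)
        for rank, pid in enumerate(pool):
            d_pc0, d_pc1, d_rt0, d_rt1 = jitter[pid]
            for sess in range(1, _sessions_for(cfg, task, rank, len(pool)) + 1):
                frames.append(
                    _simulate_session(cfg, task, pid, sess,
                                      d_pc0, d_pc1, d_rt0, d_rt1, rng)
                )
    trials = pd.concat(frames, ignore_index=True)
    return trials[TRIAL_COLUMNS]


def _simulate_session(cfg, task, pid, sess, d_pc0, d_pc1, d_rt0, d_rt1, rng):
    n = task.n_trials
    bins = bin_assignments(n, 4)  # 1-based
    p_correct = np.clip(
        (cfg.pc_start + d_pc0) + (cfg.pc_slope + d_pc1) * (bins - 1), 0.0, 1.0
    )
    rt_mean = np.maximum(
        (cfg.rt_start_s + d_rt0) + (cfg.rt_slope_s + d_rt1) * (bins - 1), 0.05
    )
    is_critical = rng.random(n) < task.critical_fraction
    correct = rng.random(n) < p_correct
    responded = np.where(is_critical, correct, ~correct)
    rt = np.maximum(rng.normal(rt_mean, cfg.rt_trial_sd), 0.05)
    rt = np.where(responded, rt, np.nan)

    outcome = np.select(
        [
            is_critical & correct,
            is_critical & ~correct,
            ~is_critical & correct,
        ],
        ["hit", "miss", "correct_rejection"],
        default="false_alarm",
    )
    iti = rng.uniform(task.iti_range_s[0], task.iti_range_s[1], n)
    t_stim = np.concatenate([[0.0], np.cumsum(iti[:-1])])
    return pd.DataFrame(
        {
            "participant_id": pid,
            "task_id": task.name,
            "session_id": sess,
            "trial_index": np.arange(n),
            "t_stimulus": t_stim,
            "t_response": t_stim + rt,
            "is_critical": is_critical,
            "outcome": outcome,
            "rt": rt,
        }
    )


# ---------------------------------------------------------------------------
# EEG

def _band_bins(cfg: SimConfig, n: int) -> list[np.ndarray]:
    """rfft bin indices per band (half-open [f_lo, f_hi) on the bin grid)."""
    df = cfg.fs / n
    freqs = np.arange(n // 2 + 1) * df
    out = []
    for b in cfg.bands:
        k = np.flatnonzero((freqs >= b.f_lo) & (freqs < b.f_hi))
        if k.size == 0:
            raise ValueError(
                f"band {b.name!r} contains no frequency bins at fs={cfg.fs}, "
                f"n={n}"
            )
        out.append(k)
    return out


def participant_channel_gains(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Per-participant log-normal channel gains (variance scale), identical
    across bands within a participant."""
    rng = np.random.default_rng([cfg.seed, 1])
    gains = {}
    for exp in (1, 2):
        for pid in participant_ids(cfg, exp):
            gains[pid] = np.exp(
                rng.normal(0.0, cfg.participant_scale_sd, cfg.n_channels)
            )
    return gains


def task_band_offsets(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Per-task log-normal band-power offsets (variance scale)."""
    rng = np.random.default_rng([cfg.seed, 2])
    return {
        t.name: np.exp(rng.normal(0.0, cfg.task_offset_sd, len(cfg.bands)))
        for t in cfg.tasks
    }


def expected_band_power(
    cfg: SimConfig,
    band_name: str,
    participant_id: str | None = None,
    task_id: str | None = None,
    elapsed_fraction: float = 0.0,
) -> float | np.ndarray:
    """Closed-form per-channel variance of one band's component.

    With no participant this is the population-level expectation (unit gain);
    with a participant the per-channel gains are applied, returning an array.
    """
    i = cfg.band_names.index(band_name)
    v = cfg.base_band_power[i]
    if task_id is not None:
        v = v * task_band_offsets(cfg)[task_id][i]
    if band_name == "alpha":
        v = v * (1.0 + cfg.alpha_fatigue_gain * elapsed_fraction)
    if participant_id is not None:
        return v * participant_channel_gains(cfg)[participant_id]
    return v


def expected_alpha_power_ratio(cfg: SimConfig, task_name: str) -> float:
    """Closed-form expected ratio of mean alpha power between bin 4 and
    bin 1 of a session of ``task_name`` (exact for the given trial count)."""
    task = cfg.task(task_name)
    n = task.n_trials
    bins = bin_assignments(n, 4)
    frac = np.arange(n) / (n - 1) if n > 1 else np.zeros(n)
    d = cfg.alpha_fatigue_gain
    m1 = np.mean(1.0 + d * frac[bins == 1])
    m4 = np.mean(1.0 + d * frac[bins == 4])
    return float(m4 / m1)


def simulate_eeg(
    cfg: SimConfig,
    trials: pd.DataFrame,
    trial_mask: np.ndarray | None = None,
) -> EpochSet:
    """Synthesize one epoch per (retained) trial.

    ``trial_mask`` optionally restricts generation to a boolean subset of
    the trial rows (e.g. labeled bins only); the structural parameters
    (participant gains, task offsets) do not depend on the subset.
    Deterministic under ``cfg.seed`` for a given call.
    """
    cfg.validate()
    n_samp = cfg.n_samples
    band_bins = _band_bins(cfg, n_samp)
    gains = participant_channel_gains(cfg)
    offsets = task_band_offsets(cfg)
    alpha_i = cfg.band_names.index("alpha")
    rng = np.random.default_rng([cfg.seed, 3])

    if trial_mask is not None:
        trials = trials.loc[np.asarray(trial_mask)]
    trials = trials.reset_index(drop=True)
    n_ep = len(trials)
    n_ch = cfg.n_channels

    task_ntrials = {t.name: t.n_trials for t in cfg.tasks}
    tvals = trials["trial_index"].to_numpy(dtype=float)
    denom = np.array(
        [max(task_ntrials[t] - 1, 1) for t in trials["task_id"]], dtype=float
    )
    frac = tvals / denom

    # per-epoch, per-band variance scale before channel gains
    base = np.asarray(cfg.base_band_power, dtype=float)
    off = np.stack([offsets[t] for t in trials["task_id"]])  # (n_ep, n_band)
    v_eb = base[None, :] * off
    v_eb[:, alpha_i] *= 1.0 + cfg.alpha_fatigue_gain * frac
    gain_ec = np.stack(
        [gains[p] for p in trials["participant_id"]]
    ) if n_ep else np.zeros((0, n_ch))  # (n_ep, n_ch)

    data = np.empty((n_ep, n_ch, n_samp), dtype=np.float32)
    n_rfft = n_samp // 2 + 1
    for start in range(0, n_ep, _CHUNK):
        stop = min(start + _CHUNK, n_ep)
        m = stop - start
        x = rng.normal(0.0, cfg.noise_sd, (m, n_ch, n_samp))
        for bi, kbins in enumerate(band_bins):
            K = kbins.size
            # variance per epoch/channel for this band
            v = v_eb[start:stop, bi][:, None] * gain_ec[start:stop]  # (m, n_ch)
            phases = rng.uniform(0.0, 2.0 * np.pi, (m, n_ch, K))
            spec = np.zeros((m, n_ch, n_rfft), dtype=complex)
            amp = (n_samp / 2.0) * np.sqrt(2.0 * v / K)  # (m, n_ch)
            spec[:, :, kbins] = amp[:, :, None] * np.exp(1j * phases)
            x += np.fft.irfft(spec, n=n_samp, axis=-1)
        data[start:stop] = x.astype(np.float32)

    bins_per_task = {
        name: bin_assignments(nt, 4) for name, nt in task_ntrials.items()
    }
    bin_index = np.array(
        [
            bins_per_task[t][i]
            for t, i in zip(trials["task_id"], trials["trial_index"])
        ],
        dtype=int,
    ) if n_ep else np.zeros(0, dtype=int)

    meta = pd.DataFrame(
        {
            "participant_id": trials["participant_id"].to_numpy(),
            "task_id": trials["task_id"].to_numpy(),
            "session_id": trials["session_id"].to_numpy(),
            "trial_index": trials["trial_index"].to_numpy(),
            "bin_index": bin_index,
            "label": np.full(n_ep, LABEL_UNLABELED, dtype=int),
        }
    )
    channel_names = [f"ch{c:02d}" for c in range(n_ch)]
    return EpochSet(data=data, meta=meta, fs=cfg.fs, channel_names=channel_names)
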