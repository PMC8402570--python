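"""Configuration dataclasses for the simulation, feature, and model stages.

The default :class:`SimConfig` encodes the study conditions the analysis is
designed for: two experiments with three visual sustained-attention tasks
(the air-traffic-controller task, a 3-stimulus oddball task, and a line
discrimination task), four-bin performance trajectories that decline over a
session, and EEG whose alpha-band power rises with accumulating mental
fatigue.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class BandDef:
    """A clinical EEG frequency band (inclusive edges, Hz)."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(
                f"band {self.name!r}: f_lo ({self.f_lo}) must be < f_hi ({self.f_hi})"
            )


#: The five traditional clinical bands.
DEFAULT_BANDS: tuple[BandDef, ...] = (
    BandDef("delta", 2.0, 4.0),
    BandDef("theta", 4.0, 7.0),
    BandDef("alpha", 8.0, 12.0),
    BandDef("beta", 13.0, 29.0),
    BandDef("gamma", 33.0, 80.0),
)


@dataclass(frozen=True)
class TaskSpec:
    """One vigilance task as performed in a single experiment.

    Parameters
    ----------
    name
        Task identifier (``"atc"``, ``"oddball"``, ``"line"``).
    experiment
        Which participant pool performs it (1 or 2).
    n_trials
        Experimental trials per session (practice trials are not modeled).
    n_sessions
        Sessions per participant (the line task was run on two days).
    critical_fraction
        Fraction of trials that are critical events requiring a response.
    iti_range_s
        Uniform range of stimulus-onset asynchrony in seconds.
    """

    name: str
    experiment: int
    n_trials: int
    n_sessions: int = 1
    critical_fraction: float = 0.1
    iti_range_s: tuple[float, float] = (2.0, 2.0)

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError(f"task {self.name!r}: n_trials must be positive")
        if not 0.0 < self.critical_fraction <= 1.0:
            raise ValueError(
                f"task {self.name!r}: critical_fraction must be in (0, 1], "
                f"got {self.critical_fraction}"
            )
        if self.n_sessions <= 0:
            raise ValueError(f"task {self.name!r}: n_sessions must be positive")


@dataclass
class SimConfig:
    """Parameters of the synthetic behavior + EEG generator.

    The behavioral trajectory is parameterized per time bin (four contiguous
    bins per session): expected proportion correct in bin ``b`` (0-based) is
    ``pc_start + b * pc_slope`` and the expected correct response time is
    ``rt_start_s + b * rt_slope_s``, each with per-participant jitter.

    The EEG signal model is a sum of band-limited processes: per epoch,
    channel and band the variance is ``base_band_power[band] *
    participant_gain[channel] * task_offset[band]``, with the alpha-band
    variance additionally multiplied by ``1 + alpha_fatigue_gain * f`` where
    ``f`` in [0, 1] is the trial's elapsed fraction of the session, plus
    additive broadband Gaussian noise.
    """

    n_participants_exp1: int = 14
    n_participants_exp2: int = 29
    tasks: tuple[TaskSpec, ...] = (
        TaskSpec("atc", 1, 1600, 1, 0.033, (2.0, 2.0)),
        TaskSpec("oddball", 1, 360, 1, 0.10, (2.0, 2.0)),
        TaskSpec("line", 2, 1600, 2, 0.10, (1.3, 1.7)),
    )
    #: exp-2 participants (taken from the end of the id list) with only one
    #: session of any multi-session task (26 of 29 returned for day two).
    n_exp2_single_session: int = 3

    fs: float = 250.0
    n_channels: int = 64
    epoch_len_s: float = 1.0
    bands: tuple[BandDef, ...] = DEFAULT_BANDS
    #: baseline variance per band, in the order of ``bands`` (uV^2 scale;
    #: only relative power matters downstream)
    base_band_power: tuple[float, ...] = (1.0, 0.7, 1.0, 0.5, 0.3)
    #: multiplicative alpha-power gain per unit elapsed session fraction
    alpha_fatigue_gain: float = 1.0
    #: log-normal SD (natural log) of per-participant, per-channel gains
    participant_scale_sd: float = 0.2
    #: log-normal SD (natural log) of per-task, per-band power offsets
    task_offset_sd: float = 0.1
    #: broadband additive noise SD (uV)
    noise_sd: float = 0.5

    # behavioral trajectory (per bin, 4 bins per session)
    pc_start: float = 0.95
    pc_slope: float = -0.025
    rt_start_s: float = 0.40
    rt_slope_s: float = 0.030
    #: within-trial SD of response times (s)
    rt_trial_sd: float = 0.08
    # per-participant jitter SDs on the trajectory parameters
    pc_start_jitter_sd: float = 0.02
    pc_slope_jitter_sd: float = 0.005
    rt_start_jitter_sd: float = 0.03
    rt_slope_jitter_sd: float = 0.005

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nyquist = self.fs / 2.0
        for b in self.bands:
            if b.f_hi >= nyquist:
                raise ValueError(
                    f"band {b.name!r} upper edge {b.f_hi} Hz is at or above "
                    f"Nyquist ({nyquist} Hz)"
                )
        if len(self.base_band_power) != len(self.bands):
            raise ValueError("base_band_power must have one entry per band")
        if self.alpha_fatigue_gain < 0:
            raise ValueError("alpha_fatigue_gain must be >= 0")
        if self.n_participants_exp1 <= 0 or self.n_participants_exp2 < 0:
            raise ValueError("participant counts must be positive")
        for t in self.tasks:
            if t.experiment not in (1, 2):
                raise ValueError(f"task {t.name!r}: experiment must be 1 or 2")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len_s))

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def task(self, name: str) -> TaskSpec:
        for t in self.tasks:
            if t.name == name:
                return t
        raise KeyError(name)


def full_scale_config(seed: int = 0, **overrides) -> SimConfig:
    """The study-condition replica: 14 + 29 participants, full trial counts."""
    return SimConfig(seed=seed, **overrides)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Alias for :func:`full_scale_config`."""
    return full_scale_config(seed=seed, **overrides)


def desk_scale_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced configuration sized for a single CPU.

    Four participants per experiment; 400-trial ATC sessions, 90-trial
    oddball sessions, one 400-trial line session -- the same task ratios at
    a quarter of the trial counts.
    """
    params = dict(
        n_participants_exp1=4,
        n_participants_exp2=4,
        tasks=(
            TaskSpec("atc", 1, 400, 1, 0.033, (2.0, 2.0)),
            TaskSpec("oddball", 1, 90, 1, 0.10, (2.0, 2.0)),
            TaskSpec("line", 2, 400, 1, 0.10, (1.3, 1.7)),
        ),
        n_exp2_single_session=0,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class MLPConfig:
    """Spectral-feature MLPNN: three ReLU hidden layers, each followed by
    dropout, and a sigmoid output unit."""

    hidden_units: tuple[int, int, int] = (250, 200, 150)
    dropout_rate: float = 0.5
    learning_rate: float = 1e-5
    epochs: int = 300
    batch_size: int = 64

    def __post_init__(self) -> None:
        if len(self.hidden_units) != 3:
            raise ValueError("MLPConfig.hidden_units must have exactly 3 entries")


@dataclass
class TCNConfig:
    """A temporal convolutional network stack.

    ``receptive_field`` follows the product rule
    kernel_size * n_blocks * final_dilation.
    """

    dilations: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    kernel_size: int = 2
    n_blocks: int = 2
    n_filters: int = 10
    dropout_rate: float = 0.0
    #: channel-wise dropout applied inside residual units (the second,
    #: "recurrent-style" dropout); defaults to ``dropout_rate`` when None
    recurrent_dropout_rate: float | None = None
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 64
    causal: bool = True
    use_batch_norm: bool = True

    def __post_init__(self) -> None:
        if not self.dilations:
            raise ValueError("dilations must be non-empty")
        if any(d <= 0 for d in self.dilations):
            raise ValueError("dilations must be positive")
        if list(self.dilations) != sorted(self.dilations) or len(
            set(self.dilations)
        ) != len(self.dilations):
            raise ValueError("dilations must be strictly increasing")
        if self.kernel_size < 1 or self.n_blocks < 1 or self.n_filters < 1:
            raise ValueError("kernel_size, n_blocks and n_filters must be >= 1")

    @property
    def d_final(self) -> int:
        return self.dilations[-1]

    @property
    def effective_recurrent_dropout(self) -> float:
        if self.recurrent_dropout_rate is None:
            return self.dropout_rate
        return self.recurrent_dropout_rate


@dataclass
class AEConfig:
    """TCN autoencoder with a latent-feature classifier.

    Encoder: TCN (ReLU) -> Conv1D(k=1, ``latent_filters``, ReLU) ->
    temporal average pool (5), giving a (input_len / 5) x L latent.
    Decoder: nearest-neighbor upsample (x5) -> TCN -> Conv1D back to the
    input channel count, with no activation anywhere in the decoder.
    Classifier: flatten -> two ReLU hidden layers with dropout -> sigmoid.
    """

    encoder: TCNConfig = field(
        default_factory=lambda: TCNConfig(
            kernel_size=2, n_blocks=2, n_filters=36, dropout_rate=0.0,
            learning_rate=1e-4,
        )
    )
    decoder: TCNConfig = field(
        default_factory=lambda: TCNConfig(
            kernel_size=2, n_blocks=2, n_filters=36, dropout_rate=0.0,
            learning_rate=1e-4, use_batch_norm=False,
        )
    )
    latent_filters: int = 8
    pool_size: int = 5
    ae_epochs: int = 50
    ae_learning_rate: float = 1e-4
    classifier_hidden_units: tuple[int, int] = (64, 32)
    classifier_dropout_rate: float = 0.5
    classifier_learning_rate: float = 1e-4
    classifier_epochs: int = 100
    batch_size: int = 64
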