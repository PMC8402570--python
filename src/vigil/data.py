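"""In-memory containers and on-disk round-trip for trial logs and epoched EEG.

A dataset on disk is::

    <dir>/trials.csv        one behavioral trial per row
    <dir>/epochs.npy        float32 array (n_epochs, n_channels, n_samples)
    <dir>/epochs_meta.csv   one row per epoch (participant/task/session/...)
    <dir>/epochs_meta.json  sidecar: fs, channel names, shape, dtype

All files are plain text except the numpy array container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: valid behavioral outcomes of a go/no-go style trial
OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection")

#: label codes in epoch metadata
LABEL_ATTENTIVE = 0
LABEL_DECREMENT = 1
LABEL_UNLABELED = -1

TRIAL_COLUMNS = [
    "participant_id",
    "task_id",
    "session_id",
    "trial_index",
    "t_stimulus",
    "t_response",
    "is_critical",
    "outcome",
    "rt",
]

EPOCH_META_COLUMNS = [
    "participant_id",
    "task_id",
    "session_id",
    "trial_index",
    "bin_index",
    "label",
]


class DatasetError(ValueError):
    """Raised when a dataset on disk is inconsistent with its sidecar."""


@dataclass
class EpochSet:
    """Labeled 1 s EEG epochs: ``data[epoch, channel, sample]`` in uV.

    ``meta`` has one row per epoch with participant/task/session/trial
    identity, the four-quarter ``bin_index`` (1-based) and a ``label``
    (0 = attentive, 1 = decrement, -1 = unlabeled).
    """

    data: np.ndarray
    meta: pd.DataFrame
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise DatasetError(
                f"epoch array must be 3-D (epochs, channels, samples), "
                f"got shape {self.data.shape}"
            )
        if len(self.meta) != self.data.shape[0]:
            raise DatasetError(
                f"n_epochs mismatch: array has {self.data.shape[0]} epochs "
                f"but metadata has {len(self.meta)} rows"
            )
        if self.channel_names and len(self.channel_names) != self.data.shape[1]:
            raise DatasetError(
                f"n_channels mismatch: array has {self.data.shape[1]} channels "
                f"but {len(self.channel_names)} channel names were given"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def labeled(self) -> "EpochSet":
        """The subset of epochs carrying a 0/1 label."""
        mask = (self.meta["label"].to_numpy() != LABEL_UNLABELED)
        return self.select(np.flatnonzero(mask))

    def select(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            fs=self.fs,
            channel_names=list(self.channel_names),
        )


def write_dataset(trials: pd.DataFrame, epochs: EpochSet | None, dir_path) -> Path:
    """Write a trial log and (optionally) its epochs to ``dir_path``.

    The round trip through :func:`read_dataset` is lossless: arrays compare
    bit-identical and CSV fields are preserved.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    trials.to_csv(out / "trials.csv", index=False)
    if epochs is not None:
        np.save(out / "epochs.npy", epochs.data)
        epochs.meta.to_csv(out / "epochs_meta.csv", index=False)
        sidecar = {
            "fs": epochs.fs,
            "channel_names": epochs.channel_names,
            "n_epochs": int(epochs.n_epochs),
            "n_channels": int(epochs.n_channels),
            "n_samples": int(epochs.n_samples),
            "dtype": str(epochs.data.dtype),
        }
        (out / "epochs_meta.json").write_text(json.dumps(sidecar, indent=1))
    return out


def read_dataset(dir_path) -> tuple[pd.DataFrame, EpochSet | None]:
    """Read a dataset written by :func:`write_dataset`.

    Raises
    ------
    DatasetError
        If the sidecar is missing while epochs exist, or any sidecar field
        disagrees with the stored array.
    """
    d = Path(dir_path)
    trials_path = d / "trials.csv"
    if not trials_path.exists():
        raise DatasetError(f"missing trials.csv in {d}")
    trials = pd.read_csv(trials_path)
    # an empty trial table loses its dtypes through CSV; keep the schema
    if trials.empty:
        trials = trials.reindex(columns=TRIAL_COLUMNS)

    epochs_path = d / "epochs.npy"
    if not epochs_path.exists():
        return trials, None
    sidecar_path = d / "epochs_meta.json"
    if not sidecar_path.exists():
        raise DatasetError(f"missing sidecar epochs_meta.json in {d}")
    sidecar = json.loads(sidecar_path.read_text())
    data = np.load(epochs_path)
    for fld, axis in (("n_epochs", 0), ("n_channels", 1), ("n_samples", 2)):
        if int(sidecar[fld]) != data.shape[axis]:
            raise DatasetError(
                f"sidecar field {fld!r} = {sidecar[fld]} does not match "
                f"array shape {data.shape}"
            )
    meta = pd.read_csv(d / "epochs_meta.csv")
    if meta.empty:
        meta = meta.reindex(columns=EPOCH_META_COLUMNS)
    return trials, EpochSet(
        data=data,
        meta=meta,
        fs=float(sidecar["fs"]),
        channel_names=list(sidecar["channel_names"]),
    )
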