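"""Dataset containers and HDF5/CSV persistence.

A dataset is one HDF5 container holding the epoched voltage data of up to
three events (``memory_array``, ``impulse1``, ``impulse2``) plus a sibling
CSV trial table.  Layout::

    /channels                      ordered channel names (authoritative order)
    /events/<event>/data           trials x channels x samples (float64, volts a.u.)
    /events/<event>/times          sample times in ms relative to event onset
    /events/<event>  @sample_rate  Hz

The trial table CSV starts with the columns
``participant,orientation_left,orientation_right,cue_side,cued_orientation,report_error``
and may carry the derived columns ``adjusted_error``, ``response_class`` and
``include`` added by the behaviour module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

EVENTS = ("memory_array", "impulse1", "impulse2")

TRIAL_TABLE_COLUMNS = [
    "participant",
    "orientation_left",
    "orientation_right",
    "cue_side",
    "cued_orientation",
    "report_error",
]
OPTIONAL_COLUMNS = ["adjusted_error", "response_class", "include"]


class DatasetError(ValueError):
    """Raised for malformed or inconsistent dataset containers."""


@dataclass
class EpochSet:
    """Epoched voltage data for one event.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
    times : ndarray of ms relative to event onset, strictly increasing and
        uniformly spaced at 1000 / sample_rate.
    channels : list of channel names, in the authoritative order.
    event : one of ``memory_array``, ``impulse1``, ``impulse2``.
    sample_rate : sampling rate in Hz.
    """

    data: np.ndarray
    times: np.ndarray
    channels: list[str]
    event: str
    sample_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = [str(c) for c in self.channels]
        if self.data.ndim != 3:
            raise DatasetError("epoch data must be trials x channels x samples")
        n_tr, n_ch, n_sp = self.data.shape
        if n_ch != len(self.channels):
            raise DatasetError(
                f"{n_ch} data channels but {len(self.channels)} channel names"
            )
        if self.times.shape != (n_sp,):
            raise DatasetError("times length must equal the sample count")
        step = 1000.0 / self.sample_rate
        if n_sp > 1 and not np.allclose(np.diff(self.times), step, atol=1e-6):
            raise DatasetError(
                "time axis must be uniform with spacing 1000/sample_rate"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select_trials(self, index) -> "EpochSet":
        """Return a view-like EpochSet restricted to the given trial index."""
        return EpochSet(
            self.data[index], self.times, self.channels, self.event, self.sample_rate
        )


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise DatasetError(f"trial table missing columns: {missing}")
    bad_side = set(table["cue_side"].unique()) - {"left", "right"}
    if bad_side:
        raise DatasetError(f"invalid cue_side values: {sorted(bad_side)}")
    cued = np.where(
        table["cue_side"] == "left",
        table["orientation_left"],
        table["orientation_right"],
    )
    if not np.allclose(np.asarray(table["cued_orientation"], float), cued):
        raise DatasetError("cued_orientation does not match the orientation on cue_side")
    return table


def write_dataset(
    path: str | Path,
    epochs: dict[str, EpochSet],
    table: pd.DataFrame,
) -> tuple[Path, Path]:
    """Write epochs to ``path`` (HDF5) and the trial table to a sibling CSV.

    Returns the (hdf5_path, csv_path) pair actually written.
    """
    path = Path(path)
    validate_trial_table(table)
    first = next(iter(epochs.values()))
    for ep in epochs.values():
        if ep.channels != first.channels:
            raise DatasetError("all events must share the channel list")
        if ep.n_trials != len(table):
            raise DatasetError(
                f"event {ep.event!r} has {ep.n_trials} trials but the table "
                f"has {len(table)} rows"
            )
    with h5py.File(path, "w") as f:
        # track_times=False keeps re-runs byte-for-byte reproducible
        f.create_dataset(
            "channels",
            data=np.array(first.channels, dtype=h5py.string_dtype()),
            track_times=False,
        )
        grp = f.create_group("events")
        for name, ep in epochs.items():
            g = grp.create_group(name)
            g.create_dataset("data", data=ep.data, track_times=False)
            g.create_dataset("times", data=ep.times, track_times=False)
            g.attrs["sample_rate"] = ep.sample_rate
    csv_path = path.with_suffix(".csv")
    cols = TRIAL_TABLE_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in table.columns]
    table[cols].to_csv(csv_path, index=False)
    return path, csv_path


def read_dataset(path: str | Path) -> tuple[dict[str, EpochSet], pd.DataFrame]:
    """Read an HDF5 epoch container and its sibling CSV trial table.

    Fails loudly on missing events, shape mismatches between table and data,
    and non-uniform time axes.
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    if not path.exists():
        raise DatasetError(f"no such dataset: {path}")
    if not csv_path.exists():
        raise DatasetError(f"missing sibling trial table: {csv_path}")
    table = validate_trial_table(pd.read_csv(csv_path))
    epochs: dict[str, EpochSet] = {}
    with h5py.File(path, "r") as f:
        if "channels" not in f or "events" not in f:
            raise DatasetError("container missing /channels or /events")
        channels = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][...]]
        for name in f["events"]:
            g = f["events"][name]
            if "data" not in g or "times" not in g:
                raise DatasetError(f"event {name!r} missing data or times")
            ep = EpochSet(
                data=g["data"][...],
                times=g["times"][...],
                channels=channels,
                event=name,
                sample_rate=float(g.attrs["sample_rate"]),
            )
            if ep.n_trials != len(table):
                raise DatasetError(
                    f"event {name!r} has {ep.n_trials} trials but the trial "
                    f"table has {len(table)} rows"
                )
            epochs[name] = ep
    return epochs, table


def require_event(epochs: dict[str, EpochSet], event: str) -> EpochSet:
    if event not in epochs:
        raise DatasetError(f"event absent from container: {event!r}")
    return epochs[event]


def write_result_meta(result_path: str | Path, config: dict, seed) -> Path:
    """Write a sidecar JSON recording the configuration hash and seed.

    Every CLI result file gets one of these so a run can be reproduced
    byte-for-byte.
    """
    import hashlib

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    meta = {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
    }
    meta_path = Path(str(result_path) + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    return meta_path
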