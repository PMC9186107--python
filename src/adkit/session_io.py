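"""Session bundles: one HDF5 file per recording session, CSV for exports.

Bundle layout (schema version 1)::

    /spikes/counts        int array, neurons x stimulus-periods
    /spikes/orientations  float, degrees per stimulus period (45 or 135)
    /eeg/data             float, electrodes x samples (volts); attr rate_hz
    /eye/data             float, samples x 3 (x deg, y deg, pupil a.u.); attr rate_hz
    /events/<column>      one dataset per event-table column
    root attrs            session_id, subject_id, duration_s, schema_version

Times are seconds from session start (float64); binned series elsewhere use
minutes.  All period intervals are half-open [onset, onset + duration).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["SessionRecording", "SchemaError", "read_session", "write_session",
           "export_results"]

SCHEMA_VERSION = 1

_EVENT_COLUMNS = ["period_type", "onset", "duration", "trial_index",
                  "is_first_prestim", "orientation", "outcome",
                  "change_time", "saccade_time"]
_STRING_COLUMNS = {"period_type", "outcome"}


class SchemaError(ValueError):
    """A session bundle is missing a required field or violates an invariant."""


@dataclass
class SessionRecording:
    """One session's spikes, EEG, eye trace and event table."""

    session_id: str
    subject_id: str
    spike_counts: np.ndarray      # neurons x stimulus-periods, nonnegative int
    orientations: np.ndarray      # degrees per stimulus period
    eeg: np.ndarray               # electrodes x samples, volts
    eeg_rate: float               # Hz
    eye: np.ndarray               # samples x 3: x deg, y deg, pupil
    eye_rate: float               # Hz
    events: pd.DataFrame
    duration_s: float = None

    def __post_init__(self):
        self.spike_counts = np.asarray(self.spike_counts)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        self.eye = np.asarray(self.eye, dtype=float)
        if self.duration_s is None:
            ends = self.events.onset + self.events.duration
            self.duration_s = float(ends.max()) if len(ends) else 0.0
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self):
        for name in ("eeg_rate", "eye_rate"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"{name} must be positive")
        if self.spike_counts.size and self.spike_counts.min() < 0:
            raise SchemaError("spike counts must be nonnegative")
        n_stim = int((self.events.period_type == "stimulus").sum())
        if self.orientations.size != n_stim:
            raise SchemaError("one orientation label per stimulus period required")
        if self.spike_counts.size and self.spike_counts.shape[1] != n_stim:
            raise SchemaError("spike-count columns must match stimulus periods")
        bad = set(np.unique(self.orientations[np.isfinite(self.orientations)])) - {45.0, 135.0}
        if bad:
            raise SchemaError(f"orientations must be 45 or 135, got {sorted(bad)}")
        ev = self.events.sort_values("onset")
        ends = (ev.onset + ev.duration).to_numpy()
        if len(ev) > 1 and np.any(ev.onset.to_numpy()[1:] < ends[:-1] - 1e-9):
            raise SchemaError("event periods must be nonoverlapping and ordered")
        for arr, rate, name in ((self.eeg, self.eeg_rate, "eeg"),
                                (self.eye, self.eye_rate, "eye")):
            n = arr.shape[-1] if name == "eeg" else arr.shape[0]
            if n and len(ev) and n / rate < ends[-1] - 1e-6:
                raise SchemaError(f"{name} trace does not cover all event times")
        return self

    @property
    def n_neurons(self) -> int:
        return self.spike_counts.shape[0]

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def stimulus_periods(self) -> pd.DataFrame:
        return self.events[self.events.period_type == "stimulus"]

    def prestimulus_periods(self) -> pd.DataFrame:
        return self.events[self.events.period_type == "prestimulus"]


def write_session(rec: SessionRecording, path, force: bool = False) -> Path:
    """Write a session bundle; refuses to overwrite unless ``force``."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (pass force=True to overwrite)")
    rec.validate()
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.attrs["session_id"] = rec.session_id
        h5.attrs["subject_id"] = rec.subject_id
        h5.attrs["duration_s"] = rec.duration_s
        spk = h5.create_group("spikes")
        spk.create_dataset("counts", data=rec.spike_counts.astype(np.int64))
        spk.create_dataset("orientations", data=rec.orientations)
        eeg = h5.create_group("eeg")
        eeg.create_dataset("data", data=rec.eeg)
        eeg.attrs["rate_hz"] = rec.eeg_rate
        eye = h5.create_group("eye")
        eye.create_dataset("data", data=rec.eye)
        eye.attrs["rate_hz"] = rec.eye_rate
        ev = h5.create_group("events")
        for col in _EVENT_COLUMNS:
            if col not in rec.events.columns:
                raise SchemaError(f"event table missing column: {col}")
            vals = rec.events[col].to_numpy()
            if col in _STRING_COLUMNS:
                vals = vals.astype("S")
            elif col == "is_first_prestim":
                vals = vals.astype(bool)
            else:
                vals = vals.astype(float)
            ev.create_dataset(col, data=vals)
    return path


def read_session(path) -> SessionRecording:
    """Read and validate a session bundle written by :func:`write_session`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as h5:
        version = int(h5.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unrecognized schema version: {version}")
        for group, key in (("spikes", "counts"), ("spikes", "orientations"),
                           ("eeg", "data"), ("eye", "data")):
            if group not in h5 or key not in h5[group]:
                raise SchemaError(f"bundle missing field: /{group}/{key}")
        ev = {}
        for col in _EVENT_COLUMNS:
            if "events" not in h5 or col not in h5["events"]:
                raise SchemaError(f"bundle missing field: /events/{col}")
            vals = h5["events"][col][()]
            if col in _STRING_COLUMNS:
                vals = np.array([v.decode() for v in vals], dtype=object)
            ev[col] = vals
        events = pd.DataFrame(ev)
        events["trial_index"] = events["trial_index"].astype(int)
        events["is_first_prestim"] = events["is_first_prestim"].astype(bool)
        rec = SessionRecording(
            session_id=str(h5.attrs["session_id"]),
            subject_id=str(h5.attrs["subject_id"]),
            spike_counts=h5["spikes"]["counts"][()],
            orientations=h5["spikes"]["orientations"][()],
            eeg=h5["eeg"]["data"][()],
            eeg_rate=float(h5["eeg"].attrs["rate_hz"]),
            eye=h5["eye"]["data"][()],
            eye_rate=float(h5["eye"].attrs["rate_hz"]),
            events=events,
            duration_s=float(h5.attrs["duration_s"]))
    return rec


def export_results(tables: dict, out_dir) -> list:
    """Write each table (DataFrame or BinnedSeries) to ``<out_dir>/<name>.csv``."""
    from .binning import BinnedSeries

    if not tables:
        raise ValueError("no tables to export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        if isinstance(table, BinnedSeries):
            table = pd.DataFrame({"bin_center_min": table.bin_centers,
                                  "value": table.values})
        dest = out / f"{name}.csv"
        table.to_csv(dest, index=False)
        written.append(dest)
    return written
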