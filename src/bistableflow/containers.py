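"""In-memory containers for recordings and behavioral event logs.

A :class:`Recording` is a dense channels x samples array with a sampling
rate and per-channel metadata (label, anatomical group, optional MNI-style
coordinate).  An :class:`EventLog` wraps the tidy button-press table
(presentation_id, time_s, percept_code) produced either by the synthetic
generator or by parsing a real experiment's logs.

Both round-trip through plain-text/HDF5 formats: recordings to HDF5
(datasets ``/data``, ``/fs`` and a ``/channels`` table), event logs to CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

PERCEPT_A = "A"
PERCEPT_B = "B"
PERCEPT_UNSURE = "unsure"


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one recording channel."""

    label: str
    group: str = ""
    xyz: tuple[float, float, float] | None = None


@dataclass
class Recording:
    """Multichannel time series with per-channel metadata.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples), signal units.
    fs
        Sampling rate in Hz, > 0.
    channels
        One :class:`ChannelInfo` per row of ``data``.
    """

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channels:
            self.channels = [ChannelInfo(label=f"ch{i}") for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel metadata count does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def groups(self) -> list[str]:
        return [c.group for c in self.channels]

    def copy_with(self, data: np.ndarray | None = None, fs: float | None = None) -> "Recording":
        return Recording(
            data=self.data.copy() if data is None else np.asarray(data, float),
            fs=self.fs if fs is None else fs,
            channels=list(self.channels),
        )

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("fs", data=float(self.fs))
            labels = np.array([c.label for c in self.channels], dtype=h5py.string_dtype())
            groups = np.array([c.group for c in self.channels], dtype=h5py.string_dtype())
            xyz = np.full((self.n_channels, 3), np.nan)
            for i, c in enumerate(self.channels):
                if c.xyz is not None:
                    xyz[i] = c.xyz
            g = f.create_group("channels")
            g.create_dataset("label", data=labels)
            g.create_dataset("group", data=groups)
            g.create_dataset("xyz", data=xyz)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Recording":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            fs = float(f["fs"][()])
            labels = [s.decode() if isinstance(s, bytes) else s for s in f["channels/label"][()]]
            groups = [s.decode() if isinstance(s, bytes) else s for s in f["channels/group"][()]]
            xyz = f["channels/xyz"][()]
        channels = []
        for i, (lab, grp) in enumerate(zip(labels, groups)):
            coord = None if np.any(np.isnan(xyz[i])) else tuple(float(v) for v in xyz[i])
            channels.append(ChannelInfo(label=lab, group=grp, xyz=coord))
        return cls(data=data, fs=fs, channels=channels)


@dataclass
class EventLog:
    """Button-press log: one row per press.

    ``events`` columns: presentation_id (int), time_s (float, within the
    presentation), percept_code (str).  ``presentation_length`` is the
    duration of each image presentation in seconds; ``presentation_onsets``
    maps presentation_id to its onset time in the continuous recording.
    """

    events: pd.DataFrame
    presentation_length: float
    presentation_onsets: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"presentation_id", "time_s", "percept_code"}
        if not req.issubset(self.events.columns):
            raise ValueError(f"event table must have columns {sorted(req)}")
        for pid, g in self.events.groupby("presentation_id"):
            t = g["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"press times not strictly increasing in presentation {pid}")
            if np.any(t < 0) or np.any(t > self.presentation_length):
                raise ValueError(f"press outside presentation window in presentation {pid}")
        if not self.presentation_onsets:
            self.presentation_onsets = {
                int(pid): float(pid) * self.presentation_length
                for pid in self.events["presentation_id"].unique()
            }

    @property
    def presentation_ids(self) -> list[int]:
        return sorted(int(p) for p in self.events["presentation_id"].unique())

    def presses(self, presentation_id: int) -> pd.DataFrame:
        return self.events[self.events["presentation_id"] == presentation_id]

    def absolute_press_times(self) -> np.ndarray:
        """Press times on the continuous-recording clock, sorted."""
        t = [
            self.presentation_onsets[int(r.presentation_id)] + r.time_s
            for r in self.events.itertuples()
        ]
        return np.sort(np.asarray(t))

    def to_csv(self, path: str | Path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, presentation_length: float,
                 presentation_onsets: dict[int, float] | None = None) -> "EventLog":
        df = pd.read_csv(path)
        return cls(events=df, presentation_length=presentation_length,
                   presentation_onsets=presentation_onsets or {})


@dataclass(frozen=True)
class PerceptPeriod:
    """Half-open interval [start_s, end_s) of one maintained percept."""

    presentation_id: int
    start_s: float
    end_s: float
    percept_code: str

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("period must have positive length")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


def periods_to_frame(periods: Sequence[PerceptPeriod]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "presentation_id": [p.presentation_id for p in periods],
            "start_s": [p.start_s for p in periods],
            "end_s": [p.end_s for p in periods],
            "percept_code": [p.percept_code for p in periods],
        }
    )


def frame_to_periods(df: pd.DataFrame) -> list[PerceptPeriod]:
    return [
        PerceptPeriod(int(r.presentation_id), float(r.start_s), float(r.end_s), str(r.percept_code))
        for r in df.itertuples()
    ]
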