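"""Core data containers shared by every stage of the pipeline.

Two containers carry data between modules:

* :class:`SignalRecord` — a multichannel time series with sampling rate,
  channel names and an event/annotation track (R-peak positions for ECG,
  stimulus onsets for EEG).
* :class:`PatternMatrix` — an ``n x p`` labeled pattern set, rows are
  patterns (heartbeat cycles, EEG epochs, embedded coordinates) and columns
  are samples/features.

Both round-trip through plain-text formats: records to a column-delimited
file (time column + one column per channel, metadata in ``#`` header
lines, events in a ``<stem>.events.csv`` sidecar) and pattern matrices to
CSV with the label as first column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SignalRecord", "PatternMatrix"]


@dataclass
class SignalRecord:
    """Multichannel time series with events.

    Parameters
    ----------
    data:
        ``(channels, samples)`` real matrix. Units are mV for ECG and µV
        for EEG; the container does not enforce units.
    fs:
        Sampling rate in Hz, strictly positive.
    channel_names:
        Ordered, unique channel labels, one per row of ``data``.
    events:
        List of ``(sample_index, code)`` pairs; for ECG the code is the
        beat class at each ground-truth R position, for EEG the trial
        label at each stimulus onset.
    meta:
        Free-form provenance metadata (generator parameters, seed, ...).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        n = self.data.shape[1]
        self.events = [(int(i), str(c)) for i, c in self.events]
        for i, _ in self.events:
            if not 0 <= i < n:
                raise ValueError(f"event index {i} outside [0, {n})")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def event_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.events], dtype=int)

    @property
    def event_labels(self) -> list[str]:
        return [c for _, c in self.events]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D view, by name."""
        try:
            row = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in record "
                f"(channels: {', '.join(self.channel_names)})"
            ) from None
        return self.data[row]

    # -- text round-trip --------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write ``time + channels`` columns; events go to a sidecar CSV."""
        path = Path(path)
        t = np.arange(self.n_samples) / self.fs
        with open(path, "w") as fh:
            fh.write(f"# fs: {self.fs!r}\n")
            fh.write("# channels: " + ",".join(self.channel_names) + "\n")
            frame = pd.DataFrame(self.data.T, columns=self.channel_names)
            frame.insert(0, "time", t)
            frame.to_csv(fh, index=False)
        if self.events:
            ev = pd.DataFrame(self.events, columns=["sample", "code"])
            ev.to_csv(path.with_suffix(path.suffix + ".events.csv"), index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SignalRecord":
        path = Path(path)
        header = {}
        with open(path) as fh:
            while True:
                pos = fh.tell()
                line = fh.readline()
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
            fh.seek(pos)
            frame = pd.read_csv(fh)
        fs = float(header["fs"])
        channels = header["channels"].split(",")
        events: list[tuple[int, str]] = []
        sidecar = path.with_suffix(path.suffix + ".events.csv")
        if sidecar.exists():
            ev = pd.read_csv(sidecar)
            events = list(zip(ev["sample"].astype(int), ev["code"].astype(str)))
        return cls(
            data=frame[channels].to_numpy().T,
            fs=fs,
            channel_names=channels,
            events=events,
        )


@dataclass
class PatternMatrix:
    """Labeled ``n x p`` pattern set: rows are patterns, columns features."""

    X: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.X.shape[0],):
            raise ValueError(
                f"{self.labels.size} labels for {self.X.shape[0]} patterns"
            )

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list[str]:
        """Sorted distinct labels."""
        return sorted({str(v) for v in self.labels})

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, rows: np.ndarray) -> "PatternMatrix":
        return PatternMatrix(self.X[rows], self.labels[rows], dict(self.meta))

    def with_features(self, X: np.ndarray, **meta) -> "PatternMatrix":
        """Same patterns/labels, new feature matrix (e.g. after embedding)."""
        if X.shape[0] != self.n_patterns:
            raise ValueError("row count changed")
        return PatternMatrix(X, self.labels.copy(), {**self.meta, **meta})

    # -- text round-trip --------------------------------------------------
    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        """CSV with the label column first, then one column per feature."""
        frame = pd.DataFrame(
            self.X, columns=[f"s{j}" for j in range(self.n_features)]
        )
        frame.insert(0, "label", self.labels.astype(str))
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "PatternMatrix":
        frame = pd.read_csv(path)
        if frame.columns[0] != "label":
            raise ValueError("pattern CSV must have 'label' as first column")
        return cls(
            X=frame.iloc[:, 1:].to_numpy(dtype=float),
            labels=frame["label"].astype(str).to_numpy(dtype=object),
        )
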