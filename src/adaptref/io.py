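"""Minimal multichannel record container and delimited-text I/O.

Records travel as CSV with a first column of time in seconds and one
channel-labeled amplitude column (microvolts) per electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Record", "read_record_csv", "write_record_csv"]


@dataclass
class Record:
    """A multichannel EEG record: (channels, T) amplitudes in microvolts."""

    data: np.ndarray
    channels: list[str]
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} channel labels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        lut = {c.lower(): i for i, c in enumerate(self.channels)}
        return self.data[lut[label.lower()]]

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.fs
        df = pd.DataFrame(self.data.T, columns=self.channels)
        df.insert(0, "time_s", t)
        return df


def read_record_csv(path: str | Path) -> Record:
    """Read a record CSV (first column time in seconds, rest channels)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one channel")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: record too short to infer a sampling rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / dt[0]
    channels = list(df.columns[1:])
    return Record(df.iloc[:, 1:].to_numpy(dtype=float).T, channels, fs)


def write_record_csv(record: Record, path: str | Path) -> None:
    record.to_frame().to_csv(path, index=False, float_format="%.6f")
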