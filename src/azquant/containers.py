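"""Core in-memory containers shared across the pipeline.

Tabular data (AZ tables, event lists, Pr maps, intensity tables) are plain
pandas DataFrames with documented column sets; only the movie stack and the
multi-session series carry enough coupled metadata to warrant a class.

Coordinate convention: positions are in micrometres with ``x`` along image
columns and ``y`` along image rows; the centre of pixel ``(row, col)`` is at
``(x, y) = (col * pixel_size_um, row * pixel_size_um)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Columns of an AZ table (synthetic ground-truth columns are optional).
AZ_COLUMNS = ["az_id", "x_um", "y_um"]

#: Columns of an event list as produced by detection / simulation.
EVENT_COLUMNS = [
    "event_id", "frame", "time_s", "x_um", "y_um", "peak_dF", "kind", "az_id",
]


@dataclass
class MovieStack:
    """A single-plane fluorescence time series.

    Parameters
    ----------
    data
        ``(n_frames, n_rows, n_cols)`` intensity array.
    frame_interval_s
        Time between consecutive frames, seconds.
    pixel_size_um
        Lateral pixel size, micrometres per pixel.
    stim_times_s
        Optional stimulus onset times (seconds from frame 0).
    meta
        Free-form provenance (processing steps, composite frames, shifts...).
    """

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    stim_times_s: tuple[float, ...] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("movie data must be (frames, rows, cols) with >= 1 frame")
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame interval and pixel size must be positive")
        if self.stim_times_s is not None:
            st = tuple(float(t) for t in self.stim_times_s)
            dur = self.n_frames * self.frame_interval_s
            if st and (min(st) < 0 or max(st) > dur):
                raise ValueError("stimulus times must lie within the recording")
            self.stim_times_s = st

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def copy_with(self, data: np.ndarray, **meta) -> "MovieStack":
        """New stack with replaced data and extended provenance."""
        m = dict(self.meta)
        m.update(meta)
        return MovieStack(
            data=data,
            frame_interval_s=self.frame_interval_s,
            pixel_size_um=self.pixel_size_um,
            stim_times_s=self.stim_times_s,
            meta=m,
        )


@dataclass
class SessionSeries:
    """An ordered list of imaging sessions of the same field.

    ``sessions`` maps strictly increasing timestamps (days) to AZ tables.
    Synthetic series carry persistent ``az_id`` across sessions; analysis code
    must not rely on that and instead recover correspondence geometrically
    (:func:`azquant.development.match_sessions`).
    """

    timestamps_days: tuple[float, ...]
    tables: tuple[pd.DataFrame, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.timestamps_days)
        if len(ts) != len(self.tables):
            raise ValueError("one AZ table per timestamp required")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be strictly increasing")
        self.timestamps_days = ts
        self.tables = tuple(self.tables)

    def __len__(self) -> int:
        return len(self.tables)

    def __iter__(self):
        return iter(zip(self.timestamps_days, self.tables))


def make_az_table(x_um: Sequence[float], y_um: Sequence[float], **extra) -> pd.DataFrame:
    """Assemble an AZ table from coordinate vectors (ids are 0..n-1)."""
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x_um and y_um must be equal-length 1-D sequences")
    tab = pd.DataFrame({"az_id": np.arange(len(x)), "x_um": x, "y_um": y})
    for k, v in extra.items():
        tab[k] = v
    return tab


def empty_event_list() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        EVENT_COLUMNS,
        [int, int, float, float, float, float, object, object],
    )})
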