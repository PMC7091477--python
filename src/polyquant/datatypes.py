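"""Core in-memory containers shared across the pipeline stages.

All spatial units are explicit in the field names: super-resolution
localizations are in nanometres, single-particle trajectories in
micrometres, images carry a pixel size in nanometres and extracellular
voltage traces a sampling rate in hertz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LocalizationTable",
    "TrajectorySet",
    "SpikeTrains",
]


@dataclass
class LocalizationTable:
    """Time-stamped 2-D single-molecule detections in nanometres.

    ``frame`` is the 0-based acquisition frame of each detection; ``x_nm`` /
    ``y_nm`` are positions inside a rectangular field of view of extent
    ``field_width_nm`` x ``field_height_nm``.
    """

    frame: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    field_width_nm: float
    field_height_nm: float
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.x_nm = np.asarray(self.x_nm, dtype=np.float64)
        self.y_nm = np.asarray(self.y_nm, dtype=np.float64)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.field_width_nm <= 0 or self.field_height_nm <= 0:
            raise ValueError("field extent must be positive")
        if len(self.frame) != len(self.x_nm) or len(self.frame) != len(self.y_nm):
            raise ValueError("frame/x/y arrays must have equal length")
        if len(self.frame) and self.frame.min() < 0:
            raise ValueError("frame indices must be non-negative")
        if not (np.all(np.isfinite(self.x_nm)) and np.all(np.isfinite(self.y_nm))):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def field_area_um2(self) -> float:
        return self.field_width_nm * self.field_height_nm / 1e6

    def sort_order(self) -> np.ndarray:
        """Deterministic (frame, x, y) lexicographic ordering."""
        return np.lexsort((self.y_nm, self.x_nm, self.frame))

    def take(self, idx: np.ndarray) -> "LocalizationTable":
        return LocalizationTable(
            frame=self.frame[idx],
            x_nm=self.x_nm[idx],
            y_nm=self.y_nm[idx],
            field_width_nm=self.field_width_nm,
            field_height_nm=self.field_height_nm,
            intensity=None if self.intensity is None else self.intensity[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"frame": self.frame, "x_nm": self.x_nm, "y_nm": self.y_nm}
        if self.intensity is not None:
            cols["intensity"] = self.intensity
        return pd.DataFrame(cols)


@dataclass
class TrajectorySet:
    """Single-particle trajectories sampled at a fixed frame interval.

    Positions are in micrometres; ``dt_s`` is the frame interval in seconds
    (20 ms for 50 Hz acquisitions).  Within each trajectory the frame index
    increases; unit steps denote consecutive observations.
    """

    trajectory_id: np.ndarray
    frame: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    dt_s: float = 0.020

    def __post_init__(self) -> None:
        self.trajectory_id = np.asarray(self.trajectory_id, dtype=np.int64)
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.x_um = np.asarray(self.x_um, dtype=np.float64)
        self.y_um = np.asarray(self.y_um, dtype=np.float64)
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        n = len(self.trajectory_id)
        if any(len(a) != n for a in (self.frame, self.x_um, self.y_um)):
            raise ValueError("all columns must have equal length")

    def __len__(self) -> int:
        return len(self.trajectory_id)

    @property
    def n_trajectories(self) -> int:
        return len(np.unique(self.trajectory_id))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "traj_id": self.trajectory_id,
                "frame": self.frame,
                "x_um": self.x_um,
                "y_um": self.y_um,
            }
        )


@dataclass
class SpikeTrains:
    """Per-channel sorted spike times (seconds) with detection metadata."""

    times_s: list  # list of 1-D float arrays, one per channel
    sampling_rate_hz: float
    analysis_duration_s: float = 600.0
    threshold_sd: float = 6.0
    highpass_hz: float = 300.0
    dead_time_ms: float = 1.0
    sd_estimator: str = "robust"
    sd_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times_s = [np.asarray(t, dtype=np.float64) for t in self.times_s]
        for t in self.times_s:
            if len(t) and (t.min() < 0 or t.max() > self.analysis_duration_s):
                raise ValueError("spike times outside the analysis window")
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return len(self.times_s)

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.times_s], dtype=np.int64)
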