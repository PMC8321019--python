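"""Shared data containers used across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSeries", "VelocityCurve"]


@dataclass
class FrameSeries:
    """A timed stack of 2D magnitude images.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, n_rows, n_cols)
        Image intensities, non-negative.
    frame_interval : float
        Seconds between consecutive frames (uniform sampling).
    pixel_spacing : tuple of float
        (row, col) spacing in mm/pixel.
    t0 : float
        Acquisition time of the first frame, seconds.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_spacing: tuple[float, float]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) stack")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) * self.frame_interval


@dataclass
class VelocityCurve:
    """Time-stamped scalar velocity samples in cm/s.

    Positive values correspond to upward (closing) motion of the
    tongue tip, i.e. motion toward the palate.
    """

    times: np.ndarray
    values: np.ndarray
    sign_convention: str = "positive = upward/closure"
    missing: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.missing is None:
            self.missing = np.zeros(self.times.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)

    def __len__(self) -> int:
        return self.times.size

    def valid(self) -> "VelocityCurve":
        """Return a copy with missing samples dropped."""
        keep = ~self.missing
        return VelocityCurve(self.times[keep], self.values[keep], self.sign_convention)
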