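"""Velocity decoding from velocity-encoded phase-contrast images.

Phase images are stored as 16-bit integers carrying a 12-bit payload:
code 0 maps to -pi and code 4095 to +pi, and phase maps linearly to
velocity with +/-pi corresponding to +/-VENC.  The ROI velocity is the
per-frame mean of decoded velocities over a 5x5 square, excluding
pixels whose magnitude falls below 5% of the frame's maximal magnitude
(low-density air regions carry random phase).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import VelocityCurve

__all__ = [
    "PhaseContrastSeries",
    "ROISpec",
    "decode_phase",
    "phase_to_velocity",
    "roi_velocity",
    "roi_size_mm",
    "cine_frame_interval",
    "series_duration",
]

MAXCODE_12BIT = 2**12 - 1  # 4095


@dataclass
class PhaseContrastSeries:
    """Paired magnitude/phase stacks with velocity-encoding metadata."""

    magnitude: np.ndarray
    phase_codes: np.ndarray
    venc: float = 30.0                  # cm/s
    frame_interval: float = 0.03552     # s
    trigger_times: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    times: np.ndarray | None = None
    encoding_dir: str = "through-plane, feet-to-head positive"

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase_codes = np.asarray(self.phase_codes)
        if self.magnitude.shape != self.phase_codes.shape:
            raise ValueError("magnitude and phase stacks must be congruent")
        if self.magnitude.ndim != 3:
            raise ValueError("stacks must be (n_frames, rows, cols)")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if np.any(self.phase_codes < 0) or np.any(self.phase_codes >= 2**16):
            raise ValueError("phase codes must fit a 16-bit container")
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        if self.times is not None:
            return self.times
        return self.trigger_times[0] + np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned square region of interest, in pixel coordinates."""

    top_left: tuple[int, int]
    size: tuple[int, int] = (5, 5)

    def slices(self) -> tuple[slice, slice]:
        r, c = self.top_left
        return slice(r, r + self.size[0]), slice(c, c + self.size[1])

    def validate(self, shape: tuple[int, int]) -> None:
        r, c = self.top_left
        if r < 0 or c < 0 or r + self.size[0] > shape[0] or c + self.size[1] > shape[1]:
            raise ValueError(f"ROI {self} not inside image of shape {shape}")


def decode_phase(code) -> np.ndarray:
    """Map a 12-bit payload (0..4095) to phase in [-pi, pi] radians."""
    code = np.asarray(code)
    if np.any(code < 0) or np.any(code > MAXCODE_12BIT):
        raise ValueError(
            "phase code exceeds 4095: inputs are assumed to carry a 12-bit "
            "payload (codes 0..2^12-1) in their 16-bit container")
    return -np.pi + code / MAXCODE_12BIT * 2.0 * np.pi


def phase_to_velocity(phase, venc: float) -> np.ndarray:
    """Map phase in [-pi, pi] to velocity in cm/s: v = phase * venc / pi."""
    phase = np.asarray(phase, dtype=float)
    if np.any(np.abs(phase) > np.pi + 1e-12):
        raise ValueError("phase outside [-pi, pi]")
    return phase * venc / np.pi


def roi_velocity(series: PhaseContrastSeries, roi: ROISpec,
                 mask_frac: float = 0.05,
                 per_frame_max: bool = True) -> VelocityCurve:
    """Per-frame mean decoded velocity over the magnitude-masked ROI.

    Pixels with magnitude below ``mask_frac`` times the maximal
    magnitude (per frame by default, per series otherwise) are excluded.
    Frames whose ROI is fully masked are flagged missing (NaN), never
    reported as zero.
    """
    roi.validate(series.magnitude.shape[1:])
    rs, cs = roi.slices()
    n = series.n_frames
    values = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)
    series_max = series.magnitude.max()
    for k in range(n):
        mag = series.magnitude[k]
        ref = mag.max() if per_frame_max else series_max
        m = mag[rs, cs] >= mask_frac * ref
        if not m.any():
            missing[k] = True
            continue
        v = phase_to_velocity(decode_phase(series.phase_codes[k][rs, cs][m]),
                              series.venc)
        values[k] = v.mean()
    return VelocityCurve(series.frame_times, values, missing=missing)


def roi_size_mm(roi_px: int, fov: float, matrix: int) -> float:
    """Physical side length of a square ROI, reported to 0.1 mm."""
    if fov <= 0 or matrix <= 0:
        raise ValueError("fov and matrix must be positive")
    return round(roi_px * fov / matrix, 1)


# --- protocol metadata arithmetic -----------------------------------------

def cine_frame_interval(tr_ms: float = 5.92, n_encodings: int = 2,
                        lines_per_segment: int = 3) -> float:
    """Temporal resolution (ms) of a segmented phase-contrast cine scan.

    One cine frame requires ``lines_per_segment`` k-space lines for each
    of the ``n_encodings`` velocity-encoding gradient types, each taking
    one repetition time.
    """
    if tr_ms <= 0 or n_encodings < 1 or lines_per_segment < 1:
        raise ValueError("invalid sequence parameters")
    return tr_ms * n_encodings * lines_per_segment


def series_duration(n_frames: int, frame_interval_ms: float) -> float:
    """Duration (s, 2 decimals) of a dynamic series of *n_frames*."""
    if n_frames < 1 or frame_interval_ms <= 0:
        raise ValueError("invalid series parameters")
    return round(n_frames * frame_interval_ms / 1000.0, 2)
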