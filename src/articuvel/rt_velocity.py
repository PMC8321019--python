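"""Trajectory-to-velocity conversion with slice-normal projection.

Converts a tracked (row, col) trajectory to patient-space mm, measures
the signed distance to the edge line of the oblique phase-contrast
slice, and differentiates it to obtain the transverse velocity in cm/s.
Positive displacement (and hence velocity) is upward, toward closure.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import VelocityCurve
from .registration import TrackedTrajectory

__all__ = [
    "SliceGeometry",
    "trajectory_to_patient",
    "signed_distance_to_slice_edge",
    "differentiate",
    "transverse_vs_full_speed",
]


@dataclass
class SliceGeometry:
    """Position and orientation of an acquisition slice in patient space.

    ``normal`` is ``row_dir x col_dir`` and is expected to have a
    positive feet-to-head component so that "up" is positive.
    """

    origin: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray
    thickness: float = 6.0
    edge_side: str = "upper"  # which slice edge anchors the distance

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.row_dir = np.asarray(self.row_dir, dtype=float)
        self.col_dir = np.asarray(self.col_dir, dtype=float)
        for name in ("row_dir", "col_dir"):
            v = getattr(self, name)
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-8):
                raise ValueError(f"{name} must be a unit vector")
        if not np.isclose(np.dot(self.row_dir, self.col_dir), 0.0, atol=1e-8):
            raise ValueError("row_dir and col_dir must be orthogonal")
        if self.edge_side not in ("upper", "lower"):
            raise ValueError("edge_side must be 'upper' or 'lower'")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.row_dir, self.col_dir)

    @property
    def up_normal(self) -> np.ndarray:
        """Slice normal oriented so its feet-to-head component is positive."""
        n = self.normal
        return -n if n[2] < 0 else n

    @property
    def edge_point(self) -> np.ndarray:
        off = 0.5 * self.thickness if self.edge_side == "upper" else -0.5 * self.thickness
        return self.origin + off * self.up_normal


def trajectory_to_patient(traj: TrackedTrajectory, geom: SliceGeometry,
                          spacing: tuple[float, float]) -> np.ndarray:
    """Map (row, col) pixel coordinates to patient-space mm points."""
    sr, sc = spacing
    if sr <= 0 or sc <= 0:
        raise ValueError("pixel spacing must be positive")
    pts = traj.points
    return (geom.origin[None, :]
            + pts[:, 0:1] * sr * geom.row_dir[None, :]
            + pts[:, 1:2] * sc * geom.col_dir[None, :])


def signed_distance_to_slice_edge(p_mm: np.ndarray, geom: SliceGeometry) -> np.ndarray:
    """Signed perpendicular distance (mm) to the slice edge line.

    Positive on the "up" (feet-to-head) side of the edge.  Invariant
    under in-plane displacement parallel to the edge.
    """
    p = np.asarray(p_mm, dtype=float)
    single = p.ndim == 1
    d = (np.atleast_2d(p) - geom.edge_point[None, :]) @ geom.up_normal
    return float(d[0]) if single else d


def differentiate(d_mm: np.ndarray, frame_interval: float,
                  times: np.ndarray | None = None,
                  savgol_window: int | None = None) -> VelocityCurve:
    """Differentiate a displacement series (mm) into a VelocityCurve (cm/s).

    Central differences in the interior, one-sided at the ends.  An
    optional Savitzky-Golay derivative (odd *savgol_window*, order 2)
    can be enabled for noisy tracks; it is off by default.
    """
    d_mm = np.asarray(d_mm, dtype=float)
    if d_mm.size < 2:
        raise ValueError("at least two samples required to differentiate")
    if times is None:
        times = np.arange(d_mm.size) * frame_interval
    times = np.asarray(times, dtype=float)
    if savgol_window is not None:
        from scipy.signal import savgol_filter
        v_mm_s = savgol_filter(d_mm, savgol_window, polyorder=2, deriv=1,
                               delta=frame_interval)
    else:
        v_mm_s = np.gradient(d_mm, times)
    return VelocityCurve(times, v_mm_s / 10.0)


def transverse_vs_full_speed(traj_mm: np.ndarray, geom: SliceGeometry,
                             frame_interval: float,
                             floor: float = 1e-6) -> np.ndarray:
    """Relative difference between full speed and its slice-normal part.

    Returns ``(|v_full| - |v_normal|) / |v_full|`` per sample; samples
    where the full speed is below *floor* (cm/s) are NaN.
    """
    traj_mm = np.asarray(traj_mm, dtype=float)
    v_full_vec = np.gradient(traj_mm, frame_interval, axis=0) / 10.0
    v_full = np.linalg.norm(v_full_vec, axis=1)
    v_norm = np.abs(v_full_vec @ geom.up_normal)
    out = np.full(v_full.shape, np.nan)
    ok = v_full > floor
    out[ok] = (v_full[ok] - v_norm[ok]) / v_full[ok]
    return out
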