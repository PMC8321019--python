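"""Plain-text readers/writers for pipeline artifacts."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import VelocityCurve
from .registration import TrackedTrajectory
from .rt_velocity import SliceGeometry

__all__ = [
    "write_trajectory_csv", "read_trajectory_csv",
    "write_velocity_csv", "read_velocity_csv",
    "write_geometry_json", "read_geometry_json",
    "read_manual_annotations", "write_marks_csv", "read_marks_csv",
    "write_peaks_table_csv", "write_timing_table_csv",
]


def write_trajectory_csv(traj: TrackedTrajectory, path) -> None:
    pd.DataFrame({
        "time_s": traj.times,
        "row": traj.points[:, 0],
        "col": traj.points[:, 1],
    }).to_csv(path, index=False)


def read_trajectory_csv(path) -> TrackedTrajectory:
    df = pd.read_csv(path)
    return TrackedTrajectory(df[["row", "col"]].to_numpy(),
                             df["time_s"].to_numpy())


def read_manual_annotations(path) -> TrackedTrajectory:
    """Read a manual annotation CSV with columns frame,row,col."""
    df = pd.read_csv(path).sort_values("frame")
    return TrackedTrajectory(df[["row", "col"]].to_numpy(),
                             df["frame"].to_numpy(dtype=float))


def write_velocity_csv(curve: VelocityCurve, path) -> None:
    pd.DataFrame({"time_s": curve.times, "v_cm_s": curve.values}).to_csv(
        path, index=False)


def read_velocity_csv(path) -> VelocityCurve:
    df = pd.read_csv(path)
    vals = df["v_cm_s"].to_numpy()
    return VelocityCurve(df["time_s"].to_numpy(), vals,
                         missing=np.isnan(vals))


def write_geometry_json(geom: SliceGeometry, path) -> None:
    Path(path).write_text(json.dumps({
        "origin": geom.origin.tolist(),
        "row_dir": geom.row_dir.tolist(),
        "col_dir": geom.col_dir.tolist(),
        "thickness": geom.thickness,
        "edge_side": geom.edge_side,
    }, indent=2))


def read_geometry_json(path) -> SliceGeometry:
    d = json.loads(Path(path).read_text())
    return SliceGeometry(
        origin=np.array(d["origin"]), row_dir=np.array(d["row_dir"]),
        col_dir=np.array(d["col_dir"]), thickness=d.get("thickness", 6.0),
        edge_side=d.get("edge_side", "upper"))


def write_marks_csv(marks, path) -> None:
    df = pd.DataFrame(marks.q, columns=["q1", "q2", "q3", "q4"])
    df.insert(0, "rep", np.arange(len(df)))
    df["flagged"] = marks.flagged
    df.to_csv(path, index=False)


def write_peaks_table_csv(report: dict, path) -> None:
    """Per-source mean (std. dev.) table of peak and phase-mean velocities.

    One row per (source, quantity); std is blank when only a single
    repetition contributed.
    """
    rows = []
    for route, label in (("rt", "Real-time"), ("pc", "PC cine")):
        for key, cols in (("peaks_aggregate",
                           ("left_min", "max", "right_min")),
                          ("means_aggregate",
                           ("first_opening", "closure", "second_opening"))):
            agg = report[route].get(key)
            if agg is None:
                continue
            row = {"source": label,
                   "quantity": "peak" if key.startswith("peaks") else "phase_mean",
                   "n": agg["n"]}
            for j, col in enumerate(cols):
                row[col] = round(float(agg["mean"][j]), 2)
                row[f"{col}_std"] = (round(float(agg["std"][j]), 2)
                                     if agg["std"] is not None else "")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_timing_table_csv(report: dict, path) -> None:
    """Mean (std. dev.) of q_i - t_i in ms, one row per source."""
    rows = []
    for route, label in (("rt", "Real-time"), ("pc", "PC cine")):
        ts = report[route].get("timing")
        if ts is None:
            continue
        row = {"source": label, "n": ts.n}
        for i in range(4):
            row[f"q{i+1}-t{i+1}_ms"] = round(float(ts.mean_ms[i]), 1)
            row[f"q{i+1}-t{i+1}_std_ms"] = (
                round(float(ts.std_ms[i]), 1)
                if not np.isnan(ts.std_ms[i]) else "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_marks_csv(path):
    from .audio import SpeechMarks

    df = pd.read_csv(path).sort_values("rep")
    flagged = (df["flagged"].to_numpy(dtype=bool)
               if "flagged" in df else np.zeros(len(df), dtype=bool))
    return SpeechMarks(df[["q1", "q2", "q3", "q4"]].to_numpy(), flagged)
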