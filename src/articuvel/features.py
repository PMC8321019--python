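"""Kinematic feature extraction and kinematics-vs-acoustics statistics.

Six stop points per repetition mark the zero-velocity instants of the
two-closure utterance: movement start t0, first top t1, first bottom
t2, second top t3, second bottom t4, movement stop t5.  Zero crossings
are located by linear interpolation; runs of samples below a noise
floor (the velocity plateaus at the consonant closures) are collapsed
to a single crossing at the run midpoint.

Peak velocities are the sampled extrema on (t1,t2), (t2,t3), (t3,t4);
phase means are the mean absolute velocities on the same intervals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import VelocityCurve
from .audio import SpeechMarks

__all__ = [
    "StopPoints",
    "TimingStats",
    "zero_crossings",
    "peak_velocities",
    "phase_means",
    "timing_stats",
    "aggregate_peaks",
]

NOISE_FLOOR_CM_S = 0.5


@dataclass
class StopPoints:
    """Per-repetition kinematic stop points t0..t5 (seconds).

    Flagged repetitions did not yield exactly six crossings and are
    excluded from statistics; their rows are NaN.
    """

    t: np.ndarray            # (n_reps, 6)
    flagged: np.ndarray      # (n_reps,) bool

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if self.t.ndim != 2 or self.t.shape[1] != 6:
            raise ValueError("t must be (n_reps, 6)")
        good = ~self.flagged
        if np.any(np.diff(self.t[good], axis=1) <= 0):
            raise ValueError("stop points must increase within a repetition")

    @property
    def n_reps(self) -> int:
        return self.t.shape[0]


@dataclass(frozen=True)
class TimingStats:
    """Mean/std of q_i - t_i per landmark i in {1..4}, milliseconds."""

    mean_ms: np.ndarray
    std_ms: np.ndarray
    n: int


def _crossings_in_window(times: np.ndarray, values: np.ndarray,
                         noise_floor: float) -> list[float]:
    """Ordered zero-crossing instants within one repetition window."""
    sgn = np.zeros(values.size, dtype=int)
    sgn[values > noise_floor] = 1
    sgn[values < -noise_floor] = -1

    events: list[float] = []
    nz = np.flatnonzero(sgn)
    if nz.size == 0:
        return events

    # leading zero run followed by motion -> movement start
    if nz[0] > 0:
        events.append(0.5 * (times[0] + times[nz[0] - 1]))
    for a, b in zip(nz[:-1], nz[1:]):
        if b == a + 1:
            if sgn[a] != sgn[b]:
                va, vb = values[a], values[b]
                if vb == va:
                    events.append(0.5 * (times[a] + times[b]))
                else:
                    events.append(times[a] - va * (times[b] - times[a]) / (vb - va))
        else:
            # a plateau run of sub-floor samples; one crossing at its
            # midpoint when the motion direction flips across it
            if sgn[a] != sgn[b]:
                events.append(0.5 * (times[a + 1] + times[b - 1]))
    # trailing zero run after the last motion -> movement stop
    if nz[-1] < sgn.size - 1:
        events.append(0.5 * (times[nz[-1] + 1] + times[-1]))
    return events


def zero_crossings(curve: VelocityCurve, rep_windows,
                   noise_floor: float = NOISE_FLOOR_CM_S) -> StopPoints:
    """Locate t0..t5 for each repetition window.

    Repetitions with other than six crossings are flagged and excluded.
    Missing samples (flagged by upstream decoding) are dropped first.
    """
    valid = curve.valid()
    times, values = valid.times, valid.values
    n = len(rep_windows)
    t = np.full((n, 6), np.nan)
    flagged = np.zeros(n, dtype=bool)
    for k, (w0, w1) in enumerate(rep_windows):
        sel = (times >= w0) & (times < w1)
        ev = _crossings_in_window(times[sel], values[sel], noise_floor)
        if len(ev) != 6:
            flagged[k] = True
            continue
        t[k] = ev
    return StopPoints(t, flagged)


def _interval_samples(curve: VelocityCurve, a: float, b: float) -> np.ndarray:
    valid = curve.valid()
    sel = (valid.times > a) & (valid.times < b)
    return valid.values[sel]


def peak_velocities(curve: VelocityCurve, stops: StopPoints) -> np.ndarray:
    """Sampled extrema per repetition: (left min, max, right min), cm/s.

    NaN rows for flagged repetitions or empty intervals.
    """
    out = np.full((stops.n_reps, 3), np.nan)
    for k in range(stops.n_reps):
        if stops.flagged[k]:
            continue
        _, t1, t2, t3, t4, _ = stops.t[k]
        for j, (a, b, ext) in enumerate(((t1, t2, np.min), (t2, t3, np.max),
                                         (t3, t4, np.min))):
            vals = _interval_samples(curve, a, b)
            if vals.size:
                out[k, j] = ext(vals)
    return out


def phase_means(curve: VelocityCurve, stops: StopPoints) -> np.ndarray:
    """Mean |v| per utterance phase: first opening, closure, second opening.

    Sample mean over the interval's samples; for uniform sampling this
    equals the time-weighted mean.
    """
    out = np.full((stops.n_reps, 3), np.nan)
    for k in range(stops.n_reps):
        if stops.flagged[k]:
            continue
        _, t1, t2, t3, t4, _ = stops.t[k]
        for j, (a, b) in enumerate(((t1, t2), (t2, t3), (t3, t4))):
            vals = _interval_samples(curve, a, b)
            if vals.size:
                out[k, j] = np.mean(np.abs(vals))
    return out


def timing_stats(stops: StopPoints, marks: SpeechMarks) -> TimingStats:
    """Mean and sample std (ms) of q_i - t_i over matched repetitions."""
    if stops.n_reps != marks.n_reps:
        raise ValueError("stop points and speech marks must cover the same repetitions")
    good = ~(stops.flagged | marks.flagged)
    if not good.any():
        raise ValueError("no matched repetitions")
    diff_ms = (marks.q[good] - stops.t[good, 1:5]) * 1000.0
    mean = diff_ms.mean(axis=0)
    std = (diff_ms.std(axis=0, ddof=1) if good.sum() > 1
           else np.full(4, np.nan))
    return TimingStats(mean_ms=mean, std_ms=std, n=int(good.sum()))


def aggregate_peaks(per_rep: np.ndarray) -> dict:
    """Mean (std. dev.) across repetitions, per column.

    Std is reported only when at least two repetitions contribute
    (single-cycle cine output has no deviation).
    """
    per_rep = np.asarray(per_rep, dtype=float)
    if per_rep.ndim != 2:
        raise ValueError("expected (n_reps, n_columns)")
    good = ~np.isnan(per_rep).any(axis=1)
    vals = per_rep[good]
    if vals.shape[0] == 0:
        raise ValueError("no valid repetitions")
    mean = vals.mean(axis=0)
    std = vals.std(axis=0, ddof=1) if vals.shape[0] > 1 else None
    return {"mean": mean, "std": std, "n": int(vals.shape[0])}
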