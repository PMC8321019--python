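"""End-to-end pipeline orchestration shared by the CLI and the tests."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import audio as audio_mod
from . import features
from .core import FrameSeries, VelocityCurve
from .pc_velocity import PhaseContrastSeries, ROISpec, roi_velocity
from .preproc import PreprocParams, filter_series
from .registration import RegParams, TrackedTrajectory, propagate_point, register
from .rt_velocity import (SliceGeometry, differentiate,
                          signed_distance_to_slice_edge, trajectory_to_patient)
from .synthetic import (GroundTruth, PhantomSpec, default_roi, make_trajectory,
                        phantom_geometry, render_audio, render_pc_series,
                        render_rt_series)

__all__ = ["run_rt", "run_pc", "run_audio", "run_compare", "PhantomRun",
           "run_phantom"]


def run_rt(series: FrameSeries, start, image_geom: SliceGeometry,
           slice_geom: SliceGeometry,
           reg_params: RegParams = RegParams(),
           preproc_params: PreprocParams | None = PreprocParams(),
           ) -> tuple[TrackedTrajectory, VelocityCurve]:
    """Filter, register, propagate the start point and differentiate.

    *image_geom* maps pixels of the tracked series into patient space;
    *slice_geom* is the phase-contrast slice whose edge line anchors
    the projected displacement.
    """
    filtered = filter_series(series, preproc_params) if preproc_params else series
    fld = register(filtered, reg_params)
    traj = propagate_point(start, fld, times=series.times)
    p_mm = trajectory_to_patient(traj, image_geom, series.pixel_spacing)
    dist = signed_distance_to_slice_edge(p_mm, slice_geom)
    curve = differentiate(dist, series.frame_interval, times=series.times)
    return traj, curve


def run_pc(series: PhaseContrastSeries, roi: ROISpec) -> VelocityCurve:
    """Decode, mask and average the phase-contrast series over the ROI."""
    return roi_velocity(series, roi)


def run_audio(rec, sequence_duration: float,
              rep_windows: list[tuple[float, float]],
              background_level: float | None = None):
    """Segment the recording, extract q-marks and align to MRI time.

    Returns (marks_in_mri_time, alignment).
    """
    env = audio_mod.envelope(rec.samples, rec.rate)
    align = audio_mod.align_audio_to_mri(
        env, rec.rate, sequence_duration, rec.ttl_times, rec.generator_times)
    if background_level is None:
        background_level = audio_mod.estimate_background_level(env)
    segments = audio_mod.detect_segments(env, background_level, rec.rate)
    labels = audio_mod.classify_segments(segments, env, rec.rate)
    audio_windows = [(w0 + align.offset, w1 + align.offset)
                     for w0, w1 in rep_windows]
    marks = audio_mod.vowel_marks(segments, labels, audio_windows)
    q_mri = marks.q - align.offset
    return audio_mod.SpeechMarks(q_mri, marks.flagged), align


def run_compare(rt_curve: VelocityCurve, pc_curve: VelocityCurve,
                marks, rep_windows, noise_floor: float = features.NOISE_FLOOR_CM_S,
                ) -> dict:
    """Apply the features module to both curves and build a joint report."""
    report: dict = {"n_reps": len(rep_windows)}
    for name, curve in (("rt", rt_curve), ("pc", pc_curve)):
        stops = features.zero_crossings(curve, rep_windows, noise_floor)
        peaks = features.peak_velocities(curve, stops)
        means = features.phase_means(curve, stops)
        try:
            peaks_agg = features.aggregate_peaks(peaks)
            means_agg = features.aggregate_peaks(means)
        except ValueError:
            peaks_agg = means_agg = None
        entry = {
            "stops": stops,
            "peaks": peaks,
            "phase_means": means,
            "peaks_aggregate": peaks_agg,
            "means_aggregate": means_agg,
        }
        if marks is not None:
            try:
                entry["timing"] = features.timing_stats(stops, marks)
            except ValueError:
                entry["timing"] = None
        report[name] = entry
    return report


@dataclass
class PhantomRun:
    """All artifacts of a full phantom pipeline execution."""

    spec: PhantomSpec
    truth: GroundTruth
    rt_series: FrameSeries
    rt_traj: TrackedTrajectory
    rt_curve: VelocityCurve
    pc_curve: VelocityCurve
    marks: object
    alignment: object
    report: dict
    rep_windows: list


def run_phantom(spec: PhantomSpec, venc: float = 30.0,
                reg_params: RegParams = RegParams(),
                preproc: bool = True) -> PhantomRun:
    """Generate the phantom and run both pipelines plus the comparison."""
    truth = make_trajectory(spec)
    image_geom, pc_geom, _ = phantom_geometry(spec)
    rt_series = render_rt_series(truth, spec)
    pc_series = render_pc_series(truth, spec, venc=venc)
    rec = render_audio(truth, spec)

    # start the track at the ground-truth tip position in frame 0
    h = spec.image_shape[0]
    sp_r, sp_c = rt_series.pixel_spacing
    x0, y0 = truth.position_mm(0.0)
    start = ((h - 1) - y0 / sp_r, x0 / sp_c)
    rt_traj, rt_curve = run_rt(
        rt_series, start, image_geom, pc_geom, reg_params,
        PreprocParams() if preproc else None)

    pc_curve = run_pc(pc_series, default_roi(truth, spec))

    rep_windows = [(k * spec.cycle_period, (k + 1) * spec.cycle_period)
                   for k in range(spec.n_cycles)]
    marks, align = run_audio(rec, spec.duration, rep_windows)
    report = run_compare(rt_curve, pc_curve, marks, rep_windows)
    return PhantomRun(spec, truth, rt_series, rt_traj, rt_curve, pc_curve,
                      marks, align, report, rep_windows)
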