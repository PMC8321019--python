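"""Synthetic phantom generator with analytic ground truth.

Produces the three inputs the pipeline consumes — a mid-sagittal
magnitude image series, a velocity-encoded phase-contrast series and a
synchronized audio track — from a single closed-form tongue-tip
trajectory, so every downstream stage can be validated against known
ground truth.

The trajectory emulates a periodically repeated two-closure utterance:
per cycle the tip rises from rest to the palate, holds (first closure),
descends to an open position, rises back (second closure), descends
again and finally returns to rest.  All moving segments are quintic
smoothsteps, so the trajectory is C1 and its derivative is available in
closed form.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import FrameSeries

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_trajectory",
    "render_rt_series",
    "render_pc_series",
    "render_audio",
    "default_roi",
    "phantom_geometry",
    "AudioRecording",
]

# Per-cycle phase schedule as fractions of a 2-second reference cycle:
# (name, duration).  Moving segments scale their distance with the
# requested peak speed; plateau segments pin the velocity to zero.
_SCHEDULE = (
    ("rest_pre", 0.08),
    ("ascend0", 0.12),   # rest -> palate
    ("hold_pal1", 0.09),  # first closure        (t1 at midpoint)
    ("descend1", 0.36),  # palate -> open        (left minimum peak)
    ("hold_open1", 0.09),  # first open position (t2 at midpoint)
    ("ascend1", 0.36),   # open -> palate        (positive peak)
    ("hold_pal2", 0.09),  # second closure       (t3 at midpoint)
    ("descend2", 0.36),  # palate -> open        (right minimum peak)
    ("hold_open2", 0.09),  # second open position (t4 at midpoint)
    ("ascend_f", 0.24),  # open -> rest (gentle, avoids tracking overshoot)
    ("rest_post", 0.12),
)

_SMOOTHSTEP_PEAK = 1.875  # max of d/dx (6x^5 - 15x^4 + 10x^3) at x = 1/2


def _smoothstep(x: np.ndarray) -> np.ndarray:
    return x * x * x * (10.0 + x * (-15.0 + 6.0 * x))


def _smoothstep_deriv(x: np.ndarray) -> np.ndarray:
    return 30.0 * x * x * (1.0 - x) ** 2


@dataclass
class PhantomSpec:
    """Parameters of the synthetic phantom.

    Identical (spec, seed) pairs produce bit-identical outputs.
    """

    cycle_period: float = 2.0      # s
    n_cycles: int = 2
    frame_interval_rt: float = 0.01998   # s, real-time series
    frame_interval_pc: float = 0.03552   # s, phase-contrast series
    peak_speed: float = 15.0       # cm/s, main stroke peak
    rest_gap: float = 12.0         # mm, tip rest distance below palate
    image_shape: tuple[int, int] = (64, 64)
    fov: float = 160.0             # mm
    noise_sd: float = 0.01         # fraction of peak intensity
    motion_blur: bool = True
    motion_angle_deg: float = 0.0  # in-plane tilt of the motion axis
    acoustic_lag: float = 0.05     # s, vowel onset after kinematic stop
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")
        if self.peak_speed < 0:
            raise ValueError("peak_speed must be non-negative")
        if self.fov <= 0:
            raise ValueError("fov must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.rest_gap <= 0:
            raise ValueError("rest_gap must be positive")

    @property
    def open_gap(self) -> float:
        """Palate-to-open-position distance in mm, from the peak speed."""
        scale = self.cycle_period / 2.0
        tau = 0.36 * scale  # duration of each main stroke
        return self.peak_speed * 10.0 * tau / _SMOOTHSTEP_PEAK

    @property
    def duration(self) -> float:
        return self.cycle_period * self.n_cycles

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


@dataclass
class AudioRecording:
    """Mono audio with synchronization metadata.

    ``ttl_times`` are beep pulses on the recorder's clock;
    ``generator_times`` are the same events on the scanner's clock;
    ``saec_sequence_end_times`` are sequence-end timestamps recorded by
    the external synchronization unit (scanner clock).
    """

    samples: np.ndarray
    rate: int = 16000
    ttl_times: np.ndarray = field(default_factory=lambda: np.array([]))
    generator_times: np.ndarray = field(default_factory=lambda: np.array([]))
    saec_sequence_end_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        for name in ("ttl_times", "generator_times", "saec_sequence_end_times"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size > 1 and np.any(np.diff(arr) < 0):
                raise ValueError(f"{name} must be non-decreasing")
            setattr(self, name, arr)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


class GroundTruth:
    """Closed-form trajectory with analytic velocity and event times.

    The motion coordinate ``s(t)`` is the displacement along the motion
    axis relative to palate contact (0 at the palate, negative below).
    Positive velocity means motion toward the palate (upward).
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        scale = spec.cycle_period / 2.0
        g = spec.rest_gap
        d_open = spec.open_gap
        if spec.peak_speed > 0 and d_open <= g:
            raise ValueError(
                "peak_speed too small for rest_gap: open position would not "
                "lie below the rest position"
            )
        # Positions along the motion axis (mm, palate = 0).
        pos = {
            "rest": -g,
            "palate": 0.0,
            "open": -d_open if spec.peak_speed > 0 else -g,
        }
        route = {
            "rest_pre": ("rest", "rest"),
            "ascend0": ("rest", "palate"),
            "hold_pal1": ("palate", "palate"),
            "descend1": ("palate", "open"),
            "hold_open1": ("open", "open"),
            "ascend1": ("open", "palate"),
            "hold_pal2": ("palate", "palate"),
            "descend2": ("palate", "open"),
            "hold_open2": ("open", "open"),
            "ascend_f": ("open", "rest"),
            "rest_post": ("rest", "rest"),
        }
        if spec.peak_speed == 0:
            route = {k: ("rest", "rest") for k in route}
        self._segments = []  # (t_start, t_end, y_from, y_to)
        t = 0.0
        for name, frac in _SCHEDULE:
            dur = frac * scale
            a, b = route[name]
            self._segments.append((name, t, t + dur, pos[a], pos[b]))
            t += dur
        self._cycle = spec.cycle_period

        mids = {name: 0.5 * (t0 + t1) for name, t0, t1, _, _ in self._segments}
        stop_base = np.array([
            mids["rest_pre"], mids["hold_pal1"], mids["hold_open1"],
            mids["hold_pal2"], mids["hold_open2"], mids["rest_post"],
        ])
        # (n_cycles, 6) kinematic stop points t0..t5
        self.stop_times = (
            stop_base[None, :]
            + np.arange(spec.n_cycles)[:, None] * spec.cycle_period
        )
        lag = spec.acoustic_lag
        self.vowel_intervals = []
        for k in range(spec.n_cycles):
            t0_, t1_, t2_, t3_, t4_, t5_ = self.stop_times[k]
            self.vowel_intervals.append((t1_ + lag, t2_ + lag))
            self.vowel_intervals.append((t3_ + lag, t4_ + lag))
        self.beep_times = np.arange(spec.n_cycles) * spec.cycle_period

        th = np.deg2rad(spec.motion_angle_deg)
        self._dir = np.array([np.sin(th), np.cos(th)])  # (x, up)

        # Dense samples (1 kHz) exposing the spec'd array fields.
        self.times = np.arange(0.0, spec.duration + 5e-4, 1e-3)
        self.tip_trajectory = self.position_mm(self.times)
        self.tip_velocity_normal = self.velocity_normal_cm_s(self.times)

    # -- closed forms -------------------------------------------------

    def s_mm(self, t) -> np.ndarray:
        """Motion-axis displacement (mm) relative to palate contact."""
        t = np.asarray(t, dtype=float)
        tc = np.mod(t, self._cycle)
        out = np.empty_like(tc)
        for _, t0, t1, ya, yb in self._segments:
            m = (tc >= t0) & (tc < t1)
            if not np.any(m):
                continue
            x = (tc[m] - t0) / (t1 - t0)
            out[m] = ya + (yb - ya) * _smoothstep(x)
        out[tc >= self._segments[-1][2]] = self._segments[-1][4]
        return out

    def speed_cm_s(self, t) -> np.ndarray:
        """Signed speed along the motion axis (cm/s, positive upward)."""
        t = np.asarray(t, dtype=float)
        tc = np.mod(t, self._cycle)
        out = np.zeros_like(tc)
        for _, t0, t1, ya, yb in self._segments:
            if yb == ya:
                continue
            m = (tc >= t0) & (tc < t1)
            if not np.any(m):
                continue
            x = (tc[m] - t0) / (t1 - t0)
            out[m] = (yb - ya) / (t1 - t0) * _smoothstep_deriv(x) / 10.0
        return out

    def position_mm(self, t) -> np.ndarray:
        """Tip position, columns (x_mm, y_up_mm) in the image frame."""
        s = np.atleast_1d(self.s_mm(t))
        spec = self.spec
        base = np.array([spec.fov / 2.0, 0.72 * spec.fov])  # palate contact
        p = base[None, :] + s[:, None] * self._dir[None, :]
        return p if np.asarray(t).ndim else p[0]

    def velocity_normal_cm_s(self, t) -> np.ndarray:
        """Slice-normal (vertical) velocity component, cm/s."""
        return self.speed_cm_s(t) * self._dir[1]

    def velocity_full_cm_s(self, t) -> np.ndarray:
        """Magnitude of the full in-plane velocity, cm/s."""
        return np.abs(self.speed_cm_s(t))

    @property
    def palate_y_mm(self) -> float:
        return 0.72 * self.spec.fov

    def save_csv(self, path) -> None:
        arr = np.column_stack([
            self.times, self.tip_trajectory, self.tip_velocity_normal,
        ])
        np.savetxt(
            path, arr, delimiter=",",
            header="time_s,x_mm,y_mm,v_normal_cm_s", comments="",
        )


def make_trajectory(spec: PhantomSpec) -> GroundTruth:
    """Build the closed-form ground-truth trajectory for *spec*."""
    return GroundTruth(spec)


# ---------------------------------------------------------------------------
# real-time magnitude series
# ---------------------------------------------------------------------------

def _pixel_grids(spec: PhantomSpec):
    h, w = spec.image_shape
    sp = spec.fov / h, spec.fov / w
    rows = np.arange(h)
    cols = np.arange(w)
    y_up = (h - 1 - rows) * sp[0]     # mm, up-positive
    x = cols * sp[1]
    return np.meshgrid(x, y_up)       # (X, Y) each (h, w)


def _render_frame(truth: GroundTruth, spec: PhantomSpec, t: float,
                  X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xt, yt = truth.position_mm(float(t))
    dx, dy = X - xt, Y - yt
    img = np.exp(-(dx**2 + dy**2) / (2.0 * 4.0**2))          # tip blob
    img += 0.6 * np.exp(-(dx**2 / (2.0 * 7.0**2)            # tongue body
                          + (dy + 10.0)**2 / (2.0 * 9.0**2)))
    img = np.minimum(img, 1.0)
    yp = truth.palate_y_mm
    # static palate band, composited with max so the moving tip stays
    # the brightest pixel even at closure
    palate = 0.75 * np.exp(-((Y - (yp + 4.0)) / 2.0)**4)
    return np.maximum(img, palate)


def render_rt_series(truth: GroundTruth, spec: PhantomSpec) -> FrameSeries:
    """Render the mid-sagittal magnitude series.

    Frames are rendered at ``frame_interval_rt``; if ``motion_blur`` is
    set each frame averages 5 sub-exposures across the frame interval,
    which reproduces directional blurring proportional to speed.
    """
    lo = truth.position_mm(truth.times)
    margin = 8.0
    if (lo.min() < margin) or (lo.max() > spec.fov - margin):
        raise ValueError("trajectory leaves the field of view")
    X, Y = _pixel_grids(spec)
    # one extra frame past the last cycle so that every in-cycle sample
    # of the derivative uses a central difference
    n = int(round(spec.duration / spec.frame_interval_rt)) + 1
    times = np.arange(n) * spec.frame_interval_rt
    frames = np.empty((n, *spec.image_shape))
    if spec.motion_blur:
        offsets = (np.arange(5) / 4.0 - 0.5) * spec.frame_interval_rt
    else:
        offsets = np.array([0.0])
    for k, t in enumerate(times):
        acc = np.zeros(spec.image_shape)
        for off in offsets:
            acc += _render_frame(truth, spec, max(t + off, 0.0), X, Y)
        frames[k] = acc / offsets.size
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frames += rng.normal(0.0, spec.noise_sd, frames.shape)
        np.maximum(frames, 0.0, out=frames)
    h, _ = spec.image_shape
    return FrameSeries(frames, spec.frame_interval_rt,
                       (spec.fov / h, spec.fov / spec.image_shape[1]))


def phantom_geometry(spec: PhantomSpec):
    """Geometries of the phantom's two acquisition planes.

    Returns ``(image_geom, pc_slice_geom, pixel_spacing)``.  The
    mid-sagittal image plane maps pixel (row, col) into patient space
    (x = left-right, z = feet-to-head, up-positive); the phase-contrast
    slice touches the palate and is perpendicular to the motion, so its
    normal points feet-to-head.
    """
    from .rt_velocity import SliceGeometry

    h, w = spec.image_shape
    sp = (spec.fov / h, spec.fov / w)
    image_geom = SliceGeometry(
        origin=np.array([0.0, 0.0, (h - 1) * sp[0]]),
        row_dir=np.array([0.0, 0.0, -1.0]),
        col_dir=np.array([1.0, 0.0, 0.0]),
        thickness=8.0,
    )
    pc_geom = SliceGeometry(
        origin=np.array([0.0, 0.0, 0.72 * spec.fov]),
        row_dir=np.array([0.0, -1.0, 0.0]),
        col_dir=np.array([1.0, 0.0, 0.0]),
        thickness=6.0,
    )
    return image_geom, pc_geom, sp


# ---------------------------------------------------------------------------
# phase-contrast series
# ---------------------------------------------------------------------------

_PC_MAXCODE = 2**12 - 1  # 12-bit payload in a 16-bit container


def _encode_velocity(v, venc: float, allow_aliasing: bool = False) -> np.ndarray:
    """Forward 12-bit velocity encoding (inverse of the decoder)."""
    v = np.asarray(v, dtype=float)
    if not allow_aliasing and np.any(np.abs(v) >= venc):
        raise ValueError("velocity reaches VENC; enable allow_aliasing to wrap")
    phase = v / venc * np.pi
    phase = np.mod(phase + np.pi, 2.0 * np.pi) - np.pi
    codes = np.rint((phase + np.pi) / (2.0 * np.pi) * _PC_MAXCODE)
    return codes.astype(np.uint16)


def render_pc_series(truth: GroundTruth, spec: PhantomSpec, venc: float = 30.0,
                     allow_aliasing: bool = False):
    """Render the velocity-encoded phase-contrast series.

    Tissue pixels (tongue column below the tip, static palate) carry
    12-bit codes for the local through-plane velocity; air pixels have
    near-zero magnitude and uniformly random phase codes.
    """
    from .pc_velocity import PhaseContrastSeries

    vmax = np.max(np.abs(truth.tip_velocity_normal))
    if not allow_aliasing and vmax >= venc:
        raise ValueError(
            f"peak normal velocity {vmax:.1f} cm/s reaches VENC={venc}"
        )
    X, Y = _pixel_grids(spec)
    n_per_cycle = int(np.floor(spec.cycle_period / spec.frame_interval_pc))
    times = np.concatenate([
        k * spec.cycle_period + np.arange(n_per_cycle) * spec.frame_interval_pc
        for k in range(spec.n_cycles)
    ])
    rng = np.random.default_rng(spec.seed + 1)
    h, w = spec.image_shape
    mag = np.empty((times.size, h, w))
    codes = np.empty((times.size, h, w), dtype=np.uint16)
    yp = truth.palate_y_mm
    palate = (Y > yp + 1.0) & (Y < yp + 6.0)
    for k, t in enumerate(times):
        xt, yt = truth.position_mm(float(t))
        v = float(truth.velocity_normal_cm_s(float(t)))
        tongue = (np.abs(X - xt) <= 10.0) & (Y <= yt)
        m = rng.uniform(0.0, 0.04, (h, w))          # air magnitude < 5%
        c = rng.integers(0, _PC_MAXCODE + 1, (h, w)).astype(np.uint16)
        m[palate] = 0.8
        c[palate] = _encode_velocity(0.0, venc)
        m[tongue] = 1.0
        c[tongue] = _encode_velocity(v, venc, allow_aliasing)
        mag[k], codes[k] = m, c
    return PhaseContrastSeries(
        magnitude=mag, phase_codes=codes, venc=venc,
        frame_interval=spec.frame_interval_pc,
        trigger_times=truth.beep_times.copy(), times=times,
    )


def default_roi(truth: GroundTruth, spec: PhantomSpec):
    """5x5 ROI inside the tongue column, below the lowest tip position."""
    from .pc_velocity import ROISpec

    h, w = spec.image_shape
    sp_r, sp_c = spec.fov / h, spec.fov / w
    y_lowest = truth.position_mm(truth.times)[:, 1].min()
    row_c = int(round((h - 1) - (y_lowest - 6.0) / sp_r))
    col_c = int(round(truth.position_mm(0.0)[0] / sp_c))
    return ROISpec(top_left=(row_c - 2, col_c - 2), size=(5, 5))


# ---------------------------------------------------------------------------
# audio
# ---------------------------------------------------------------------------

def render_audio(truth: GroundTruth, spec: PhantomSpec, *,
                 rate: int = 16000, pre_roll: float = 1.0,
                 post_roll: float = 0.5, beep_amp: float = 0.15,
                 vowel_amp: float = 0.5, scanner_noise_amp: float = 0.005,
                 beep_duration: float = 0.15) -> AudioRecording:
    """Render the simultaneous audio recording.

    Per cycle: a pure-tone beep at the trigger, two band-limited
    (0-4 kHz) vowel bursts at the ground-truth vowel intervals, each
    louder than the beep, over a low-level broadband scanner-noise bed
    spanning the acquisition with a sharp ending.  The audio clock leads
    the scanner clock by ``pre_roll`` seconds.
    """
    for (a0, a1), bt in zip(truth.vowel_intervals[::2], truth.beep_times):
        if bt + beep_duration > a0:
            raise ValueError("beep overlaps the first vowel burst")
    n = int(round((pre_roll + spec.duration + post_roll) * rate))
    t = np.arange(n) / rate
    sig = np.zeros(n)
    rng = np.random.default_rng(spec.seed + 2)

    noise_sel = (t >= pre_roll) & (t < pre_roll + spec.duration)
    if scanner_noise_amp > 0:
        sig[noise_sel] += scanner_noise_amp * rng.standard_normal(noise_sel.sum())

    def _burst(t0: float, dur: float, wave) -> None:
        i0, i1 = int(round(t0 * rate)), int(round((t0 + dur) * rate))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            return
        tt = np.arange(i1 - i0) / rate
        env = np.ones(i1 - i0)
        ramp = min(int(0.01 * rate), (i1 - i0) // 2)
        if ramp > 0:
            win = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
            env[:ramp] *= win
            env[-ramp:] *= win[::-1]
        sig[i0:i1] += env * wave(tt)

    if beep_amp > 0:
        for bt in truth.beep_times:
            _burst(pre_roll + bt, beep_duration,
                   lambda tt: beep_amp * np.sin(2.0 * np.pi * 1000.0 * tt))
    if vowel_amp > 0:
        f0 = 150.0
        harmonics = np.arange(1, int(4000.0 / f0) + 1) * f0
        weights = 1.0 / np.sqrt(np.arange(1, harmonics.size + 1))
        weights /= np.abs(weights).sum()

        def vowel(tt):
            return vowel_amp * np.sum(
                weights[:, None]
                * np.sin(2.0 * np.pi * harmonics[:, None] * tt[None, :]),
                axis=0,
            ) / np.max(np.abs(np.sum(
                weights[:, None]
                * np.sin(2.0 * np.pi * harmonics[:, None]
                         * (np.arange(rate) / rate)[None, :]), axis=0)))

        for (a0, a1) in truth.vowel_intervals:
            _burst(pre_roll + a0, a1 - a0, vowel)

    ttl = pre_roll + truth.beep_times
    return AudioRecording(
        samples=sig, rate=rate, ttl_times=ttl,
        generator_times=truth.beep_times.copy(),
        saec_sequence_end_times=np.array([spec.duration]),
    )


def write_outputs(truth: GroundTruth, spec: PhantomSpec, out_dir,
                  venc: float = 30.0) -> dict:
    """Write all phantom outputs to *out_dir*; returns the path map."""
    from scipy.io import wavfile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rt = render_rt_series(truth, spec)
    pc = render_pc_series(truth, spec, venc=venc)
    audio = render_audio(truth, spec)
    paths = {
        "rt_frames": out / "rt_frames.npy",
        "pc_magnitude": out / "pc_magnitude.npy",
        "pc_phase": out / "pc_phase.npy",
        "pc_times": out / "pc_times.csv",
        "audio": out / "audio.wav",
        "ground_truth": out / "ground_truth.csv",
        "sidecar": out / "phantom.json",
    }
    np.save(paths["rt_frames"], rt.frames)
    np.save(paths["pc_magnitude"], pc.magnitude)
    np.save(paths["pc_phase"], pc.phase_codes)
    np.savetxt(paths["pc_times"], pc.times, delimiter=",",
               header="time_s", comments="")
    pcm = np.clip(audio.samples, -1.0, 1.0)
    wavfile.write(paths["audio"], audio.rate,
                  (pcm * 32767).astype(np.int16))
    truth.save_csv(paths["ground_truth"])
    sidecar = {
        "spec": spec.to_dict(),
        "venc": venc,
        "frame_interval_rt": spec.frame_interval_rt,
        "frame_interval_pc": spec.frame_interval_pc,
        "ttl_times": audio.ttl_times.tolist(),
        "generator_times": audio.generator_times.tolist(),
        "beep_times": truth.beep_times.tolist(),
        "stop_times": truth.stop_times.tolist(),
        "vowel_intervals": [list(v) for v in truth.vowel_intervals],
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return {k: str(v) for k, v in paths.items()}
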