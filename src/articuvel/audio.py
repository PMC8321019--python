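"""Audio segmentation, vowel landmarking and audio-to-MRI alignment.

The segmentation follows a simple level-based rule: the rectified
signal is passed through a 10 ms sliding-maximum filter and a 10 ms
sliding-median filter; maximal runs of the envelope above the
background level lasting strictly more than 0.1 s are kept as segments.
Speech is always louder than the synchronization beeps, so segments are
split into {beep, speech} by their mean level.  Vowel onsets/offsets
(q1..q4, two vowels per repetition) are the boundaries of the speech
segments in each repetition window.

Alignment to the scanner clock uses the sharp ending of the scanner
noise (sequence start = noise ending - sequence duration) refined by
the median offset between stimulus-generator timestamps and the pulses
recorded on the recorder's TTL channel.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SpeechMarks",
    "AlignmentResult",
    "envelope",
    "detect_segments",
    "classify_segments",
    "vowel_marks",
    "align_audio_to_mri",
    "spectrogram",
    "estimate_background_level",
    "noise_gate",
]

MIN_SEGMENT_S = 0.1   # segments must be strictly longer than this
ENVELOPE_WIN_S = 0.010


@dataclass
class SpeechMarks:
    """Per-repetition acoustic landmarks q1..q4 (seconds).

    ``flagged`` repetitions had an unexpected number of speech segments
    and must be excluded from statistics; their marks are NaN.
    """

    q: np.ndarray               # (n_reps, 4)
    flagged: np.ndarray         # (n_reps,) bool

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if self.q.ndim != 2 or self.q.shape[1] != 4:
            raise ValueError("q must be (n_reps, 4)")
        good = ~self.flagged
        if np.any(np.diff(self.q[good], axis=1) <= 0):
            raise ValueError("q1 < q2 < q3 < q4 violated in an unflagged repetition")

    @property
    def n_reps(self) -> int:
        return self.q.shape[0]


@dataclass(frozen=True)
class AlignmentResult:
    sequence_start: float   # audio time of the MRI sequence start
    residual: float         # median TTL-vs-generator offset, seconds
    noise_end: float        # audio time of the scanner-noise ending

    @property
    def offset(self) -> float:
        """Total offset: mri_time = audio_time - offset."""
        return self.sequence_start + self.residual

    def to_mri_time(self, audio_times):
        return np.asarray(audio_times, dtype=float) - self.offset


def _odd_window(rate: int, seconds: float = ENVELOPE_WIN_S) -> int:
    w = int(round(seconds * rate))
    return max(w + (w % 2 == 0), 1)


def envelope(samples: np.ndarray, rate: int) -> np.ndarray:
    """10 ms sliding maximum of |samples| followed by a 10 ms median.

    Windows are centred; boundaries use edge replication.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty signal")
    w = _odd_window(rate)
    env = ndimage.maximum_filter1d(np.abs(samples), size=w, mode="nearest")
    return ndimage.median_filter(env, size=w, mode="nearest")


def detect_segments(env: np.ndarray, background_level: float,
                    rate: int) -> list[tuple[float, float]]:
    """Maximal runs with env > background_level lasting > 0.1 s.

    Returns (start, end) times in seconds; a run of exactly 0.1 s is
    rejected (strict inequality).
    """
    if background_level < 0:
        raise ValueError("background_level must be non-negative")
    env = np.asarray(env, dtype=float)
    above = env > background_level
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    out = []
    for i0, i1 in zip(starts, ends):
        if (i1 - i0) / rate > MIN_SEGMENT_S:
            out.append((i0 / rate, i1 / rate))
    return out


def classify_segments(segments: list[tuple[float, float]], env: np.ndarray,
                      rate: int, threshold: float | None = None) -> list[str]:
    """Label each segment 'speech' or 'beep' by its mean envelope level.

    By default the threshold is the midpoint between the two cluster
    means of a 1-D two-means split of the segment levels.  If all
    levels coincide, everything is labeled speech with a warning.
    """
    if not segments:
        return []
    env = np.asarray(env, dtype=float)
    means = np.array([
        env[int(round(a * rate)):int(round(b * rate))].mean()
        for a, b in segments
    ])
    if threshold is None:
        if np.ptp(means) == 0.0:
            warnings.warn("all segment levels equal; labeling all as speech")
            return ["speech"] * len(segments)
        lo, hi = means.min(), means.max()
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            lo_new = means[means <= mid].mean()
            hi_new = means[means > mid].mean()
            if (lo_new, hi_new) == (lo, hi):
                break
            lo, hi = lo_new, hi_new
        threshold = 0.5 * (lo + hi)
    return ["speech" if m > threshold else "beep" for m in means]


def vowel_marks(segments: list[tuple[float, float]], labels: list[str],
                rep_windows: list[tuple[float, float]],
                manual: np.ndarray | None = None) -> SpeechMarks:
    """Assemble q1..q4 per repetition from labeled speech segments.

    Each repetition window must contain exactly two speech segments;
    others are flagged and excluded.  If *manual* marks are given
    (array (n_reps, 4), NaN rows ignored) they override the detected
    values verbatim.
    """
    n = len(rep_windows)
    q = np.full((n, 4), np.nan)
    flagged = np.zeros(n, dtype=bool)
    speech = [s for s, lab in zip(segments, labels) if lab == "speech"]
    for k, (w0, w1) in enumerate(rep_windows):
        inside = [s for s in speech if w0 <= 0.5 * (s[0] + s[1]) < w1]
        if len(inside) != 2:
            flagged[k] = True
            continue
        (a0, a1), (b0, b1) = sorted(inside)
        q[k] = (a0, a1, b0, b1)
    if manual is not None:
        manual = np.asarray(manual, dtype=float)
        if manual.shape != q.shape:
            raise ValueError("manual marks must be (n_reps, 4)")
        override = ~np.isnan(manual).any(axis=1)
        q[override] = manual[override]
        flagged[override] = False
    return SpeechMarks(q, flagged)


def estimate_background_level(env: np.ndarray, factor: float = 3.0) -> float:
    """Default background level: *factor* times the median envelope.

    The scanner-noise bed dominates the recording, so its level is close
    to the median; thresholds in real data depend on subject and
    sequence and should be set explicitly when this heuristic fails.
    """
    return factor * float(np.median(env))


def align_audio_to_mri(env: np.ndarray, rate: int, sequence_duration: float,
                       ttl_times: np.ndarray, generator_times: np.ndarray,
                       noise_threshold: float | None = None,
                       min_noise_duration: float = 1.0) -> AlignmentResult:
    """Map audio time to MRI time.

    The scanner-noise ending is the end of the last suprathreshold run
    longer than *min_noise_duration*; the sequence start is that ending
    minus *sequence_duration*.  The residual clock offset is the median
    difference between TTL-channel pulses and generator timestamps
    shifted to the audio clock.
    """
    env = np.asarray(env, dtype=float)
    if noise_threshold is None:
        noise_threshold = 0.5 * float(np.median(env))
    above = env > noise_threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above.size and above[0]:
        starts = np.r_[0, starts]
    if above.size and above[-1]:
        ends = np.r_[ends, above.size]
    runs = [(i0, i1) for i0, i1 in zip(starts, ends)
            if (i1 - i0) / rate >= min_noise_duration]
    if not runs:
        raise ValueError("no scanner-noise segment found above threshold")
    noise_end = runs[-1][1] / rate
    sequence_start = noise_end - sequence_duration
    ttl = np.asarray(ttl_times, dtype=float)
    gen = np.asarray(generator_times, dtype=float)
    if ttl.size == 0 or gen.size == 0:
        raise ValueError("at least one TTL and one generator timestamp required")
    m = min(ttl.size, gen.size)
    residual = float(np.median(ttl[:m] - (gen[:m] + sequence_start)))
    return AlignmentResult(sequence_start=sequence_start, residual=residual,
                           noise_end=noise_end)


def spectrogram(samples: np.ndarray, rate: int, window_s: float = 0.025,
                hop_s: float = 0.010):
    """Short-time Fourier magnitude (Hann window).

    Returns (times, freqs, magnitude) with magnitude of shape
    (n_freqs, n_frames); frames are fully inside the signal (no
    padding), so Parseval's relation holds per frame.
    """
    samples = np.asarray(samples, dtype=float)
    nwin = int(round(window_s * rate))
    hop = max(int(round(hop_s * rate)), 1)
    if samples.size < nwin:
        return np.array([]), np.fft.rfftfreq(nwin, 1.0 / rate), np.zeros(
            (nwin // 2 + 1, 0))
    win = np.hanning(nwin)
    n_frames = 1 + (samples.size - nwin) // hop
    idx = np.arange(nwin)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = samples[idx] * win[None, :]
    mag = np.abs(np.fft.rfft(frames, axis=1)).T
    times = (np.arange(n_frames) * hop + nwin / 2) / rate
    freqs = np.fft.rfftfreq(nwin, 1.0 / rate)
    return times, freqs, mag


def noise_gate(samples: np.ndarray, rate: int,
               noise_interval: tuple[float, float],
               reduction_db: float = 20.0) -> np.ndarray:
    """Simple spectral noise gate learned from a noise-only interval.

    Stand-in for a dedicated MR-noise cancellation algorithm; attenuates
    STFT bins that do not exceed the per-bin noise profile.  Off by
    default in the pipeline.
    """
    from scipy.signal import stft, istft

    samples = np.asarray(samples, dtype=float)
    i0, i1 = (int(round(t * rate)) for t in noise_interval)
    nper = 512
    _, _, noise_spec = stft(samples[i0:i1], fs=rate, nperseg=nper)
    profile = np.abs(noise_spec).mean(axis=1, keepdims=True)
    f, t, spec = stft(samples, fs=rate, nperseg=nper)
    gain = np.where(np.abs(spec) > 2.0 * profile, 1.0,
                    10.0 ** (-reduction_db / 20.0))
    _, out = istft(spec * gain, fs=rate, nperseg=nper)
    return out[:samples.size]
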