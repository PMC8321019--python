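"""Overview figures: velocity curves with stop points over sound panels."""
from __future__ import annotations

import numpy as np

from .audio import spectrogram as _spectrogram
from .core import VelocityCurve

__all__ = ["velocity_overview", "peaks_bar_data"]


def velocity_overview(rt_curve: VelocityCurve, pc_curve: VelocityCurve,
                      path, samples=None, rate: int = 16000,
                      stops=None, audio_offset: float = 0.0) -> None:
    """Save a figure with both velocity curves, sound level and spectrogram.

    *samples*/*rate* are optional audio on the recorder clock;
    *audio_offset* maps audio time to MRI time (mri = audio - offset).
    Stop points, if given, are drawn as vertical lines.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows = 3 if samples is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(10, 3 * n_rows),
                             sharex=True, squeeze=False)
    ax = axes[0, 0]
    rt, pc = rt_curve.valid(), pc_curve.valid()
    ax.plot(rt.times, rt.values, "-", label="real-time (tracked)")
    ax.plot(pc.times, pc.values, "--", label="phase contrast")
    if stops is not None:
        for row, flagged in zip(stops.t, stops.flagged):
            if flagged:
                continue
            for t in row:
                ax.axvline(t, color="k", ls="-.", lw=0.6, alpha=0.5)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_ylabel("v (cm/s)")
    ax.legend(loc="upper right", fontsize=8)

    if samples is not None:
        from .audio import envelope

        t_audio = np.arange(len(samples)) / rate - audio_offset
        axes[1, 0].plot(t_audio, envelope(np.asarray(samples, float), rate),
                        color="tab:gray")
        axes[1, 0].set_ylabel("level")
        times, freqs, mag = _spectrogram(np.asarray(samples, float), rate)
        if mag.size:
            fsel = freqs <= 5000.0
            axes[2, 0].pcolormesh(times - audio_offset, freqs[fsel] / 1000.0,
                                  20 * np.log10(mag[fsel] + 1e-9),
                                  shading="auto", cmap="magma")
        axes[2, 0].set_ylabel("kHz")
    axes[-1, 0].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def peaks_bar_data(report: dict) -> dict:
    """Bar-chart data comparing both methods' peak and mean |velocities|."""
    out = {}
    for route in ("rt", "pc"):
        agg_p = report[route]["peaks_aggregate"]
        agg_m = report[route]["means_aggregate"]
        if agg_p is None or agg_m is None:
            continue
        out[route] = {
            "peak_abs_mean": np.abs(agg_p["mean"]).tolist(),
            "peak_std": None if agg_p["std"] is None else agg_p["std"].tolist(),
            "phase_mean": np.abs(agg_m["mean"]).tolist(),
            "phase_std": None if agg_m["std"] is None else agg_m["std"].tolist(),
        }
    return out
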