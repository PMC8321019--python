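"""Pre-filtering of magnitude frames before motion registration.

The chain is: background subtraction (10% of the global maximum), low
thresholding (10% of the post-subtraction maximum, strict inequality),
3x3 median filtering, edge-preserving smoothing, and 5x5 Gaussian
smoothing.  All thresholds are relative, so the chain commutes with
positive intensity scaling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import FrameSeries

__all__ = [
    "PreprocParams",
    "subtract_background",
    "threshold_low",
    "median_filter",
    "edge_preserving_smooth",
    "gaussian_smooth",
    "filter_frame",
    "filter_series",
]


@dataclass(frozen=True)
class PreprocParams:
    background_frac: float = 0.1
    threshold_frac: float = 0.1
    median_size: int = 3
    edge_strength: float = 0.1
    min_edge_distance: int = 3
    gaussian_size: int = 5
    gaussian_radius: float = 5.0

    def __post_init__(self) -> None:
        for name in ("background_frac", "threshold_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("median_size", "gaussian_size"):
            v = getattr(self, name)
            if v <= 0 or v % 2 == 0:
                raise ValueError(f"{name} must be an odd positive integer")
        if self.min_edge_distance < 0:
            raise ValueError("min_edge_distance must be non-negative")


def subtract_background(img: np.ndarray, p: PreprocParams = PreprocParams()) -> np.ndarray:
    """Subtract ``background_frac * max(img)`` from every pixel.

    May produce negative values; these are removed by ``threshold_low``.
    An all-zero image is returned unchanged.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    return img - p.background_frac * img.max()


def threshold_low(img_prime: np.ndarray, p: PreprocParams = PreprocParams()) -> np.ndarray:
    """Zero pixels not strictly above ``threshold_frac * max`` of the input.

    Equality with the threshold maps to 0 (conservative suppression; the
    strict-inequality branches leave the tie undefined otherwise).
    """
    img_prime = np.asarray(img_prime, dtype=float)
    thresh = p.threshold_frac * img_prime.max()
    return np.where(img_prime > thresh, img_prime, 0.0)


def median_filter(img: np.ndarray, p: PreprocParams = PreprocParams()) -> np.ndarray:
    return ndimage.median_filter(np.asarray(img, dtype=float),
                                 size=p.median_size, mode="reflect")


def edge_preserving_smooth(img: np.ndarray, p: PreprocParams = PreprocParams()) -> np.ndarray:
    """Smooth texture while keeping strong edges.

    Pixels whose gradient magnitude reaches ``edge_strength`` times the
    maximal gradient are treated as edges; the edge set is dilated by
    ``min_edge_distance`` so that edges closer than that distance merge
    into one preserved band.  Non-edge pixels are replaced with a mildly
    Gaussian-smoothed value.
    """
    img = np.asarray(img, dtype=float)
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    gmag = np.hypot(gx, gy)
    gmax = gmag.max()
    smoothed = ndimage.gaussian_filter(img, sigma=1.0, mode="reflect")
    if gmax == 0.0:
        return smoothed
    edges = gmag >= p.edge_strength * gmax
    if p.min_edge_distance > 0:
        edges = ndimage.binary_dilation(
            edges, structure=np.ones((3, 3), dtype=bool),
            iterations=p.min_edge_distance)
    return np.where(edges, img, smoothed)


def gaussian_smooth(img: np.ndarray, p: PreprocParams = PreprocParams()) -> np.ndarray:
    """Gaussian smoothing with a ``gaussian_size`` kernel, sigma = radius/3."""
    sigma = p.gaussian_radius / 3.0
    return ndimage.gaussian_filter(np.asarray(img, dtype=float), sigma=sigma,
                                   radius=p.gaussian_size // 2, mode="reflect")


_STAGES = (subtract_background, threshold_low, median_filter,
           edge_preserving_smooth, gaussian_smooth)


def filter_frame(img: np.ndarray, p: PreprocParams = PreprocParams()) -> np.ndarray:
    """Apply the full filtering chain to one frame."""
    out = np.asarray(img, dtype=float)
    for stage in _STAGES:
        out = stage(out, p)
    return np.maximum(out, 0.0)


def filter_series(series: FrameSeries, p: PreprocParams = PreprocParams()) -> FrameSeries:
    frames = np.stack([filter_frame(f, p) for f in series.frames])
    return FrameSeries(frames, series.frame_interval, series.pixel_spacing,
                       series.t0)
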