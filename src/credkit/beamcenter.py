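"""Primary-beam position estimation.

Two estimators serve two pipeline stages.  Processing uses the arg-max of a
heavily Gaussian-smoothed frame (the direct beam dominates every diffraction
pattern once speckle is smoothed away).  Screening uses the centroid of the
top-percentile brightest pixels, which is cheaper and needs no smoothing
parameter.  Integration software expects one stationary beam center per data
set, so per-frame estimates are aggregated with a component-wise median,
robust to frames where the beam is obscured.

Positions are (x, y) = (column, row) in 0-based logical pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .frames import DetectorFrame
from .physics import InvalidArgumentError


class NoSignalError(RuntimeError):
    """Frame contains no usable signal (e.g. all-zero counts)."""


class CenterMethod(str, Enum):
    GAUSSIAN_MAX = "gaussian_max"
    TOP_PERCENTILE = "top_percentile"


@dataclass(frozen=True)
class BeamCenterEstimate:
    position: tuple[float, float]   # (x, y) logical pixels
    method: CenterMethod
    frame_index: int = 0


def _as_array(frame) -> np.ndarray:
    if isinstance(frame, DetectorFrame):
        return frame.pixels
    return np.asarray(frame, dtype=float)


def center_gaussian_max(frame, sigma: float = 10.0,
                        frame_index: int | None = None) -> BeamCenterEstimate:
    """Arg-max of the Gaussian-smoothed frame (sigma in pixels, default 10).

    Reflect padding at the borders; ties broken deterministically toward the
    lowest row, then lowest column.
    """
    if not sigma > 0:
        raise InvalidArgumentError("sigma must be positive")
    pixels = _as_array(frame)
    if pixels.size == 0:
        raise InvalidArgumentError("empty frame")
    if not np.any(pixels > 0):
        raise NoSignalError("all-zero frame: no beam to locate")
    smoothed = gaussian_filter(pixels, sigma=sigma, mode="reflect")
    # C-order argmax scans rows then columns: exactly the tie-break we want.
    row, col = np.unravel_index(int(np.argmax(smoothed)), smoothed.shape)
    idx = frame_index if frame_index is not None else getattr(frame, "frame_index", 0)
    return BeamCenterEstimate(
        position=(float(col), float(row)),
        method=CenterMethod.GAUSSIAN_MAX,
        frame_index=idx,
    )


def center_top_percentile(frame, fraction: float = 0.05,
                          frame_index: int = 0) -> BeamCenterEstimate:
    """Mean position of the brightest ``fraction`` of pixels.

    The default 5% matches how screening locates the beam before cropping.
    The cutoff intensity is the ceil(fraction * N)-th brightest value and
    every pixel at or above it is included, so ties at the cutoff never
    depend on storage order (a constant frame yields the geometric center).
    """
    if not 0.0 < fraction <= 1.0:
        raise InvalidArgumentError("fraction must be in (0, 1]")
    pixels = _as_array(frame)
    if pixels.size == 0:
        raise InvalidArgumentError("empty frame")
    n = pixels.size
    k = math.ceil(fraction * n)
    flat = pixels.ravel()
    threshold = np.partition(flat, n - k)[n - k]
    rows, cols = np.nonzero(pixels >= threshold)
    return BeamCenterEstimate(
        position=(float(cols.mean()), float(rows.mean())),
        method=CenterMethod.TOP_PERCENTILE,
        frame_index=frame_index,
    )


def median_center(estimates: Sequence[BeamCenterEstimate]) -> tuple[float, float]:
    """Component-wise median of per-frame beam-center estimates.

    Robust to a minority of outlier frames (obscured beam, grid shadow).
    Even counts average the two middle values per component.
    """
    if len(estimates) == 0:
        raise InvalidArgumentError("no estimates to aggregate")
    xs = np.array([e.position[0] for e in estimates])
    ys = np.array([e.position[1] for e in estimates])
    return float(np.median(xs)), float(np.median(ys))


def estimates_to_rows(estimates: Iterable[BeamCenterEstimate]) -> list[dict]:
    """Per-frame estimates as records (frame_index, x, y, method) for CSV logs."""
    return [
        {"frame_index": e.frame_index, "x": e.position[0], "y": e.position[1],
         "method": e.method.value}
        for e in estimates
    ]
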