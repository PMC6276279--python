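"""Crystal-tracking quality control from per-frame diffracted intensity.

When a crystal drifts (partially) out of the selected-area aperture, the
diffracted intensities weaken before anything else changes, so a per-frame
intensity scale is a cheap tracking diagnostic — integration programs report
an equivalent number (the per-image scale of the initial background job).
The statistic here is specifiable rather than borrowed: per data frame, the
summed counts outside a central-beam exclusion disc and outside the module
cross, normalized so the series median is 1.  Dips flag frames where the
crystal was probably obscured; a long run of dips (or a large coefficient of
variation) marks the run as poorly tracked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .beamcenter import NoSignalError
from .frames import DetectorFrame, cross_mask
from .physics import InvalidArgumentError

DEFAULT_BEAM_EXCLUSION_RADIUS = 30.0   # px
DEFAULT_DIP_THRESHOLD = 0.5
DEFAULT_RUN_LENGTH = 5
DEFAULT_CV_CUTOFF = 0.5


@dataclass
class ScaleSeries:
    """Per-data-frame intensity scale, median-normalized to 1."""

    scale: np.ndarray
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        self.scale = np.asarray(self.scale, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)

    @property
    def coefficient_of_variation(self) -> float:
        return float(self.scale.std() / self.scale.mean())


def scale_series(
    frames: Sequence[DetectorFrame],
    beam_center: tuple[float, float],
    beam_exclusion_radius: float = DEFAULT_BEAM_EXCLUSION_RADIUS,
) -> ScaleSeries:
    """Per-frame summed counts away from the beam and mask, over the median.

    The direct beam carries most of the counts but no tracking information,
    so a disc of ``beam_exclusion_radius`` around ``beam_center`` is excluded
    along with the module-cross strips.  Both the Bragg spots and the diffuse
    (inelastic) background scale with how much of the crystal the aperture
    still admits, so the remaining summed counts trace the crystal's presence.
    """
    if len(frames) < 2:
        raise InvalidArgumentError("need at least 2 data frames")
    shape = frames[0].pixels.shape
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    live = (np.hypot(xx - beam_center[0], yy - beam_center[1])
            > beam_exclusion_radius)
    if shape == (516, 516):
        live &= ~cross_mask(shape)
    if not live.any():
        raise NoSignalError("all pixels masked")
    sums = np.array([f.pixels[live].sum() for f in frames], dtype=float)
    med = np.median(sums)
    if med <= 0:
        raise NoSignalError("median frame intensity is zero outside the mask")
    return ScaleSeries(
        scale=sums / med,
        frame_indices=np.array([f.frame_index for f in frames]),
    )


@dataclass
class TrackingReport:
    flags: np.ndarray          # True where scale dipped below threshold
    poorly_tracked: bool
    longest_flag_run: int
    coefficient_of_variation: float

    @property
    def verdict(self) -> str:
        return "poorly tracked" if self.poorly_tracked else "tracked"


def tracking_flags(
    series: ScaleSeries,
    dip_threshold: float = DEFAULT_DIP_THRESHOLD,
    run_length: int = DEFAULT_RUN_LENGTH,
    cv_cutoff: float = DEFAULT_CV_CUTOFF,
) -> TrackingReport:
    """Flag dipped frames and judge the run.

    A run is "poorly tracked" iff it contains ``run_length`` or more
    consecutive flagged frames, or the scale's coefficient of variation
    exceeds ``cv_cutoff``.  A single-frame dip (e.g. a grid bar crossing the
    beam at high tilt) is flagged but does not fail the run.
    """
    flags = series.scale < dip_threshold
    longest = run = 0
    for f in flags:
        run = run + 1 if f else 0
        longest = max(longest, run)
    cv = series.coefficient_of_variation
    return TrackingReport(
        flags=flags,
        poorly_tracked=bool(longest >= run_length or cv > cv_cutoff),
        longest_flag_run=longest,
        coefficient_of_variation=cv,
    )


def series_to_rows(series: ScaleSeries, report: TrackingReport) -> list[dict]:
    """Plot-ready records (frame, scale, flag) for CSV export."""
    return [
        {"frame": int(i), "scale": float(s), "flag": bool(f)}
        for i, s, f in zip(series.frame_indices, series.scale, report.flags)
    ]
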