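"""Timepix detector geometry and per-pixel response correction.

The Timepix camera is a 2x2 tile of 256x256 modules.  The single row/column of
pixels on each module edge that faces the neighbouring module is physically
three times wider (165 um instead of 55 um).  Recorded 512x512 raw frames
therefore have the wrong geometry near the module cross: each of the two
boundary pixels per dimension really covers three logical 55 um pixels.
``expand_timepix`` rewrites a raw frame onto the correct 516x516 logical grid,
splitting each big pixel's counts equally among its three logical pixels so
that integrated intensity is conserved.  The resulting 6-pixel-wide cross is
unreliable for integration and is masked downstream via UNTRUSTED_RECTANGLE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
import numpy as np

from .physics import InvalidArgumentError

RAW_SIZE = 512
CORRECTED_SIZE = 516
MODULE_SIZE = 256

# Raw (0-based) indices of the physically wide pixels along each axis.
_BIG_RAW = (255, 256)
# Logical (0-based) index range covered by the expanded cross, inclusive.
CROSS_LO = 255
CROSS_HI = 260


class GeometryError(ValueError):
    """Frame shape or geometry state does not match the operation."""


class FrameKind(str, Enum):
    DATA = "data"
    DEFOCUS_TRACKING = "defocus_tracking"


class GeometryState(str, Enum):
    RAW512 = "raw512"
    CORRECTED516 = "corrected516"


_EXPECTED_SHAPE = {
    GeometryState.RAW512: (RAW_SIZE, RAW_SIZE),
    GeometryState.CORRECTED516: (CORRECTED_SIZE, CORRECTED_SIZE),
}


@dataclass
class DetectorFrame:
    """One 2-D frame of counts plus its geometry state and slot metadata."""

    pixels: np.ndarray
    geometry_state: GeometryState = GeometryState.RAW512
    frame_index: int = 1
    kind: FrameKind = FrameKind.DATA
    timestamp: float = 0.0
    exposure: float = 0.5

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        expected = _EXPECTED_SHAPE[GeometryState(self.geometry_state)]
        if self.pixels.shape != expected:
            raise GeometryError(
                f"{self.geometry_state} frame must be {expected}, "
                f"got {self.pixels.shape}"
            )
        if np.any(self.pixels < 0):
            raise GeometryError("counts must be non-negative")
        if self.frame_index < 1:
            raise InvalidArgumentError("frame_index is 1-based")


def _expansion_matrix() -> np.ndarray:
    """516x512 matrix E with column sums 1; out = E @ raw @ E.T."""
    e = np.zeros((CORRECTED_SIZE, RAW_SIZE))
    logical = 0
    for raw in range(RAW_SIZE):
        if raw in _BIG_RAW:
            e[logical:logical + 3, raw] = 1.0 / 3.0
            logical += 3
        else:
            e[logical, raw] = 1.0
            logical += 1
    assert logical == CORRECTED_SIZE
    return e

_E = _expansion_matrix()


def expand_timepix(frame: DetectorFrame) -> DetectorFrame:
    """Expand a raw 512x512 Timepix frame to the 516x516 logical grid.

    The two module-boundary pixels per dimension (raw 0-based indices 255 and
    256) each become three logical pixels holding one third of the recorded
    counts; all other pixels are copied with shifted indices.  Total counts
    are conserved to machine precision.
    """
    if frame.geometry_state != GeometryState.RAW512:
        raise GeometryError("expand_timepix requires a raw512 frame")
    out = _E @ frame.pixels @ _E.T
    return DetectorFrame(
        pixels=out,
        geometry_state=GeometryState.CORRECTED516,
        frame_index=frame.frame_index,
        kind=frame.kind,
        timestamp=frame.timestamp,
        exposure=frame.exposure,
    )


def cross_untrusted_rectangles() -> list[tuple[int, int, int, int]]:
    """Module-cross mask as XDS UNTRUSTED_RECTANGLE tuples (x1, x2, y1, y2).

    XDS treats the bounds as open intervals on 1-based pixel coordinates:
    a pixel at coordinate x is masked iff x1 < x < x2 (likewise y).  The
    expanded cross covers logical 0-based indices 255..260, i.e. 1-based
    256..261, per axis, giving one full-height vertical strip and one
    full-width horizontal strip.
    """
    lo = CROSS_LO          # 0-based 255 -> open lower bound for 1-based 256
    hi = CROSS_HI + 2      # 262: open upper bound for 1-based 261
    full = (0, CORRECTED_SIZE + 1)
    return [
        (lo, hi, full[0], full[1]),   # vertical strip, all rows
        (full[0], full[1], lo, hi),   # horizontal strip, all columns
    ]


def cross_mask(shape: tuple[int, int] = (CORRECTED_SIZE, CORRECTED_SIZE)) -> np.ndarray:
    """Boolean mask, True on the expanded module-cross pixels."""
    mask = np.zeros(shape, dtype=bool)
    mask[CROSS_LO:CROSS_HI + 1, :] = True
    mask[:, CROSS_LO:CROSS_HI + 1] = True
    return mask


@dataclass
class FlatField:
    """Per-pixel detector response map.

    ``response`` is normalized on construction so its mean over live pixels
    (response > 0) is 1; pixels with response <= 0 are dead.
    """

    response: np.ndarray
    geometry_state: GeometryState = GeometryState.CORRECTED516
    dead: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        resp = np.asarray(self.response, dtype=float)
        expected = _EXPECTED_SHAPE[GeometryState(self.geometry_state)]
        if resp.shape != expected:
            raise GeometryError(
                f"flatfield must be {expected}, got {resp.shape}"
            )
        self.dead = resp <= 0
        if self.dead.all():
            raise InvalidArgumentError("flatfield has no live pixels")
        mean = resp[~self.dead].mean()
        resp = resp / mean
        resp[self.dead] = 0.0
        self.response = resp


def apply_flatfield(frame: DetectorFrame, ff: FlatField) -> DetectorFrame:
    """Divide counts by the mean-normalized response; dead pixels go to 0.

    With a uniform response this is the identity.  Applying the correction
    twice with the same field divides twice — the operation is deliberately
    not idempotent and callers must apply it exactly once.
    """
    if frame.geometry_state != ff.geometry_state:
        raise GeometryError(
            f"frame is {frame.geometry_state} but flatfield is {ff.geometry_state}"
        )
    out = np.zeros_like(frame.pixels)
    live = ~ff.dead
    out[live] = frame.pixels[live] / ff.response[live]
    return DetectorFrame(
        pixels=out,
        geometry_state=frame.geometry_state,
        frame_index=frame.frame_index,
        kind=frame.kind,
        timestamp=frame.timestamp,
        exposure=frame.exposure,
    )


def untrusted_rectangle_interior(
    rect: tuple[int, int, int, int],
    shape: tuple[int, int] = (CORRECTED_SIZE, CORRECTED_SIZE),
) -> np.ndarray:
    """Boolean mask of pixels inside an XDS open-interval rectangle.

    Helper for tests and mask assembly; pixel (row r, col c) 0-based has XDS
    coordinates (x, y) = (c + 1, r + 1).
    """
    x1, x2, y1, y2 = rect
    cols = np.arange(1, shape[1] + 1)
    rows = np.arange(1, shape[0] + 1)
    in_x = (cols > x1) & (cols < x2)
    in_y = (rows > y1) & (rows < y2)
    return in_y[:, None] & in_x[None, :]
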