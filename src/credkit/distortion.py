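"""Elliptical lens-distortion model, fitting, and XDS GEO_CORR tables.

Post-specimen lens distortion maps a true circle of diffraction spots into an
ellipse.  The model here is the affine stretch that produces that ellipse:
relative to the distortion center, coordinates along the major axis are
unchanged while coordinates along the minor axis are compressed by the axis
ratio b/a = sqrt(1 - e^2).  The correction is the inverse stretch.  XDS
consumes the correction as two per-pixel offset tables (X-GEO_CORR /
Y-GEO_CORR) holding the displacement in units of 1/100 pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel

from .physics import InvalidArgumentError


class FitFailureError(RuntimeError):
    """Ellipse fit failed (degenerate or collinear input points)."""


@dataclass(frozen=True)
class DistortionModel:
    """Elliptical distortion: eccentricity, major-axis azimuth, and center.

    eccentricity : e = sqrt(1 - (b/a)^2), in [0, 1); 0 means no distortion.
    azimuth : orientation of the major axis, degrees anticlockwise from +x.
    center : (x, y) of the distortion center in logical pixels.
    """

    eccentricity: float = 0.0
    azimuth: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.eccentricity < 1.0:
            raise InvalidArgumentError("eccentricity must be in [0, 1)")

    @property
    def axis_ratio(self) -> float:
        """Minor/major axis ratio b/a = sqrt(1 - e^2)."""
        return math.sqrt(1.0 - self.eccentricity**2)

    def _frames(self) -> tuple[np.ndarray, np.ndarray]:
        phi = math.radians(self.azimuth)
        c, s = math.cos(phi), math.sin(phi)
        rot = np.array([[c, -s], [s, c]])       # ellipse frame -> lab
        return rot, rot.T

    def distort(self, points: np.ndarray) -> np.ndarray:
        """Map true (circular) positions to observed (distorted) positions."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rot, rot_inv = self._frames()
        rel = (pts - self.center) @ rot_inv.T
        rel[:, 1] *= self.axis_ratio
        return rel @ rot.T + self.center

    def correct(self, points: np.ndarray) -> np.ndarray:
        """Map observed (distorted) positions back to true positions."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rot, rot_inv = self._frames()
        rel = (pts - self.center) @ rot_inv.T
        rel[:, 1] /= self.axis_ratio
        return rel @ rot.T + self.center


def fit_elliptical_distortion(points) -> DistortionModel:
    """Least-squares ellipse fit of ring-point positions.

    Parameters
    ----------
    points : (n, 2) array of (x, y) positions sampled on one distorted
        powder/diffraction ring; n >= 5 and not collinear.

    Returns
    -------
    DistortionModel with the fitted center, major-axis azimuth and
    eccentricity.  Noiseless points on a true ellipse are recovered to
    |delta e| < 1e-3.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise InvalidArgumentError("need >= 5 (x, y) points")
    if hasattr(EllipseModel, "from_estimate"):   # scikit-image >= 0.26
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise FitFailureError("degenerate point set: ellipse fit failed")
        params = (*model.center, *model.axis_lengths, model.theta)
    else:
        model = EllipseModel()
        if not model.estimate(pts) or model.params is None:
            raise FitFailureError("degenerate point set: ellipse fit failed")
        params = tuple(model.params)
    if not np.all(np.isfinite(params)):
        raise FitFailureError("degenerate point set: ellipse fit failed")
    xc, yc, a, b, theta = params
    if a <= 0 or b <= 0:
        raise FitFailureError("ellipse fit returned non-positive axes")
    if b > a:  # enforce a = major axis; rotate azimuth by 90 deg
        a, b = b, a
        theta += math.pi / 2.0
    ecc = math.sqrt(max(0.0, 1.0 - (b / a) ** 2))
    azimuth = math.degrees(theta) % 180.0
    return DistortionModel(eccentricity=ecc, azimuth=azimuth, center=(xc, yc))


def geo_corr_tables(
    model: DistortionModel, shape: tuple[int, int] = (516, 516)
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel correction offsets in the XDS GEO_CORR encoding.

    For every pixel, the tables hold (corrected - observed) displacement in
    hundredths of a pixel, rounded to integer, as int32 arrays indexed
    [row, col] (row-major): first the x (column-direction) table, then y.
    An undistorted model (e = 0) yields all-zero tables.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    observed = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    corrected = model.correct(observed)
    delta = corrected - observed
    x_tab = np.rint(delta[:, 0].reshape(shape) * 100.0).astype(np.int32)
    y_tab = np.rint(delta[:, 1].reshape(shape) * 100.0).astype(np.int32)
    return x_tab, y_tab
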