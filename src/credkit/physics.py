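"""Electron-optics constants and derivations shared by all modules.

Electrons accelerated through a few hundred kilovolts move at a substantial
fraction of the speed of light, so the de Broglie wavelength must include the
relativistic correction term; at 200 kV the non-relativistic formula is wrong
by about 9%.  All geometry downstream (resolution rings, spot projection)
hangs off this wavelength and the effective camera length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# CODATA-2018 values.
PLANCK_H = 6.62607015e-34        # J s (exact)
ELECTRON_MASS = 9.1093837015e-31  # kg
ELEMENTARY_CHARGE = 1.602176634e-19  # C (exact)
SPEED_OF_LIGHT = 299792458.0     # m/s (exact)

#: Regular Timepix pixel pitch in micrometres.
DEFAULT_PIXEL_PITCH_UM = 55.0


class InvalidArgumentError(ValueError):
    """Raised when an operation receives an argument outside its domain."""


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in angstrom.

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2)))

    Parameters
    ----------
    voltage_kv : float
        Accelerating voltage in kilovolts (must be > 0).

    Returns
    -------
    float
        Wavelength in angstrom (0.02508 at 200 kV).
    """
    if not voltage_kv > 0:
        raise InvalidArgumentError(f"voltage must be positive, got {voltage_kv} kV")
    v = voltage_kv * 1e3
    ev = ELEMENTARY_CHARGE * v
    p = math.sqrt(
        2.0 * ELECTRON_MASS * ev
        * (1.0 + ev / (2.0 * ELECTRON_MASS * SPEED_OF_LIGHT**2))
    )
    return PLANCK_H / p * 1e10


def resolution_at_radius(radius_mm: float, camera_length_mm: float,
                         wavelength_a: float) -> float:
    """Resolution d (angstrom) of a reflection at ``radius_mm`` on the detector.

    Uses the exact Bragg relation d = lambda / (2 sin(theta)) with
    2*theta = atan(r / L).  At electron wavelengths the scattering angles are
    small, so d ~= lambda * L / r is a good approximation, but the exact form
    costs nothing.  ``radius_mm == 0`` corresponds to the direct beam and
    returns ``math.inf``.
    """
    if radius_mm < 0:
        raise InvalidArgumentError(f"radius must be >= 0, got {radius_mm}")
    if not camera_length_mm > 0:
        raise InvalidArgumentError("camera length must be positive")
    if radius_mm == 0:
        return math.inf
    two_theta = math.atan2(radius_mm, camera_length_mm)
    return wavelength_a / (2.0 * math.sin(0.5 * two_theta))


@dataclass(frozen=True)
class BeamParameters:
    """Electron beam and detector geometry used across the pipeline.

    Attributes
    ----------
    accelerating_voltage : float
        In kV.
    camera_length : float
        Effective camera length in mm (nominal 250 mm on the instrument the
        defaults describe; the effective value depends on magnification
        calibration and is treated as a free input).
    pixel_pitch : float
        Regular pixel pitch in micrometres (55 um for Timepix).
    """

    accelerating_voltage: float = 200.0
    camera_length: float = 250.0
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        if not self.accelerating_voltage > 0:
            raise InvalidArgumentError("accelerating_voltage must be > 0")
        if not self.camera_length > 0:
            raise InvalidArgumentError("camera_length must be > 0")
        if not self.pixel_pitch > 0:
            raise InvalidArgumentError("pixel_pitch must be > 0")

    @property
    def wavelength(self) -> float:
        """Relativistic wavelength in angstrom."""
        return electron_wavelength(self.accelerating_voltage)

    def resolution_at_pixel_radius(self, radius_px: float) -> float:
        """d-spacing (angstrom) at a radius given in regular pixels."""
        radius_mm = radius_px * self.pixel_pitch * 1e-3
        return resolution_at_radius(radius_mm, self.camera_length, self.wavelength)
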