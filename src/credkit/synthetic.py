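"""Rotating-crystal and screening-pattern simulator with ground truth.

Everything else in the package is testable against this module: it emits
diffraction frame series with a known beam center, known per-frame spot lists,
a known lens distortion and a known aperture-drift attenuation profile, plus
labelled single-pattern classes for the screening CNN and crystal-field maps
for the isolation filter.

The diffraction model is kinematic: reciprocal-lattice points within an
excitation tolerance of the Ewald sphere at the slot's angular midpoint are
projected onto the detector with the small-angle relation r = L * lambda / d,
rendered as Gaussian spots and Poisson noise.  No dynamical scattering, no
inelastic background model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .distortion import DistortionModel
from .frames import CORRECTED_SIZE, DetectorFrame, FrameKind, GeometryState
from .physics import InvalidArgumentError, electron_wavelength
from .schedule import AcquisitionSchedule

# --------------------------------------------------------------------------
# Crystal geometry helpers
# --------------------------------------------------------------------------

def direct_basis(cell: tuple[float, float, float, float, float, float]) -> np.ndarray:
    """Cartesian direct-basis matrix (rows = a, b, c) from cell parameters."""
    a, b, c, al, be, ga = cell
    al, be, ga = map(math.radians, (al, be, ga))
    ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
    v = np.array([
        [a, 0.0, 0.0],
        [b * cg, b * sg, 0.0],
        [c * cb, c * (ca - cb * cg) / sg, 0.0],
    ])
    v[2, 2] = math.sqrt(max(c**2 - v[2, 0]**2 - v[2, 1]**2, 0.0))
    return v


def reciprocal_basis(cell) -> np.ndarray:
    """Rows are a*, b*, c* in 1/angstrom (crystallographic, no 2*pi)."""
    return np.linalg.inv(direct_basis(cell)).T


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    t = math.radians(angle_deg)
    k = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)


def disc_overlap_fraction(offset: float, r_crystal: float, r_aperture: float) -> float:
    """Fraction of a crystal disc still inside a circular aperture.

    Standard circle-circle intersection area, normalized by the crystal-disc
    area; 1.0 when concentric and fully covered, 0.0 once disjoint.
    """
    d = abs(offset)
    r, R = r_crystal, r_aperture
    if d >= r + R:
        return 0.0
    if d <= abs(R - r):
        return 1.0 if R >= r else (R / r) ** 2
    alpha = math.acos((d * d + r * r - R * R) / (2 * d * r))
    beta = math.acos((d * d + R * R - r * r) / (2 * d * R))
    area = (r * r * (alpha - math.sin(2 * alpha) / 2)
            + R * R * (beta - math.sin(2 * beta) / 2))
    return area / (math.pi * r * r)


# --------------------------------------------------------------------------
# Rotation-series simulation
# --------------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    """Ground-truth description of one simulated cRED experiment."""

    cell: tuple[float, float, float, float, float, float] = (10.0, 10.0, 10.0, 90.0, 90.0, 90.0)
    # generic mounting orientation: a real crystal lands on the grid in a
    # random attitude, almost never zone-axis aligned with the rotation axis
    orientation: np.ndarray = field(
        default_factory=lambda: rotation_about((1.0, 2.0, 3.0), 25.0))
    rotation_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    voltage_kv: float = 200.0
    camera_length: float = 1000.0     # mm, effective
    pixel_pitch: float = 55.0         # um
    d_min: float = 1.0                # resolution cutoff, angstrom
    excitation_tolerance: float = 0.002   # reciprocal angstrom
    beam_center: tuple[float, float] = (258.0, 258.0)   # (x, y) logical px
    spot_sigma: float = 1.5           # px
    peak_counts: float = 400.0        # counts at the centre of a full spot
    beam_counts: float = 5000.0       # direct-beam peak counts
    beam_sigma: float = 4.0           # px
    background: float = 0.5           # detector floor, counts / px
    crystal_background: float = 3.0   # diffuse scatter from the crystal,
                                      # counts / px at full aperture overlap
    aperture_radius: float = 0.75     # um
    crystal_radius: float = 0.35      # um
    drift_per_slot: tuple[float, float] = (0.0, 0.0)   # um / slot
    seed: int = 0

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage_kv)


@dataclass
class SimulationTruth:
    """Per-frame ground truth emitted alongside the simulated frames."""

    beam_center: tuple[float, float]
    spots: list[list[dict]]           # per data frame: hkl, x, y, intensity, d
    attenuation: list[float]          # per data frame aperture-overlap factor
    slot_indices: list[int]           # 1-based slot index of each data frame
    drift: list[tuple[float, float]]  # per data frame crystal offset, um

    def to_dict(self) -> dict:
        return {
            "beam_center": list(self.beam_center),
            "attenuation": self.attenuation,
            "slot_indices": self.slot_indices,
            "drift": [list(d) for d in self.drift],
            "spots": self.spots,
        }


def _hkl_grid(rec: np.ndarray, d_min: float) -> np.ndarray:
    """All hkl (excluding 000) with |g| <= 1/d_min."""
    g_max = 1.0 / d_min
    lim = [int(math.ceil(g_max / np.linalg.norm(rec[i]))) + 1 for i in range(3)]
    h, k, l = np.mgrid[-lim[0]:lim[0] + 1, -lim[1]:lim[1] + 1, -lim[2]:lim[2] + 1]
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    g = hkl @ rec
    keep = np.linalg.norm(g, axis=1) <= g_max
    return hkl[keep]


def _render_spots(shape, centers, amplitudes, sigma) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    half = int(math.ceil(4 * sigma))
    for (x, y), amp in zip(centers, amplitudes):
        r0, c0 = int(round(y)), int(round(x))
        rs = slice(max(r0 - half, 0), min(r0 + half + 1, shape[0]))
        cs = slice(max(c0 - half, 0), min(c0 + half + 1, shape[1]))
        if rs.start >= rs.stop or cs.start >= cs.stop:
            continue
        yy, xx = np.mgrid[rs, cs]
        img[rs, cs] += amp * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return img


def simulate_rotation_series(
    exp: SyntheticExperiment,
    schedule: AcquisitionSchedule,
    distortion: DistortionModel | None = None,
) -> tuple[list[DetectorFrame], SimulationTruth]:
    """Render one cRED frame series on the 516x516 corrected grid.

    Data slots get kinematic diffraction patterns; defocus-tracking slots get
    a crystal-silhouette image at the drifted position.  If ``distortion`` is
    given, spot positions are forward-distorted before rendering (the direct
    beam stays at the distortion-free center, mimicking a post-specimen lens
    distortion about the beam).
    """
    rng = np.random.default_rng(exp.seed)
    rec = reciprocal_basis(exp.cell)
    hkl = _hkl_grid(rec, exp.d_min)
    if hkl.size == 0:
        warnings.warn("no reciprocal-lattice points within the resolution limit;"
                      " frames will be blank", stacklevel=2)
    lam = exp.wavelength
    k0 = 1.0 / lam
    px_mm = exp.pixel_pitch * 1e-3
    shape = (CORRECTED_SIZE, CORRECTED_SIZE)
    axis = np.asarray(exp.rotation_axis, dtype=float)
    g0 = hkl @ rec @ exp.orientation.T if hkl.size else np.zeros((0, 3))

    frames: list[DetectorFrame] = []
    truth = SimulationTruth(beam_center=exp.beam_center, spots=[],
                            attenuation=[], slot_indices=[], drift=[])
    t = schedule.start_delay
    for slot in schedule.slots:
        drift = (exp.drift_per_slot[0] * (slot.index - 1),
                 exp.drift_per_slot[1] * (slot.index - 1))
        if slot.kind == FrameKind.DATA:
            atten = disc_overlap_fraction(math.hypot(*drift),
                                          exp.crystal_radius, exp.aperture_radius)
            rot = rotation_about(axis, slot.angle_mid)
            g = g0 @ rot.T
            # excitation error: distance from the Ewald sphere centred at
            # (0, 0, -k0) with the beam along +z
            s = np.sqrt(g[:, 0]**2 + g[:, 1]**2 + (g[:, 2] + k0)**2) - k0
            sel = np.abs(s) < exp.excitation_tolerance
            gsel = g[sel]
            spots = []
            centers, amps = [], []
            if gsel.size:
                gnorm = np.linalg.norm(gsel, axis=1)
                xy = gsel[:, :2] * lam * exp.camera_length / px_mm
                pos = np.asarray(exp.beam_center) + xy
                if distortion is not None:
                    pos = distortion.distort(pos)
                partiality = 1.0 - np.abs(s[sel]) / exp.excitation_tolerance
                # simple falling form factor with resolution
                inten = exp.peak_counts * np.exp(-2.0 * (gnorm * exp.d_min) ** 2) \
                    * partiality * atten
                inside = ((pos[:, 0] > -10) & (pos[:, 0] < shape[1] + 10)
                          & (pos[:, 1] > -10) & (pos[:, 1] < shape[0] + 10))
                for p, a, m, gn in zip(pos[inside], inten[inside],
                                       hkl[sel][inside], gnorm[inside]):
                    centers.append((float(p[0]), float(p[1])))
                    amps.append(float(a))
                    spots.append({
                        "hkl": [int(v) for v in m],
                        "x": float(p[0]), "y": float(p[1]),
                        "intensity": float(a), "d": float(1.0 / gn),
                    })
            img = _render_spots(shape, centers, amps, exp.spot_sigma)
            img += _render_spots(shape, [exp.beam_center],
                                 [exp.beam_counts], exp.beam_sigma)
            # diffuse crystal scatter vanishes with the crystal's aperture
            # overlap, like the Bragg spots; the detector floor does not
            img += exp.background + exp.crystal_background * atten
            img = rng.poisson(img).astype(float)
            truth.spots.append(spots)
            truth.attenuation.append(float(atten))
            truth.slot_indices.append(slot.index)
            truth.drift.append(drift)
            kind = FrameKind.DATA
            exposure = schedule.exposure
        else:
            # defocused snapshot: a silhouette of the crystal disc, drifted
            px_per_um = 50.0
            yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
            cx = exp.beam_center[0] + drift[0] * px_per_um
            cy = exp.beam_center[1] + drift[1] * px_per_um
            disc = ((xx - cx) ** 2 + (yy - cy) ** 2
                    <= (exp.crystal_radius * px_per_um) ** 2)
            img = np.full(shape, exp.background, dtype=float)
            img[disc] += 50.0
            img = rng.poisson(img).astype(float)
            kind = FrameKind.DEFOCUS_TRACKING
            exposure = schedule.defocus_exposure
        frames.append(DetectorFrame(
            pixels=img, geometry_state=GeometryState.CORRECTED516,
            frame_index=slot.index, kind=kind, timestamp=t, exposure=exposure,
        ))
        t += schedule.frame_time
    return frames, truth


def ring_points_from_truth(truth: SimulationTruth, d_target: float,
                           rel_tol: float = 0.01) -> np.ndarray:
    """Collect spot positions whose d-spacing matches ``d_target``.

    Reflections of one |g| family lie on one circle around the beam center
    (an ellipse once a lens distortion is applied), so the accumulated
    positions across frames feed the elliptical-distortion fit.
    """
    pts = [
        (s["x"], s["y"])
        for frame in truth.spots for s in frame
        if abs(s["d"] - d_target) <= rel_tol * d_target
    ]
    return np.asarray(pts, dtype=float)


# --------------------------------------------------------------------------
# Screening pattern classes
# --------------------------------------------------------------------------

PATTERN_CLASSES = ("spots", "rings", "blank", "diffuse")
#: Label convention for the classifier: sharp single-crystal spot patterns
#: are the good class; powder rings, blanks and diffuse scatter are bad.
GOOD_CLASSES = ("spots",)


def _one_pattern(cls: str, size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.full((size, size), 3.0)
    center = (size / 2.0, size / 2.0)
    if cls == "spots":
        n = rng.integers(8, 18)
        for _ in range(n):
            x, y = rng.uniform(5, size - 5, size=2)
            amp = rng.uniform(80, 250)
            img += _render_spots((size, size), [(x, y)], [amp], 1.3)
        img += _render_spots((size, size), [center], [600.0], 2.5)
    elif cls == "rings":
        yy, xx = np.mgrid[0:size, 0:size]
        r = np.hypot(xx - center[0], yy - center[1])
        for _ in range(rng.integers(1, 4)):
            radius = rng.uniform(0.15, 0.45) * size
            width = rng.uniform(1.5, 3.0)
            amp = rng.uniform(60, 150)
            img += amp * np.exp(-((r - radius) ** 2) / (2 * width**2))
        img += _render_spots((size, size), [center], [600.0], 2.5)
    elif cls == "blank":
        img += rng.uniform(0.0, 2.0)
    elif cls == "diffuse":
        for _ in range(rng.integers(2, 5)):
            x, y = rng.uniform(0.2 * size, 0.8 * size, size=2)
            amp = rng.uniform(20, 60)
            img += _render_spots((size, size), [(x, y)], [amp],
                                 rng.uniform(8, 20))
        img += _render_spots((size, size), [center], [300.0], 4.0)
    else:
        raise InvalidArgumentError(f"unknown pattern class: {cls!r}")
    noisy = rng.poisson(img).astype(float)
    lo, hi = noisy.min(), noisy.max()
    if hi == lo:
        return np.zeros_like(noisy)
    return (noisy - lo) / (hi - lo)


def simulate_pattern_classes(
    n_per_class: int,
    classes=("spots", "rings", "blank"),
    seed: int = 0,
    size: int = 150,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Labelled, class-separable pattern images for classifier training.

    Returns (images, labels, class_names): images are (N, size, size) in
    [0, 1]; labels are 1 for good classes (spots) and 0 otherwise;
    class_names records the generating class of each image.  Deterministic
    per seed.
    """
    for cls in classes:
        if cls not in PATTERN_CLASSES:
            raise InvalidArgumentError(f"unknown pattern class: {cls!r}")
    rng = np.random.default_rng(seed)
    images, labels, names = [], [], []
    for cls in classes:
        for _ in range(n_per_class):
            images.append(_one_pattern(cls, size, rng))
            labels.append(1 if cls in GOOD_CLASSES else 0)
            names.append(cls)
    return np.asarray(images, dtype=np.float32), np.asarray(labels), names


# --------------------------------------------------------------------------
# Crystal-field maps for the isolation filter
# --------------------------------------------------------------------------

def simulate_crystal_field(
    area: float = 200.0,
    n_crystals: int = 100,
    seed: int = 0,
    planted_close_pairs: int = 3,
    pair_distance: float = 1.0,
) -> dict:
    """Random crystal map over an ``area`` x ``area`` micrometre frame.

    Positions uniform, sizes lognormal; ``planted_close_pairs`` extra
    crystals are placed ``pair_distance`` um from an existing one so the
    isolation filter always has pairs to reject.
    """
    rng = np.random.default_rng(seed)
    frame = (0.0, area, 0.0, area)
    pos = rng.uniform(0.0, area, size=(n_crystals, 2))
    if n_crystals > 0:
        n_pairs = min(planted_close_pairs, n_crystals)
        mates = []
        for i in range(n_pairs):
            theta = rng.uniform(0, 2 * math.pi)
            mates.append(pos[i] + pair_distance * np.array(
                [math.cos(theta), math.sin(theta)]))
        if mates:
            pos = np.vstack([pos, mates])
    sizes = rng.lognormal(mean=math.log(0.5), sigma=0.4, size=len(pos))
    return {"positions": pos, "sizes": sizes, "frame": frame,
            "planted_pair_indices": list(range(min(planted_close_pairs, n_crystals)))}
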