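"""Frame and instruction-file I/O: SMV, TIFF, MRC, XDS, DIALS, REDp, logs.

Corrected 516x516 frames are written as SMV (ADSC dialect: a 512-byte ASCII
key=value header followed by little-endian unsigned 16-bit counts), the format
XDS and DIALS read directly.  TIFF carries the same metadata in its
description tag (JSON); MRC in a text extended header.  Instruction files
translate the schedule, beam center and distortion model into what each
processing package expects:

* XDS.INP — OSCILLATION_RANGE / DATA_RANGE / ORGX,ORGY / UNTRUSTED_RECTANGLE
  for the module cross / one EXCLUDE_DATA_RANGE per defocus gap / GEO_CORR
  references when a distortion is present;
* DIALS — scan_range= tokens for dials.find_spots and exclude_images= tokens
  for dials.integrate;
* REDp — a per-frame tilt-angle table.

All writers are deterministic byte-for-byte given identical inputs.  Angles
print with 4 decimals and wavelengths with 5, matching how acquisition run
tables report them.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .beamcenter import BeamCenterEstimate
from .distortion import DistortionModel, geo_corr_tables
from .frames import (CORRECTED_SIZE, DetectorFrame, GeometryState,
                     cross_untrusted_rectangles)
from .physics import BeamParameters, InvalidArgumentError
from .schedule import AcquisitionSchedule, RotationMetadata, dials_exclusions, excluded_ranges

SMV_HEADER_BYTES = 512


class SmvParseError(ValueError):
    """Malformed SMV header; message names the offending key."""


@dataclass
class SmvHeader:
    """ADSC-dialect SMV header fields (mm, angstrom, degrees, seconds)."""

    size1: int = CORRECTED_SIZE
    size2: int = CORRECTED_SIZE
    pixel_size: float = 0.055
    distance: float = 250.0
    wavelength: float = 0.02508
    beam_center_x: float = 0.0
    beam_center_y: float = 0.0
    osc_start: float = 0.0
    osc_range: float = 0.0
    exposure: float = 0.5


def write_smv(frame: DetectorFrame, header: SmvHeader, path) -> Path:
    """Write a corrected frame as SMV; counts clamped to [0, 65535]."""
    if frame.geometry_state != GeometryState.CORRECTED516:
        raise InvalidArgumentError("SMV export expects corrected516 frames")
    path = Path(path)
    data = np.rint(np.clip(frame.pixels, 0, 65535)).astype("<u2")
    lines = [
        "{",
        f"HEADER_BYTES= {SMV_HEADER_BYTES};",
        "DIM=2;",
        "BYTE_ORDER=little_endian;",
        "TYPE=unsigned_short;",
        f"SIZE1={header.size1};",
        f"SIZE2={header.size2};",
        f"PIXEL_SIZE={header.pixel_size:.6f};",
        "BIN=1x1;",
        f"DISTANCE={header.distance:.4f};",
        f"WAVELENGTH={header.wavelength:.5f};",
        f"OSC_START={header.osc_start:.4f};",
        f"OSC_RANGE={header.osc_range:.4f};",
        f"PHI={header.osc_start:.4f};",
        f"BEAM_CENTER_X={header.beam_center_x:.4f};",
        f"BEAM_CENTER_Y={header.beam_center_y:.4f};",
        f"TIME={header.exposure:.6f};",
        "}\n",
    ]
    text = "\n".join(lines).encode("ascii")
    if len(text) > SMV_HEADER_BYTES:
        raise InvalidArgumentError("SMV header exceeds 512 bytes")
    with path.open("wb") as fh:
        fh.write(text.ljust(SMV_HEADER_BYTES, b"\x00"))
        fh.write(data.tobytes())
    return path


def read_smv(path) -> tuple[DetectorFrame, SmvHeader]:
    """Read an SMV file written by :func:`write_smv` (bit-exact round trip)."""
    raw = Path(path).read_bytes()
    head = raw[:SMV_HEADER_BYTES].decode("ascii", errors="replace")
    fields: dict[str, str] = {}
    for line in head.splitlines():
        line = line.strip().rstrip("\x00")
        if line in ("{", "}") or not line:
            continue
        if "=" not in line:
            raise SmvParseError(f"malformed header line: {line!r}")
        key, val = line.split("=", 1)
        fields[key.strip()] = val.strip().rstrip(";")

    def need(key: str) -> str:
        if key not in fields:
            raise SmvParseError(f"missing SMV header key: {key}")
        return fields[key]

    try:
        size1, size2 = int(need("SIZE1")), int(need("SIZE2"))
    except ValueError as exc:
        raise SmvParseError(f"bad SIZE1/SIZE2: {exc}") from exc
    if need("TYPE") != "unsigned_short":
        raise SmvParseError(f"unsupported TYPE: {fields['TYPE']}")
    header = SmvHeader(
        size1=size1, size2=size2,
        pixel_size=float(need("PIXEL_SIZE")),
        distance=float(need("DISTANCE")),
        wavelength=float(need("WAVELENGTH")),
        beam_center_x=float(need("BEAM_CENTER_X")),
        beam_center_y=float(need("BEAM_CENTER_Y")),
        osc_start=float(need("OSC_START")),
        osc_range=float(need("OSC_RANGE")),
        exposure=float(need("TIME")),
    )
    n = size1 * size2
    pixels = np.frombuffer(
        raw[SMV_HEADER_BYTES:SMV_HEADER_BYTES + 2 * n], dtype="<u2"
    ).reshape(size2, size1).astype(float)
    frame = DetectorFrame(pixels=pixels, geometry_state=GeometryState.CORRECTED516)
    return frame, header


# --------------------------------------------------------------------------
# TIFF / MRC
# --------------------------------------------------------------------------

def write_tiff(frame: DetectorFrame, metadata: dict, path) -> Path:
    """uint16 TIFF with JSON metadata in the image-description tag."""
    path = Path(path)
    data = np.rint(np.clip(frame.pixels, 0, 65535)).astype(np.uint16)
    tifffile.imwrite(path, data, description=json.dumps(metadata, sort_keys=True))
    return path


def read_tiff(path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return data.astype(float), meta


def write_mrc(frame: DetectorFrame, metadata: dict, path) -> Path:
    """Minimal MRC-2014 (mode 6, uint16) with JSON metadata as extended header."""
    path = Path(path)
    data = np.rint(np.clip(frame.pixels, 0, 65535)).astype("<u2")
    ny, nx = data.shape
    ext = json.dumps(metadata, sort_keys=True).encode("ascii")
    ext = ext.ljust((len(ext) + 79) // 80 * 80, b"\x00")
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, 1)      # NX NY NZ
    struct.pack_into("<i", header, 12, 6)              # MODE 6 = uint16
    struct.pack_into("<3i", header, 28, nx, ny, 1)     # MX MY MZ
    struct.pack_into("<3f", header, 40, float(nx), float(ny), 1.0)  # CELL A
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)       # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 92, len(ext))       # NSYMBT
    header[104:108] = b"json"                          # EXTTYP
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    with path.open("wb") as fh:
        fh.write(bytes(header))
        fh.write(ext)
        fh.write(data.tobytes())
    return path


def read_mrc(path) -> tuple[np.ndarray, dict]:
    raw = Path(path).read_bytes()
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    mode, = struct.unpack_from("<i", raw, 12)
    if mode != 6:
        raise InvalidArgumentError(f"unsupported MRC mode {mode}")
    nsymbt, = struct.unpack_from("<i", raw, 92)
    ext = raw[1024:1024 + nsymbt].rstrip(b"\x00")
    meta = json.loads(ext) if ext else {}
    off = 1024 + nsymbt
    data = np.frombuffer(raw[off:off + 2 * nx * ny], dtype="<u2").reshape(ny, nx)
    return data.astype(float), meta


# --------------------------------------------------------------------------
# Instruction files
# --------------------------------------------------------------------------

def write_xds_inp(
    schedule: AcquisitionSchedule,
    beam_center: tuple[float, float] | BeamCenterEstimate | None,
    distortion: DistortionModel | None,
    beamparams: BeamParameters,
    path,
    template: str = "data/?????.img",
    geo_corr_prefix: str = "GEO_CORR",
) -> Path:
    """Emit XDS.INP from the schedule, beam center and distortion model.

    ORGX/ORGY are 1-based XDS pixel coordinates of the (0-based) logical beam
    center.  One EXCLUDE_DATA_RANGE line per defocus gap; GEO_CORR references
    only when the distortion eccentricity is non-zero.
    """
    if beam_center is None:
        raise InvalidArgumentError(
            "no beam-center estimate: run beam-center estimation before export")
    if isinstance(beam_center, BeamCenterEstimate):
        beam_center = beam_center.position
    path = Path(path)
    osc = schedule.oscillation_per_slot
    lines = [
        "JOB= XYCORR INIT COLSPOT IDXREF DEFPIX INTEGRATE CORRECT",
        f"NAME_TEMPLATE_OF_DATA_FRAMES= {template} SMV",
        f"DATA_RANGE= 1 {schedule.n_slots}",
        f"STARTING_ANGLE= {schedule.start_angle:.4f}",
        f"OSCILLATION_RANGE= {osc:.4f}",
        f"STARTING_FRAME= 1",
        f"ORGX= {beam_center[0] + 1:.4f} ORGY= {beam_center[1] + 1:.4f}",
        f"DETECTOR_DISTANCE= {beamparams.camera_length:.4f}",
        f"NX= {CORRECTED_SIZE} NY= {CORRECTED_SIZE}"
        f" QX= {beamparams.pixel_pitch * 1e-3:.6f}"
        f" QY= {beamparams.pixel_pitch * 1e-3:.6f}",
        f"X-RAY_WAVELENGTH= {beamparams.wavelength:.5f}",
        "ROTATION_AXIS= 1.0 0.0 0.0",
        "DETECTOR= ADSC MINIMUM_VALID_PIXEL_VALUE= 1 OVERLOAD= 65000",
        "TRUSTED_REGION= 0.0 1.4",
    ]
    for rect in cross_untrusted_rectangles():
        lines.append("UNTRUSTED_RECTANGLE= " + " ".join(str(v) for v in rect))
    for lo, hi in excluded_ranges(schedule):
        lines.append(f"EXCLUDE_DATA_RANGE= {lo} {hi}")
    if distortion is not None and distortion.eccentricity > 0:
        lines.append(f"X-GEO_CORR= {geo_corr_prefix}_X.img")
        lines.append(f"Y-GEO_CORR= {geo_corr_prefix}_Y.img")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_geo_corr_smv(model: DistortionModel, directory,
                       prefix: str = "GEO_CORR") -> tuple[Path, Path]:
    """GEO_CORR offset tables as SMV images (offsets in 1/100 px, biased).

    XDS reads GEO_CORR tables as unsigned SMV images; offsets are stored with
    a +32768 bias to fit negative values into uint16.
    """
    directory = Path(directory)
    x_tab, y_tab = geo_corr_tables(model)
    paths = []
    for tab, suffix in ((x_tab, "X"), (y_tab, "Y")):
        biased = tab.astype(np.int64) + 32768
        if biased.min() < 0 or biased.max() > 65535:
            raise InvalidArgumentError("GEO_CORR offsets out of uint16 range")
        frame = DetectorFrame(pixels=biased.astype(float),
                              geometry_state=GeometryState.CORRECTED516)
        p = directory / f"{prefix}_{suffix}.img"
        write_smv(frame, SmvHeader(), p)
        paths.append(p)
    return paths[0], paths[1]


def format_dials_ranges(schedule: AcquisitionSchedule) -> dict[str, list[str]]:
    """DIALS command-line tokens for the gap structure."""
    ex = dials_exclusions(schedule)
    return {
        "scan_range": [f"scan_range={lo},{hi}" for lo, hi in ex["scan_range"]],
        "exclude_images": [f"exclude_images={lo}:{hi}"
                           for lo, hi in ex["exclude_images"]],
    }


def write_dials_params(schedule: AcquisitionSchedule, path) -> Path:
    """Two-line parameter file: find_spots scan_range, integrate exclude_images."""
    tokens = format_dials_ranges(schedule)
    path = Path(path)
    lines = [
        "dials.find_spots " + " ".join(tokens["scan_range"]),
        "dials.integrate " + " ".join(tokens["exclude_images"]),
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def parse_dials_params(path) -> dict[str, list[tuple[int, int]]]:
    """Parse a file written by :func:`write_dials_params` back into ranges."""
    out: dict[str, list[tuple[int, int]]] = {"scan_range": [], "exclude_images": []}
    for line in Path(path).read_text().splitlines():
        for token in line.split():
            if token.startswith("scan_range="):
                lo, hi = token.split("=")[1].split(",")
                out["scan_range"].append((int(lo), int(hi)))
            elif token.startswith("exclude_images="):
                lo, hi = token.split("=")[1].split(":")
                out["exclude_images"].append((int(lo), int(hi)))
    return out


def write_redp(schedule: AcquisitionSchedule, path) -> Path:
    """REDp-style per-frame tilt table: data-frame number and midpoint angle."""
    path = Path(path)
    lines = ["# frame  tilt_angle(deg)"]
    for n, slot in enumerate(schedule.data_slots(), start=1):
        lines.append(f"{n:6d}  {slot.angle_mid:10.4f}")
    path.write_text("\n".join(lines) + "\n")
    return path


# --------------------------------------------------------------------------
# Experiment log and output directories
# --------------------------------------------------------------------------

def next_experiment_dir(root, prefix: str = "exp_", width: int = 6,
                        limit: int = 999_999) -> Path:
    """Create and return the next free numbered directory under ``root``.

    Successive calls yield exp_000001, exp_000002, ...; existing directories
    are never reused or overwritten.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for i in range(1, limit + 1):
        candidate = root / f"{prefix}{i:0{width}d}"
        if not candidate.exists():
            candidate.mkdir()
            return candidate
    raise IOError(f"no free experiment directory under {root} (limit {limit})")


def write_experiment_log(metadata: RotationMetadata, path) -> Path:
    """YAML log of all run-level parameters."""
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(metadata.to_dict(), fh, sort_keys=True)
    return path


def read_experiment_log(path) -> RotationMetadata:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    return RotationMetadata(**data)
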