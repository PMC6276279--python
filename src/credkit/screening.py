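"""SerialED crystal screening: preprocessing, CNN scoring, candidate selection.

A SerialED run yields one still diffraction pattern per crystal plus the
crystal's position and size from low-magnification imaging.  Screening decides
which crystals are worth a full rotation experiment: patterns are normalized
into a form a small CNN can score (good/bad), and crystals that are too close
to a neighbour or to the image edge are discarded because the beam cannot be
placed on them cleanly.  Survivors go into a candidates CSV that the
acquisition side can recall stage positions from.

Preprocessing pipeline (in order): locate the primary beam as the centroid of
the top 5% brightest pixels; crop 400x400 around it (zero-padding outside the
detector) so the strongest feature is centered at constant resolution; cap
intensities at mu + 4*sigma of the crop so the direct beam does not dwarf the
spots; feature-scale to [0, 1] (all zeros if the crop is constant); shrink to
150x150 by local-mean resampling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.transform import resize_local_mean

from .beamcenter import center_top_percentile
from .nn import BinaryCnn, CnnConfig
from .physics import InvalidArgumentError

CROP_SIZE = 400
OUTPUT_SIZE = 150
CAP_SIGMAS = 4.0
SCORE_THRESHOLD = 0.5   # strictly greater than 0.5 classifies as good


class PatternStage(str, Enum):
    RAW = "raw"
    CROPPED400 = "cropped400"
    CAPPED = "capped"
    NORMALIZED = "normalized"
    RESIZED150 = "resized150"


@dataclass
class PatternImage:
    """A diffraction pattern at some stage of the screening pipeline."""

    z: np.ndarray
    stage: PatternStage

    @property
    def mu(self) -> float:
        return float(self.z.mean())

    @property
    def sigma(self) -> float:
        return float(self.z.std())

    @property
    def z_min(self) -> float:
        return float(self.z.min())

    @property
    def z_max(self) -> float:
        return float(self.z.max())


def crop_about_beam(pattern: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Crop ``size`` x ``size`` pixels centered on the primary beam.

    Regions of the window falling outside the detector are zero-padded, so a
    beam near a corner still ends up at the window center.
    """
    est = center_top_percentile(pattern)
    cx, cy = est.position
    r0 = int(round(cy)) - size // 2
    c0 = int(round(cx)) - size // 2
    out = np.zeros((size, size), dtype=float)
    rows, cols = pattern.shape
    src_r = slice(max(r0, 0), min(r0 + size, rows))
    src_c = slice(max(c0, 0), min(c0 + size, cols))
    dst_r = slice(src_r.start - r0, src_r.stop - r0)
    dst_c = slice(src_c.start - c0, src_c.stop - c0)
    out[dst_r, dst_c] = pattern[src_r, src_c]
    return out


def cap_intensity(z: np.ndarray, n_sigma: float = CAP_SIGMAS) -> np.ndarray:
    """Clip values above mean + n_sigma * std (moments of ``z`` itself)."""
    return np.minimum(z, z.mean() + n_sigma * z.std())


def feature_scale(z: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a constant image maps to all zeros."""
    zmin, zmax = z.min(), z.max()
    if zmax == zmin:
        return np.zeros_like(z, dtype=float)
    return (z - zmin) / (zmax - zmin)


def preprocess(pattern: np.ndarray) -> PatternImage:
    """Full screening preprocessing; returns a 150x150 image in [0, 1]."""
    pattern = np.asarray(pattern, dtype=float)
    if pattern.size == 0 or pattern.ndim != 2:
        raise InvalidArgumentError("pattern must be a non-empty 2-D array")
    crop = crop_about_beam(pattern)
    capped = cap_intensity(crop)
    scaled = feature_scale(capped)
    small = resize_local_mean(scaled, (OUTPUT_SIZE, OUTPUT_SIZE))
    # local-mean resampling is a convex combination; clip guards rounding
    small = np.clip(small, 0.0, 1.0)
    return PatternImage(z=small, stage=PatternStage.RESIZED150)


# --------------------------------------------------------------------------
# CNN classification
# --------------------------------------------------------------------------

def train_classifier(
    train_images: np.ndarray,
    train_labels: Sequence[int],
    val_images: np.ndarray | None = None,
    val_labels: Sequence[int] | None = None,
    seed: int = 0,
    config: CnnConfig | None = None,
    verbose: bool = False,
) -> BinaryCnn:
    """Train the good/bad pattern classifier.

    Protocol: batches of 75 images, 20 epochs, dropout 0.15, binary
    cross-entropy loss, RMSprop optimizer; ReLU in all hidden layers and a
    logistic output.  Labels: 1 = good, 0 = bad.  Deterministic given
    ``seed``.  The returned model carries the per-epoch accuracy/loss trace
    in ``model.history``.
    """
    cfg = config or CnnConfig()
    model = BinaryCnn(cfg, seed=seed)
    model.fit(train_images, np.asarray(train_labels),
              val_images=val_images,
              val_labels=None if val_labels is None else np.asarray(val_labels),
              seed=seed + 1, verbose=verbose)
    return model


def predict_score(model: BinaryCnn, img: PatternImage | np.ndarray) -> float:
    """Prediction score in [0, 1]; > 0.5 means a good-quality pattern."""
    z = img.z if isinstance(img, PatternImage) else np.asarray(img)
    if z.shape != tuple(model.config.input_shape):
        raise InvalidArgumentError(
            f"expected {model.config.input_shape} image, got {z.shape}"
        )
    return float(model.predict_proba(z)[0])


def is_good(score: float) -> bool:
    """Strictly greater than 0.5; a tie at exactly 0.5 is classified bad."""
    return score > SCORE_THRESHOLD


# --------------------------------------------------------------------------
# Candidate selection
# --------------------------------------------------------------------------

def isolation_filter(
    positions: np.ndarray,
    frame: tuple[float, float, float, float],
    neighbor_min: float = 1.5,
    edge_min: float = 0.5,
) -> np.ndarray:
    """Indices of crystals that are isolated and away from the frame edge.

    A crystal survives iff its nearest neighbour is at least ``neighbor_min``
    (micrometres) away — both members of a closer pair are discarded — and it
    lies at least ``edge_min`` from every edge of ``frame``
    (xmin, xmax, ymin, ymax).
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.size == 0:
        return np.empty(0, dtype=int)
    if not np.all(np.isfinite(pos)):
        raise InvalidArgumentError("positions must be finite")
    xmin, xmax, ymin, ymax = frame
    edge_ok = (
        (pos[:, 0] - xmin >= edge_min) & (xmax - pos[:, 0] >= edge_min)
        & (pos[:, 1] - ymin >= edge_min) & (ymax - pos[:, 1] >= edge_min)
    )
    if len(pos) == 1:
        neighbor_ok = np.array([True])
    else:
        tree = cKDTree(pos)
        dist, _ = tree.query(pos, k=2)
        neighbor_ok = dist[:, 1] >= neighbor_min
    return np.flatnonzero(edge_ok & neighbor_ok)


@dataclass(frozen=True)
class CrystalCandidate:
    """One row of the screening candidates table."""

    image_path: str
    image_seq: int
    crystal_seq: int
    score: float
    object_size: float   # micrometres
    stage_x: float       # micrometres
    stage_y: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise InvalidArgumentError("score must be in [0, 1]")


CSV_COLUMNS = ("image_path", "image_seq", "crystal_seq", "score",
               "object_size", "stage_x", "stage_y")


def write_candidates(candidates: Sequence[CrystalCandidate], path) -> Path:
    """Write the candidates CSV: header + one row per crystal.

    Scores are printed with 4 decimals; positions and sizes at full
    precision.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for c in candidates:
            writer.writerow([
                c.image_path, c.image_seq, c.crystal_seq,
                f"{c.score:.4f}", repr(c.object_size),
                repr(c.stage_x), repr(c.stage_y),
            ])
    return path


def read_candidates(path) -> list[CrystalCandidate]:
    """Read a candidates CSV written by :func:`write_candidates`."""
    out = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != CSV_COLUMNS:
            raise InvalidArgumentError(
                f"unexpected candidate CSV columns: {reader.fieldnames}"
            )
        for row in reader:
            out.append(CrystalCandidate(
                image_path=row["image_path"],
                image_seq=int(row["image_seq"]),
                crystal_seq=int(row["crystal_seq"]),
                score=float(row["score"]),
                object_size=float(row["object_size"]),
                stage_x=float(row["stage_x"]),
                stage_y=float(row["stage_y"]),
            ))
    return out
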