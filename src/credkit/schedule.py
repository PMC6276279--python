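"""cRED acquisition timeline: data frames, defocus-tracking frames, angles.

During continuous-rotation data collection the goniometer never stops.  Every
``n_interval`` data frames, one full frame slot is spent defocusing the
diffraction pattern to image the crystal for tracking; that slot's rotation
range is lost from the diffraction data.  Because every slot (data or
defocus) lasts exactly one ``frame_time``, each gap covers exactly one frame's
oscillation, which is what integration software requires for the missing
images to be consistent with the rest.

Cycle convention: ``n_interval`` data frames, then one defocus slot.  A run of
430 data frames at n_interval = 10 therefore contains 43 defocus slots (473
slots total), and 554 data frames contain 55 (trailing partial cycles get no
defocus slot).  Frame numbering is 1-based inclusive everywhere, matching the
XDS/DIALS convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .frames import FrameKind
from .physics import InvalidArgumentError

#: Goniometer settling delay before the first frame, seconds.
DEFAULT_START_DELAY = 0.2


def tilt_range(start: float, end: float) -> float:
    """Absolute rotation range |end - start| in degrees."""
    return abs(end - start)


def oscillation_angle(tilt_range_deg: float, total_time: float,
                      frame_time: float) -> float:
    """Per-frame oscillation: rotation range divided by the collection time,
    times the slot duration.

    E.g. a 102.55 deg run over 224.7 s at 0.512 s per slot gives
    0.2336 deg/frame.
    """
    if not total_time > 0 or not frame_time > 0:
        raise InvalidArgumentError("times must be positive")
    return tilt_range_deg / total_time * frame_time


@dataclass(frozen=True)
class Slot:
    index: int                 # 1-based
    kind: FrameKind
    angle_start: float
    angle_end: float

    @property
    def angle_mid(self) -> float:
        return 0.5 * (self.angle_start + self.angle_end)


@dataclass
class AcquisitionSchedule:
    """Slot-by-slot plan of one cRED run."""

    n_interval: int = 10
    frame_time: float = 0.512
    exposure: float = 0.5
    defocus_exposure: float = 0.01
    start_angle: float = 0.0
    rotation_speed: float = 0.45   # deg/s
    start_delay: float = DEFAULT_START_DELAY
    slots: list[Slot] = field(default_factory=list)

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def n_data_frames(self) -> int:
        return sum(1 for s in self.slots if s.kind == FrameKind.DATA)

    @property
    def n_defocus_frames(self) -> int:
        return sum(1 for s in self.slots if s.kind == FrameKind.DEFOCUS_TRACKING)

    @property
    def end_angle(self) -> float:
        return self.slots[-1].angle_end if self.slots else self.start_angle

    @property
    def oscillation_per_slot(self) -> float:
        return self.rotation_speed * self.frame_time

    @property
    def total_time(self) -> float:
        return self.n_slots * self.frame_time

    def data_slots(self) -> list[Slot]:
        return [s for s in self.slots if s.kind == FrameKind.DATA]

    def slot_time(self, index: int) -> float:
        """Start time of slot ``index`` (1-based), including the start delay."""
        return self.start_delay + (index - 1) * self.frame_time


def build_schedule(
    n_data: int,
    n_interval: int = 10,
    frame_time: float = 0.512,
    start_angle: float = 0.0,
    rotation_speed: float = 0.45,
    exposure: float = 0.5,
    defocus_exposure: float = 0.01,
    start_delay: float = DEFAULT_START_DELAY,
) -> AcquisitionSchedule:
    """Lay out ``n_data`` data frames with a defocus slot after every
    ``n_interval`` of them.

    Every slot spans ``rotation_speed * frame_time`` degrees; a trailing
    partial cycle gets no defocus slot, so the total slot count is
    ``n_data + floor(n_data / n_interval)``.
    """
    if n_data < 1:
        raise InvalidArgumentError("n_data must be >= 1")
    if n_interval < 1:
        raise InvalidArgumentError("n_interval must be >= 1")
    if not frame_time > 0:
        raise InvalidArgumentError("frame_time must be positive")
    osc = rotation_speed * frame_time
    slots: list[Slot] = []
    data_emitted = 0
    index = 1

    def add(kind: FrameKind) -> None:
        nonlocal index
        a0 = start_angle + (index - 1) * osc
        slots.append(Slot(index=index, kind=kind,
                          angle_start=a0, angle_end=a0 + osc))
        index += 1

    while data_emitted < n_data:
        add(FrameKind.DATA)
        data_emitted += 1
        if data_emitted % n_interval == 0:
            add(FrameKind.DEFOCUS_TRACKING)

    return AcquisitionSchedule(
        n_interval=n_interval,
        frame_time=frame_time,
        exposure=exposure,
        defocus_exposure=defocus_exposure,
        start_angle=start_angle,
        rotation_speed=rotation_speed,
        start_delay=start_delay,
        slots=slots,
    )


def excluded_ranges(schedule: AcquisitionSchedule) -> list[tuple[int, int]]:
    """Maximal runs of defocus-tracking slot indices, 1-based inclusive.

    These are the frame ranges XDS must skip (EXCLUDE_DATA_RANGE): sorted,
    disjoint, and complementary to the data slots.
    """
    ranges: list[tuple[int, int]] = []
    run_start = None
    prev = None
    for slot in schedule.slots:
        if slot.kind == FrameKind.DEFOCUS_TRACKING:
            if run_start is None:
                run_start = slot.index
            elif slot.index != prev + 1:
                ranges.append((run_start, prev))
                run_start = slot.index
            prev = slot.index
        else:
            if run_start is not None:
                ranges.append((run_start, prev))
                run_start = None
    if run_start is not None:
        ranges.append((run_start, prev))
    return ranges


def dials_exclusions(schedule: AcquisitionSchedule) -> dict[str, list[tuple[int, int]]]:
    """DIALS view of the same gaps: ``scan_range`` runs of data frames (for
    dials.find_spots) and ``exclude_images`` ranges (for dials.integrate).

    The two lists partition [1, n_slots].
    """
    excl = excluded_ranges(schedule)
    n = schedule.n_slots
    scan: list[tuple[int, int]] = []
    pos = 1
    for lo, hi in excl:
        if lo > pos:
            scan.append((pos, lo - 1))
        pos = hi + 1
    if pos <= n:
        scan.append((pos, n))
    return {"scan_range": scan, "exclude_images": excl}


@dataclass
class RotationMetadata:
    """Derived run-level numbers mirroring an experiment-log table."""

    tilt_range: float
    total_time: float
    rotation_speed: float
    oscillation_angle: float
    n_data_frames: int
    n_defocus_frames: int
    start_angle: float
    end_angle: float
    exposure: float
    frame_time: float
    spot_size: int = 2
    camera_length: float = 250.0
    aperture_radius: float = 0.75

    @classmethod
    def from_schedule(cls, schedule: AcquisitionSchedule, *, spot_size: int = 2,
                      camera_length: float = 250.0,
                      aperture_radius: float = 0.75) -> "RotationMetadata":
        tr = tilt_range(schedule.start_angle, schedule.end_angle)
        total = schedule.total_time
        return cls(
            tilt_range=tr,
            total_time=total,
            rotation_speed=schedule.rotation_speed,
            oscillation_angle=oscillation_angle(tr, total, schedule.frame_time),
            n_data_frames=schedule.n_data_frames,
            n_defocus_frames=schedule.n_defocus_frames,
            start_angle=schedule.start_angle,
            end_angle=schedule.end_angle,
            exposure=schedule.exposure,
            frame_time=schedule.frame_time,
            spot_size=spot_size,
            camera_length=camera_length,
            aperture_radius=aperture_radius,
        )

    def to_dict(self) -> dict:
        return asdict(self)
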