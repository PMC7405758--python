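"""Shared geometry, units, sign conventions and condition vocabulary.

All positions are stored internally on the *screen axis*: signed degrees of
visual angle, positive rightward from screen center.  Two derived axes are
used only at analysis boundaries:

* the *eccentricity axis* — positive away from screen center within the
  hemifield the stimuli were shown in, so left- and right-hemifield trials
  can be pooled; and
* the *retinal axis* — position relative to the fovea, positive away from
  the fovea within the stimulus hemifield.

Only the horizontal dimension is modelled; the small vertical offsets of the
reference/target pair are metadata and never analyzed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np


class InvalidGeometryError(ValueError):
    """Raised for physically impossible screen geometry (e.g. distance <= 0)."""


class Task(str, enum.Enum):
    FIXATION_RELATIVE = "fixation_relative"
    PURSUIT_RELATIVE = "pursuit_relative"
    PURSUIT_ABSOLUTE = "pursuit_absolute"


class Phase(str, enum.Enum):
    COARSE = "coarse"
    FINE1 = "fine1"
    FINE2 = "fine2"
    NA = "n/a"


class Hemifield(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class PursuitDirection(str, enum.Enum):
    LEFTWARD = "leftward"
    RIGHTWARD = "rightward"
    NONE = "none"


class Placement(str, enum.Enum):
    AHEAD = "ahead"
    BEHIND = "behind"
    NA = "n/a"


#: The three stimulus onset asynchronies of the design, in ms (signed:
#: positive = target flashed after the reference).
SOAS_MS = (-200, 0, 200)

#: Eccentricity of the reference stimulus (and of the absolute-task target)
#: on the screen, degrees from center.
REFERENCE_ECCENTRICITY_DEG = 7.5

#: Pursuit target speed in deg/s.
PURSUIT_SPEED_DEG_S = 10.0

#: Sampling rate of the gaze recording, Hz.
SAMPLE_RATE_HZ = 500
SAMPLE_DT_MS = 1000.0 / SAMPLE_RATE_HZ

#: Trial durations, ms.
FIXATION_TRIAL_MS = 1750
PURSUIT_TRIAL_MS = 2500

#: Time of the reference flash (pursuit target crosses screen center), ms.
REFERENCE_FLASH_MS = 1250.0


@dataclass(frozen=True)
class ScreenGeometry:
    """Flat projection screen viewed head-on at a fixed distance.

    Defaults describe a 120 x 90 cm screen at 70 cm, i.e. roughly
    81 deg x 65 deg of visual angle, 1152 x 864 px at 120 Hz.
    """

    width_cm: float = 120.0
    height_cm: float = 90.0
    viewing_distance_cm: float = 70.0
    resolution_px: tuple[int, int] = (1152, 864)
    refresh_hz: float = 120.0

    def __post_init__(self) -> None:
        for name in ("width_cm", "height_cm", "viewing_distance_cm", "refresh_hz"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be positive")
        if any(r <= 0 for r in self.resolution_px):
            raise InvalidGeometryError("resolution_px must be positive")

    @property
    def frame_duration_ms(self) -> float:
        return 1000.0 / self.refresh_hz

    @property
    def width_deg(self) -> float:
        """Full horizontal extent in degrees (arctangent per half-screen)."""
        return 2.0 * cm_to_deg(self.width_cm / 2.0, self.viewing_distance_cm)

    @property
    def height_deg(self) -> float:
        return 2.0 * cm_to_deg(self.height_cm / 2.0, self.viewing_distance_cm)


@dataclass(frozen=True)
class Condition:
    """One cell of the design: task x phase x geometry x timing.

    Invariants: the fixation task has no pursuit direction and no placement;
    pursuit tasks must name a placement (flashes ahead of or behind the
    moving pursuit target along its direction of motion).
    """

    task: Task
    hemifield: Hemifield
    soa_ms: int
    phase: Phase = Phase.NA
    pursuit_direction: PursuitDirection = PursuitDirection.NONE
    placement: Placement = Placement.NA

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(self, "hemifield", Hemifield(self.hemifield))
        object.__setattr__(
            self, "pursuit_direction", PursuitDirection(self.pursuit_direction)
        )
        object.__setattr__(self, "placement", Placement(self.placement))
        if self.soa_ms not in SOAS_MS:
            raise ValueError(f"soa_ms must be one of {SOAS_MS}, got {self.soa_ms}")
        if self.task is Task.FIXATION_RELATIVE:
            if self.pursuit_direction is not PursuitDirection.NONE:
                raise ValueError("fixation task has pursuit_direction=none")
            if self.placement is not Placement.NA:
                raise ValueError("fixation task has placement=n/a")
        else:
            if self.pursuit_direction is PursuitDirection.NONE:
                raise ValueError("pursuit tasks need a pursuit direction")
            if self.placement is Placement.NA:
                raise ValueError("pursuit tasks need placement ahead/behind")
            expected = expected_hemifield(self.pursuit_direction, self.placement)
            if self.hemifield is not expected:
                raise ValueError(
                    f"{self.pursuit_direction.value}/{self.placement.value} flashes "
                    f"fall in the {expected.value} hemifield, got {self.hemifield.value}"
                )

    @property
    def is_pursuit(self) -> bool:
        return self.task is not Task.FIXATION_RELATIVE

    @property
    def trial_duration_ms(self) -> float:
        return PURSUIT_TRIAL_MS if self.is_pursuit else FIXATION_TRIAL_MS

    @property
    def reference_flash_ms(self) -> float:
        return REFERENCE_FLASH_MS

    @property
    def target_flash_ms(self) -> float:
        return REFERENCE_FLASH_MS + self.soa_ms


def expected_hemifield(
    direction: PursuitDirection, placement: Placement
) -> Hemifield:
    """Hemifield in which ahead/behind flashes appear around the center crossing.

    The flashes are timed so the pursuit target is at screen center: stimuli
    ahead of a rightward-moving target lie in the right hemifield, stimuli
    behind it in the left hemifield, and mirrored for leftward pursuit.
    """
    direction = PursuitDirection(direction)
    placement = Placement(placement)
    if direction is PursuitDirection.NONE or placement is Placement.NA:
        raise ValueError("need a pursuit direction and an ahead/behind placement")
    rightward = direction is PursuitDirection.RIGHTWARD
    ahead = placement is Placement.AHEAD
    return Hemifield.RIGHT if rightward == ahead else Hemifield.LEFT


def direction_sign(direction: PursuitDirection) -> int:
    """+1 for rightward pursuit, -1 for leftward, 0 for none (fixation)."""
    direction = PursuitDirection(direction)
    if direction is PursuitDirection.RIGHTWARD:
        return 1
    if direction is PursuitDirection.LEFTWARD:
        return -1
    return 0


def hemifield_sign(hemifield: Hemifield) -> int:
    """+1 for the right hemifield, -1 for the left."""
    return 1 if Hemifield(hemifield) is Hemifield.RIGHT else -1


def cm_to_deg(offset_cm: float, distance_cm: float) -> float:
    """Convert a lateral offset on a flat screen to degrees of visual angle.

    Uses the per-point arctangent ``atan(offset/distance)``; odd in the
    offset, strictly increasing.
    """
    if distance_cm <= 0:
        raise InvalidGeometryError("viewing distance must be positive")
    return math.degrees(math.atan2(offset_cm, distance_cm))


def deg_to_cm(angle_deg: float, distance_cm: float) -> float:
    """Inverse of :func:`cm_to_deg` (``distance * tan(angle)``)."""
    if distance_cm <= 0:
        raise InvalidGeometryError("viewing distance must be positive")
    return distance_cm * math.tan(math.radians(angle_deg))


def to_eccentricity_axis(value_screen_deg, hemifield: Hemifield):
    """Re-sign a screen-axis quantity so positive means 'more eccentric'.

    Identity for right-hemifield stimuli, negation for left-hemifield ones;
    applying it twice is the identity.  Works on scalars and numpy arrays.
    """
    return hemifield_sign(hemifield) * value_screen_deg


def retinal_position(
    stimulus_screen_deg: float, eye_screen_deg: float, hemifield: Hemifield
) -> float:
    """Retinal eccentricity of a stimulus given the eye position.

    Both inputs are on the screen axis; the signed difference
    ``stimulus - eye`` is re-signed so that positive means more eccentric
    (farther from the fovea) within the stimulus hemifield.
    """
    return to_eccentricity_axis(stimulus_screen_deg - eye_screen_deg, hemifield)


# ---------------------------------------------------------------------------
# Gaze time series
# ---------------------------------------------------------------------------


@dataclass
class EyeTrace:
    """A 500-Hz single-eye gaze time series with event annotations.

    ``t_ms`` is strictly increasing at 2-ms spacing; ``valid`` marks samples
    the tracker delivered (blinks appear as invalid runs).  ``events`` holds
    ``(kind, onset_ms, offset_ms)`` annotations: ground truth when the trace
    was simulated, detections when produced by QC.
    """

    t_ms: np.ndarray
    x_deg: np.ndarray
    valid: np.ndarray
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t_ms) == len(self.x_deg) == len(self.valid)):
            raise ValueError("t_ms, x_deg and valid must have equal length")
        if len(self.t_ms) >= 2 and not (np.diff(self.t_ms) > 0).all():
            raise ValueError("t_ms must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)

    def window_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        return (self.t_ms >= start_ms) & (self.t_ms <= stop_ms)
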