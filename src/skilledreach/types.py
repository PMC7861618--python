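"""Shared containers for the skilled-reaching pipeline.

Conventions used throughout the package:

* Images follow the usual frame convention: pixel origin at the top-left,
  ``u`` (x) rightward, ``v`` (y) downward.
* The *camera frame* is centered at the direct camera's lens with the z-axis
  along the optical axis into the scene; all 3D quantities are in mm.
* The *pellet frame* puts the sugar pellet at the origin with positive x to
  the right of the pellet, positive y below it, and positive z beyond it
  (away from the reaching chamber, i.e. toward the camera).  ``z_digit2``,
  the z-coordinate of the second digit tip, measures paw advancement.
* Video runs at 300 frames/s; each trial stores 300 pre-trigger and 1000
  post-trigger frames (1300 frames total, trigger at frame index 300).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

#: Tracked body parts, in canonical column order.
BODYPARTS: tuple[str, ...] = (
    "digit1", "digit2", "digit3", "digit4", "pawdorsum", "nose", "pellet",
)
BODYPART_INDEX: dict[str, int] = {b: i for i, b in enumerate(BODYPARTS)}

VIEWS: tuple[str, str] = ("direct", "mirror")

FRAME_RATE: float = 300.0
PRE_TRIGGER_FRAMES: int = 300
POST_TRIGGER_FRAMES: int = 1000
FRAMES_PER_TRIAL: int = PRE_TRIGGER_FRAMES + POST_TRIGGER_FRAMES
TRIGGER_FRAME: int = PRE_TRIGGER_FRAMES


class Provenance(IntEnum):
    """How a reconstructed 3D point was obtained."""

    MISSING = 0
    TRIANGULATED = 1
    ESTIMATED = 2


class Outcome(IntEnum):
    """Reach-outcome scores (human-scored in the original study).

    0  no pellet presented or other mechanical failure ('no pellet')
    1  obtained pellet on initial limb advance ('first success')
    2  obtained pellet, but not on first attempt ('multi try success')
    3  pellet grasped then dropped in the box ('drop in box')
    4  pellet knocked off the shelf ('pellet knocked off')
    5  pellet obtained with the tongue ('used tongue')
    6  approached but retreated, or video triggered without a reach
       ('trigger error')
    7  reached but the pellet remained on the shelf ('pellet remained')
    8  reached with the ipsilateral paw ('ipsilateral paw')
    9  laser fired at the wrong time ('laser error')
    10 used preferred paw after moving pellet with tongue ('tongue and paw')
    """

    NO_PELLET = 0
    FIRST_SUCCESS = 1
    MULTI_TRY_SUCCESS = 2
    DROP_IN_BOX = 3
    KNOCKED_OFF = 4
    USED_TONGUE = 5
    TRIGGER_ERROR = 6
    PELLET_REMAINED = 7
    IPSILATERAL_PAW = 8
    LASER_ERROR = 9
    TONGUE_AND_PAW = 10


#: Codes counted as trials in success-rate denominators.
TRIAL_CODES: frozenset[int] = frozenset({1, 2, 3, 4, 7})
#: Numerator codes for first-reach success.
FIRST_SUCCESS_CODES: frozenset[int] = frozenset({1})
#: Numerator codes for any-reach success.
ANY_SUCCESS_CODES: frozenset[int] = frozenset({1, 2})


@dataclass
class Pose2DSeries:
    """Per-frame 2D labels with confidence for the direct and mirror views.

    ``views[view]`` is a float array of shape ``(n_frames, n_parts, 3)``
    holding ``(u, v, confidence)`` per body part; missing labels carry NaN
    coordinates and confidence 0.
    """

    views: dict[str, np.ndarray]
    bodyparts: tuple[str, ...] = BODYPARTS

    def __post_init__(self) -> None:
        for name in VIEWS:
            if name not in self.views:
                raise ValueError(f"missing view {name!r}")
        shapes = {self.views[v].shape for v in VIEWS}
        if len(shapes) != 1:
            raise ValueError(f"view arrays disagree in shape: {shapes}")
        arr = self.views[VIEWS[0]]
        if arr.ndim != 3 or arr.shape[1] != len(self.bodyparts) or arr.shape[2] != 3:
            raise ValueError(f"expected (n_frames, {len(self.bodyparts)}, 3), got {arr.shape}")
        for v in VIEWS:
            conf = self.views[v][:, :, 2]
            if np.nanmin(conf, initial=0.0) < 0 or np.nanmax(conf, initial=0.0) > 1:
                raise ValueError("confidence outside [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.views[VIEWS[0]].shape[0]

    def part_index(self, part: str) -> int:
        return self.bodyparts.index(part)


@dataclass
class Trajectory3D:
    """Reconstructed 3D body-part positions for one trial.

    ``positions`` has shape ``(n_frames, n_parts, 3)`` in mm; invalid points
    are NaN.  ``reproj_err`` is the mean two-view reprojection error in px
    (NaN where undefined).  ``provenance`` holds :class:`Provenance` codes.
    ``in_pellet_frame`` records whether the pellet-frame convention (origin
    at the pellet, left-paw x negated) has been applied.
    """

    positions: np.ndarray
    reproj_err: np.ndarray
    provenance: np.ndarray
    bodyparts: tuple[str, ...] = BODYPARTS
    paw_side: str = "right"
    frame_rate: float = FRAME_RATE
    in_pellet_frame: bool = False

    def __post_init__(self) -> None:
        if self.paw_side not in ("left", "right"):
            raise ValueError(f"paw_side must be 'left' or 'right', got {self.paw_side!r}")
        n, p, d = self.positions.shape
        if d != 3 or p != len(self.bodyparts):
            raise ValueError(f"positions shaped {self.positions.shape}")
        if self.reproj_err.shape != (n, p) or self.provenance.shape != (n, p):
            raise ValueError("reproj_err/provenance shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def part(self, name: str) -> np.ndarray:
        """(n_frames, 3) positions of one body part."""
        return self.positions[:, self.bodyparts.index(name), :]

    def z_digit2(self) -> np.ndarray:
        return self.part("digit2")[:, 2]

    def valid(self, name: str) -> np.ndarray:
        """Boolean mask of frames where the part has a usable position."""
        return self.provenance[:, self.bodyparts.index(name)] != Provenance.MISSING


@dataclass
class ReachEvent:
    """One segmented reach within a trial."""

    trial: int
    reach_idx: int
    start_frame: int
    end_frame: int
    is_first_reach: bool = False
    paw_through_slot: bool = False
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ValueError("start_frame must precede end_frame")


@dataclass
class ReachKinematics:
    """Scalar kinematic summary of one reach."""

    trial: int
    reach_idx: int
    max_extent: float          # z_digit2 at the reach end, mm
    end_aperture: float        # digit1-digit4 distance at reach end, mm
    end_orientation: float     # digit1-digit4 line vs floor, degrees
    max_velocity: float        # peak paw-dorsum speed within the reach, mm/s


@dataclass
class AimsScore:
    """Abnormal-involuntary-movement scores for one rat/epoch."""

    axial_amplitude: float
    axial_basic: float
    limb_amplitude: float
    limb_basic: float
    contralateral_rotations: int = 0
    ipsilateral_rotations: int = 0

    def __post_init__(self) -> None:
        for f in (self.axial_amplitude, self.axial_basic,
                  self.limb_amplitude, self.limb_basic):
            if f < 0:
                raise ValueError("AIMs scores must be non-negative")


@dataclass
class TestResult:
    """A generic frequentist test result."""

    statistic: float
    p_value: float
    df: float | tuple[float, ...] | None = None
    estimate: float | None = None
    se: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
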