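"""Forward model of a single reach-to-grasp movement.

A reach is modeled in the pellet frame (pellet at the origin, positive z =
paw advancement toward and past the pellet).  The second digit tip advances
from a start position behind the reaching slot to an endpoint drawn around
``extent_mean`` along a minimum-jerk position profile (smooth, single-peaked
velocity), then retracts.  As the paw advances, the digits extend and spread
while the paw pronates: grasp aperture (digit1-digit4 distance) and paw
orientation (digit1-digit4 line vs the floor) follow logistic profiles of
the advancement coordinate z, the standard description of the rat
reach-to-grasp sub-movement sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from ..types import BODYPART_INDEX, BODYPARTS

__all__ = ["ReachGenParams", "GroundTruthReach", "simulate_reach",
           "logistic_profile", "min_jerk"]


def logistic_profile(z: np.ndarray | float, lo: float, hi: float,
                     z_half: float, slope: float) -> np.ndarray | float:
    """Logistic transition from ``lo`` (z << z_half) to ``hi`` (z >> z_half)."""
    return lo + (hi - lo) * expit(slope * (np.asarray(z, dtype=float) - z_half))


def min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) on [0, 1], s(0)=0, s(1)=1."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


@dataclass
class ReachGenParams:
    """Tunable parameters of the reach generator.

    ``aperture_profile`` is ``(a_min, a_max, z_half, slope)`` in mm and
    1/mm; ``orientation_profile`` is ``(theta_start, theta_end, z_half,
    slope)`` in degrees and 1/mm.  ``peak_speed`` sets the advance duration
    through the minimum-jerk relation peak = 1.875 * distance / duration.
    ``n_frames`` caps the frames allotted to one reach (advance + retract)
    at 300 frames/s.
    """

    extent_mean: float = 3.0          # mm past the pellet
    extent_sd: float = 2.0            # mm
    aperture_profile: tuple[float, float, float, float] = (5.0, 14.0, -7.0, 0.8)
    orientation_profile: tuple[float, float, float, float] = (85.0, 30.0, -8.0, 0.7)
    peak_speed: float = 850.0         # mm/s
    start_position: tuple[float, float, float] = (1.5, 3.0, -21.0)  # behind the slot
    n_frames: int = 120
    frame_rate: float = 300.0

    def __post_init__(self) -> None:
        a_min, a_max, _, _ = self.aperture_profile
        if a_min > a_max:
            raise ValueError("aperture profile requires a_min <= a_max")
        if self.n_frames < 5:
            raise ValueError("n_frames must be >= 5")
        if self.extent_sd < 0:
            raise ValueError("extent_sd must be non-negative")
        if self.peak_speed <= 0:
            raise ValueError("peak_speed must be positive")

    def aperture_at(self, z: np.ndarray | float) -> np.ndarray | float:
        return logistic_profile(z, *self.aperture_profile)

    def orientation_at(self, z: np.ndarray | float) -> np.ndarray | float:
        return logistic_profile(z, *self.orientation_profile)

    def shifted(self, *, extent_mean: float = 0.0, aperture_z_half: float = 0.0,
                orientation_z_half: float = 0.0, peak_speed: float = 0.0) -> "ReachGenParams":
        """Return a copy with additive shifts applied (used by effect schedules)."""
        a = list(self.aperture_profile)
        a[2] += aperture_z_half
        o = list(self.orientation_profile)
        o[2] += orientation_z_half
        return replace(self,
                       extent_mean=self.extent_mean + extent_mean,
                       aperture_profile=tuple(a),
                       orientation_profile=tuple(o),
                       peak_speed=max(50.0, self.peak_speed + peak_speed))


@dataclass
class GroundTruthReach:
    """Noise-free body-part trajectory of one reach, in the pellet frame.

    ``positions`` has shape ``(n_frames, n_parts, 3)`` following the
    canonical body-part order.  ``endpoint_frame`` indexes the frame of
    maximum ``z_digit2`` (the reach end); ``endpoint_z`` is the maximum
    reach extent in mm.
    """

    positions: np.ndarray
    endpoint_frame: int
    endpoint_z: float
    params: ReachGenParams

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def part(self, name: str) -> np.ndarray:
        return self.positions[:, BODYPART_INDEX[name], :]

    def z_digit2(self) -> np.ndarray:
        return self.part("digit2")[:, 2]


# digit tips sit on a line through the digit-cluster center; offsets in
# units of the aperture place digits 1..4 so |tip1 - tip4| = aperture
_DIGIT_OFFSETS = np.array([-0.5, -1.0 / 6.0, 1.0 / 6.0, 0.5])
_DORSUM_DROP = np.array([0.0, 2.5, -8.0])   # dorsum relative to digit center, mm
_NOSE = np.array([-5.0, -8.0, -18.0])       # nose hovers near the slot


def simulate_reach(params: ReachGenParams,
                   seed: int | np.random.Generator | None = None,
                   *, endpoint_z: float | None = None) -> GroundTruthReach:
    """Simulate one reach; the endpoint is drawn from N(extent_mean, extent_sd).

    ``endpoint_z`` overrides the random draw (used when an effect schedule
    has already sampled the trial's endpoint).  Identical seed and
    parameters give identical trajectories.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if endpoint_z is None:
        endpoint_z = float(rng.normal(params.extent_mean, params.extent_sd))
    x0, y0, z0 = params.start_position
    if endpoint_z <= z0:
        endpoint_z = z0 + 1.0      # degenerate draw: keep a minimal advance
    dist = endpoint_z - z0
    dt = 1.0 / params.frame_rate
    n_adv = max(5, int(round(1.875 * dist / params.peak_speed / dt)))
    n_ret = min(int(round(1.3 * n_adv)), params.n_frames - n_adv - 1)
    n_ret = max(n_ret, 3)
    n = n_adv + n_ret + 1

    z = np.empty(n)
    z[:n_adv + 1] = z0 + dist * min_jerk(np.arange(n_adv + 1) / n_adv)
    # retract most of the way back behind the slot
    z[n_adv:] = endpoint_z - (endpoint_z - (z0 + 0.1 * dist)) * \
        min_jerk(np.arange(n_ret + 1) / n_ret)

    # digit-cluster center sweeps toward the pellet in x/y as the paw advances
    adv = np.clip((z - z0) / dist, 0.0, 1.0)
    s = min_jerk(adv)
    center = np.empty((n, 3))
    center[:, 0] = x0 + (0.5 - x0) * s
    center[:, 1] = y0 + (-1.5 - y0) * s
    center[:, 2] = z

    a = np.asarray(params.aperture_at(z))
    theta = np.radians(np.asarray(params.orientation_at(z)))
    direction = np.stack([np.cos(theta), -np.sin(theta), np.zeros(n)], axis=1)

    positions = np.empty((n, len(BODYPARTS), 3))
    for i in range(4):
        positions[:, i, :] = center + (_DIGIT_OFFSETS[i] * a)[:, None] * direction
    positions[:, BODYPART_INDEX["pawdorsum"], :] = center + _DORSUM_DROP
    positions[:, BODYPART_INDEX["nose"], :] = _NOSE
    positions[:, BODYPART_INDEX["pellet"], :] = 0.0
    # digit2 tip defines the advancement coordinate: pin its z to the profile
    positions[:, BODYPART_INDEX["digit2"], 2] = z

    return GroundTruthReach(positions=positions, endpoint_frame=n_adv,
                            endpoint_z=float(z[n_adv]), params=params)
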