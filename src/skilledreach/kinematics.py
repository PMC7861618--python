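"""Per-reach kinematic measures and advancement-coordinate profiles.

Scalar measures per reach: maximum reach extent (z_digit2 at the reach
end), grasp aperture at reach end (Euclidean distance between the first and
fourth digit tips), paw orientation at reach end (angle between the
digit1-digit4 line and the floor, seen in the frontal plane), and the peak
paw-dorsum speed.

To compare grasp kinematics at matched paw positions, each digit tip's 3D
trajectory is re-parameterized by the advancement coordinate: interpolated
with shape-preserving piecewise cubic Hermite polynomials (pchip) as a
function of z_digit2 and evaluated on a fixed grid from -20.0 to +15.0 mm
in 0.1 mm steps.  Grid points outside a reach's observed z range are
masked and excluded from session averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .types import BODYPART_INDEX, ReachEvent, ReachKinematics, Trajectory3D

__all__ = [
    "EXTENT_GRID", "ExtentProfile",
    "aperture", "orientation", "speed_series", "max_speed",
    "reach_kinematics", "profile_by_extent", "sample_profile",
]

#: z_digit2 evaluation grid: -20.0, -19.9, ..., +14.9, +15.0 mm (351 points).
EXTENT_GRID: np.ndarray = np.round(np.arange(-200, 151) / 10.0, 1)
EXTENT_GRID.setflags(write=False)

_D1 = BODYPART_INDEX["digit1"]
_D4 = BODYPART_INDEX["digit4"]


def aperture(points: np.ndarray) -> np.ndarray | float:
    """Grasp aperture: 3D distance between digit1 and digit4 tips (mm).

    ``points`` is ``(n_parts, 3)`` for one frame or ``(n_frames, n_parts,
    3)``; NaN tips propagate to NaN (undefined).
    """
    pts = np.asarray(points, dtype=float)
    d = np.linalg.norm(pts[..., _D1, :] - pts[..., _D4, :], axis=-1)
    return float(d) if d.ndim == 0 else d


def orientation(points: np.ndarray, paw_side: str = "right") -> np.ndarray | float:
    """Paw orientation: digit1-digit4 line vs the floor, in degrees [0, 90].

    Measured in the frontal (x-y) plane as seen head-on; smaller angles
    mean a more pronated paw.  For raw left-paw coordinates pass
    ``paw_side='left'`` to negate x first (already done for trajectories in
    the standardized pellet frame).  Tips coincident in projection give NaN.
    """
    pts = np.asarray(points, dtype=float)
    delta = pts[..., _D4, :] - pts[..., _D1, :]
    dx = np.abs(delta[..., 0])      # |dx| is unchanged by left-paw negation,
    dy = np.abs(delta[..., 1])      # kept explicit for clarity of the rule
    if paw_side not in ("left", "right"):
        raise ValueError("paw_side must be 'left' or 'right'")
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(dy, dx))
    ang = np.where(np.hypot(dx, dy) < 1e-12, np.nan, ang)
    return float(ang) if ang.ndim == 0 else ang


def speed_series(traj: Trajectory3D, part: str = "pawdorsum") -> np.ndarray:
    """Per-frame-pair speed of a body part in mm/s.

    Element ``i`` is the distance between frames ``i`` and ``i+1`` times the
    frame rate (1/300 s inter-frame interval); gaps yield NaN (no bridging).
    """
    p = traj.part(part)
    return np.linalg.norm(np.diff(p, axis=0), axis=1) * traj.frame_rate


def max_speed(traj: Trajectory3D, event: ReachEvent, part: str = "pawdorsum") -> float:
    """Peak speed within [start_frame, end_frame] of a reach (NaN if no data)."""
    s = speed_series(traj, part)[event.start_frame:event.end_frame]
    if len(s) == 0 or not np.isfinite(s).any():
        return float("nan")
    return float(np.nanmax(s))


def _end_frame_values(traj: Trajectory3D, event: ReachEvent,
                      search: int = 2) -> np.ndarray:
    """Body-part positions at the reach end, falling back to the nearest
    frame within ``search`` frames when the digit tips are missing there."""
    for off in sorted(range(-search, search + 1), key=abs):
        f = event.end_frame + off
        if 0 <= f < traj.n_frames:
            pts = traj.positions[f]
            if np.isfinite(pts[_D1]).all() and np.isfinite(pts[_D4]).all():
                return pts
    return traj.positions[event.end_frame]


def reach_kinematics(traj: Trajectory3D, event: ReachEvent) -> ReachKinematics:
    """Scalar kinematic summary of one segmented reach."""
    end_pts = _end_frame_values(traj, event)
    return ReachKinematics(
        trial=event.trial, reach_idx=event.reach_idx,
        max_extent=float(traj.z_digit2()[event.end_frame]),
        end_aperture=float(aperture(end_pts)),
        end_orientation=float(orientation(end_pts)),
        max_velocity=max_speed(traj, event),
    )


@dataclass
class ExtentProfile:
    """Digit kinematics re-parameterized on the shared z_digit2 grid.

    ``digits`` holds the interpolated 3D position of digit tips 1-4,
    shaped ``(4, len(grid), 3)``; ``aperture``/``orientation`` are derived
    curves; all values are NaN (and ``mask`` False) outside the reach's
    observed z range.
    """

    aperture: np.ndarray
    orientation: np.ndarray
    digits: np.ndarray
    mask: np.ndarray
    grid: np.ndarray = field(default_factory=lambda: EXTENT_GRID)

    @classmethod
    def empty(cls) -> "ExtentProfile":
        g = len(EXTENT_GRID)
        return cls(aperture=np.full(g, np.nan), orientation=np.full(g, np.nan),
                   digits=np.full((4, g, 3), np.nan), mask=np.zeros(g, dtype=bool))


def _monotone_subsequence(z: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Indices of the running-max strictly-increasing subsequence of z.

    Keeps a frame iff its z_digit2 exceeds every previously retained value,
    making z a single-valued parameterization despite small jitter.
    """
    keep: list[int] = []
    best = -np.inf
    for i in np.flatnonzero(valid):
        if z[i] > best:
            keep.append(i)
            best = z[i]
    return np.array(keep, dtype=int)


def profile_by_extent(traj: Trajectory3D, event: ReachEvent) -> ExtentProfile:
    """Interpolate a reach's digit trajectories onto the z_digit2 grid.

    Uses the advancing (start to end) portion of the reach restricted to
    its monotone subsequence in z_digit2; each digit-tip coordinate is a
    pchip function of z_digit2 evaluated on :data:`EXTENT_GRID`.  Fewer
    than 4 usable frames yield an all-masked profile.
    """
    sl = slice(event.start_frame, event.end_frame + 1)
    z = traj.z_digit2()[sl]
    digit_idx = [BODYPART_INDEX[f"digit{i}"] for i in (1, 2, 3, 4)]
    pts = traj.positions[sl][:, digit_idx, :]       # (n, 4, 3)
    valid = np.isfinite(z) & np.isfinite(pts).all(axis=(1, 2))
    keep = _monotone_subsequence(z, valid)
    if len(keep) < 4:
        return ExtentProfile.empty()
    zk = z[keep]
    mask = (EXTENT_GRID >= zk[0]) & (EXTENT_GRID <= zk[-1])
    digits = np.full((4, len(EXTENT_GRID), 3), np.nan)
    coords = PchipInterpolator(zk, pts[keep], axis=0, extrapolate=False)(EXTENT_GRID[mask])
    digits[:, mask, :] = np.moveaxis(coords, 0, 1)

    ap = np.linalg.norm(digits[0] - digits[3], axis=-1)
    delta = digits[3] - digits[0]
    with np.errstate(invalid="ignore"):
        ori = np.degrees(np.arctan2(np.abs(delta[:, 1]), np.abs(delta[:, 0])))
    ap[~mask] = np.nan
    ori[~mask] = np.nan
    return ExtentProfile(aperture=ap, orientation=ori, digits=digits, mask=mask)


def sample_profile(profiles: list[ExtentProfile], z_query: float,
                   measure: str = "aperture") -> tuple[np.ndarray, float, int]:
    """Evaluate a measure at one grid z across reaches.

    Returns ``(per_reach_values, session_mean, n_covering)``.  Reaches not
    covering ``z_query`` contribute NaN and are excluded from the mean
    (shorter reaches never enter averages at z values they did not attain).
    The mean is NaN when no reach covers the query point.
    """
    if measure not in ("aperture", "orientation"):
        raise ValueError("measure must be 'aperture' or 'orientation'")
    j = int(np.argmin(np.abs(EXTENT_GRID - z_query)))
    if abs(EXTENT_GRID[j] - z_query) > 1e-9:
        raise ValueError(f"z_query={z_query} is not on the 0.1 mm grid")
    vals = np.array([getattr(p, measure)[j] if p.mask[j] else np.nan for p in profiles])
    covered = np.isfinite(vals)
    mean = float(vals[covered].mean()) if covered.any() else float("nan")
    return vals, mean, int(covered.sum())
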