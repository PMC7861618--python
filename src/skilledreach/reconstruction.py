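"""Triangulation of 2D tracking labels into pellet-frame 3D trajectories.

Stages, in pipeline order:

1. :func:`triangulate_series` — linear triangulation of labels confident in
   both views, with per-point reprojection error.
2. :func:`filter_by_reprojection` — drop points whose reprojection error is
   large (the signature of a label misidentified in one view).
3. :func:`estimate_missing_points` — bridge short gaps where a part was
   seen in only one view, by temporal shape-preserving interpolation of the
   3D track validated against the single-view label.
4. :func:`to_pellet_frame` — express trajectories with the pellet at the
   origin (x right of the pellet, y below it, z beyond it); left-paw x is
   negated so left- and right-pawed reaches are directly comparable.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import PchipInterpolator

from .calibration import CameraPair, flip_mirror_u
from .types import (
    TRIGGER_FRAME, Pose2DSeries, Provenance, Trajectory3D,
)

__all__ = [
    "triangulate_series", "filter_by_reprojection",
    "estimate_missing_points", "to_pellet_frame",
]

DEFAULT_CONF_MIN = 0.9
DEFAULT_REPROJ_THRESHOLD_PX = 3.0
DEFAULT_MAX_GAP = 5
DEFAULT_TOL_PX = 3.0


def _usable(view_arr: np.ndarray, conf_min: float) -> np.ndarray:
    """Mask of labels with adequate confidence and finite coordinates."""
    return (view_arr[:, :, 2] >= conf_min) & np.isfinite(view_arr[:, :, :2]).all(axis=2)


def triangulate_series(pose: Pose2DSeries, pair: CameraPair,
                       conf_min: float = DEFAULT_CONF_MIN) -> Trajectory3D:
    """Triangulate every body part confident in both views, frame by frame.

    Points usable in fewer than two views are flagged missing.  Positions
    are in the direct camera frame (mm); the reprojection error is the mean
    over the two views of the observed-vs-reprojected pixel distance.
    """
    if not 0.0 <= conf_min <= 1.0:
        raise ValueError("conf_min must lie in [0, 1]")
    d, m = pose.views["direct"], pose.views["mirror"]
    both = _usable(d, conf_min) & _usable(m, conf_min)

    n_frames, n_parts = both.shape
    positions = np.full((n_frames, n_parts, 3), np.nan)
    reproj = np.full((n_frames, n_parts), np.nan)
    provenance = np.zeros((n_frames, n_parts), dtype=np.int8)
    if both.any():
        pts, err = pair.triangulate_mm(d[both][:, :2], m[both][:, :2])
        positions[both] = pts
        reproj[both] = err
        provenance[both] = Provenance.TRIANGULATED
    return Trajectory3D(positions=positions, reproj_err=reproj,
                        provenance=provenance, bodyparts=pose.bodyparts)


def filter_by_reprojection(traj: Trajectory3D, threshold_px: float = DEFAULT_REPROJ_THRESHOLD_PX,
                           ) -> tuple[Trajectory3D, int]:
    """Remove points whose reprojection error exceeds ``threshold_px``.

    Returns the filtered trajectory and the number of points removed.
    """
    if threshold_px <= 0:
        raise ValueError("threshold_px must be positive")
    bad = np.where(np.isfinite(traj.reproj_err), traj.reproj_err > threshold_px, False)
    bad &= traj.provenance == Provenance.TRIANGULATED
    positions = traj.positions.copy()
    reproj = traj.reproj_err.copy()
    provenance = traj.provenance.copy()
    positions[bad] = np.nan
    reproj[bad] = np.nan
    provenance[bad] = Provenance.MISSING
    return (Trajectory3D(positions=positions, reproj_err=reproj, provenance=provenance,
                         bodyparts=traj.bodyparts, paw_side=traj.paw_side,
                         frame_rate=traj.frame_rate,
                         in_pellet_frame=traj.in_pellet_frame),
            int(bad.sum()))


def estimate_missing_points(traj: Trajectory3D, pose: Pose2DSeries, pair: CameraPair,
                            conf_min: float = DEFAULT_CONF_MIN,
                            max_gap: int = DEFAULT_MAX_GAP,
                            tol_px: float = DEFAULT_TOL_PX) -> Trajectory3D:
    """Fill short gaps for parts tracked in only one view.

    A missing 3D point inside a gap of at most ``max_gap`` frames (bounded
    by triangulated frames on both sides) is estimated by monotone
    piecewise-cubic (pchip) interpolation of the part's 3D track over time.
    The estimate is accepted only where the part *was* labeled in exactly
    one view and the estimate's projection into that view lands within
    ``tol_px`` of the observed label — the single-view label anchored by
    two-view geometry.  Longer gaps, unlabeled frames, and rejected
    estimates stay missing.
    """
    if traj.in_pellet_frame:
        raise ValueError("estimate before converting to the pellet frame")
    d, m = pose.views["direct"], pose.views["mirror"]
    use_d, use_m = _usable(d, conf_min), _usable(m, conf_min)
    positions = traj.positions.copy()
    reproj = traj.reproj_err.copy()
    provenance = traj.provenance.copy()

    for p in range(len(traj.bodyparts)):
        valid = provenance[:, p] == Provenance.TRIANGULATED
        idx = np.flatnonzero(valid)
        if len(idx) < 2:
            continue
        interp = PchipInterpolator(idx, positions[idx, p, :], axis=0, extrapolate=False)
        # gaps strictly between consecutive triangulated frames
        for a, b in zip(idx[:-1], idx[1:]):
            gap = b - a - 1
            if gap == 0 or gap > max_gap:
                continue
            for f in range(a + 1, b):
                one_view = use_d[f, p] ^ use_m[f, p]
                if not one_view:
                    continue
                est = interp(f)
                if use_d[f, p]:
                    proj = pair._reproject(est / pair.scale_mm, pair.P_direct)
                    obs = d[f, p, :2]
                else:
                    proj = pair._reproject(est / pair.scale_mm, pair.P_mirror)
                    obs = flip_mirror_u(m[f, p, :2], pair.principal_cx)
                if np.linalg.norm(proj - obs) <= tol_px:
                    positions[f, p, :] = est
                    provenance[f, p] = Provenance.ESTIMATED
                    reproj[f, p] = np.nan
    return Trajectory3D(positions=positions, reproj_err=reproj, provenance=provenance,
                        bodyparts=traj.bodyparts, paw_side=traj.paw_side,
                        frame_rate=traj.frame_rate, in_pellet_frame=False)


def to_pellet_frame(traj: Trajectory3D, paw_side: str,
                    floor_normal: tuple[float, float, float] = (0.0, 1.0, 0.0),
                    camera_axis: tuple[float, float, float] = (0.0, 0.0, -1.0),
                    trigger_frame: int = TRIGGER_FRAME,
                    pellet_window: int = 100,
                    min_pellet_frames: int = 10) -> Trajectory3D:
    """Re-express a camera-frame trajectory in the pellet-centered frame.

    The origin is the per-coordinate median pellet position over the
    ``pellet_window`` frames preceding the trigger.  Axes come from the
    chamber geometry: y along the supplied floor normal (pointing down),
    z along the reach direction (``camera_axis``, orthonormalized against
    y), x = y cross z.  For left-pawed sessions x is negated afterwards so
    kinematics compare directly with right-pawed reaches.
    """
    if traj.in_pellet_frame:
        raise ValueError("trajectory is already in the pellet frame")
    if paw_side not in ("left", "right"):
        raise ValueError("paw_side must be 'left' or 'right'")
    pellet = traj.part("pellet")
    lo = max(0, trigger_frame - pellet_window)
    window = pellet[lo:trigger_frame]
    ok = np.isfinite(window).all(axis=1)
    if int(ok.sum()) < min_pellet_frames:
        raise ValueError(
            f"pellet tracked in only {int(ok.sum())} of the {pellet_window} "
            f"pre-trigger frames (need {min_pellet_frames})")
    origin = np.median(window[ok], axis=0)

    y = np.asarray(floor_normal, dtype=float)
    y = y / np.linalg.norm(y)
    z = np.asarray(camera_axis, dtype=float)
    z = z - (z @ y) * y
    norm = np.linalg.norm(z)
    if norm < 1e-12:
        raise ValueError("camera axis parallel to the floor normal")
    z = z / norm
    x = np.cross(y, z)
    R = np.stack([x, y, z])          # rows: pellet-frame axes in camera coords

    positions = (traj.positions - origin) @ R.T
    if paw_side == "left":
        positions = positions.copy()
        positions[..., 0] *= -1.0
    return Trajectory3D(positions=positions, reproj_err=traj.reproj_err.copy(),
                        provenance=traj.provenance.copy(), bodyparts=traj.bodyparts,
                        paw_side=paw_side, frame_rate=traj.frame_rate,
                        in_pellet_frame=True)
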