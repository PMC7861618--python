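"""Projection of ground-truth trajectories into degraded 2D tracking tables.

The generator works in the pellet frame; this module places that frame in
front of the synthetic camera, projects every body part into the direct and
mirror views, and degrades the labels the way markerless tracking output
degrades: Gaussian pixel noise, missing detections (low confidence), and
occasional digit-identity mislabels confined to a single view and frame —
exactly the failure mode that reprojection-error filtering exists to catch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import BODYPART_INDEX, BODYPARTS, Pose2DSeries
from .camera import CameraRig

__all__ = ["NoiseConfig", "PELLET_CAM_MM", "pellet_to_camera",
           "camera_to_pellet", "project_and_degrade"]

#: Pellet position in the camera frame (mm): slightly below the optical
#: axis, 250 mm in front of the lens.
PELLET_CAM_MM: np.ndarray = np.array([0.0, 40.0, 250.0])

# pellet-frame axes expressed in camera coordinates: x right of the pellet
# (the camera's -x, facing the rat), y below the pellet (camera +y, image
# convention), z beyond the pellet toward the camera (camera -z).
_AXES = np.diag([-1.0, 1.0, -1.0])


def pellet_to_camera(points: np.ndarray) -> np.ndarray:
    """Map pellet-frame points (..., 3) into the camera/world frame."""
    return np.asarray(points, dtype=float) @ _AXES.T + PELLET_CAM_MM


def camera_to_pellet(points: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pellet_to_camera`."""
    return (np.asarray(points, dtype=float) - PELLET_CAM_MM) @ _AXES


@dataclass
class NoiseConfig:
    """Label-degradation model for synthetic tracking output."""

    px_sd: float = 0.5            # Gaussian label jitter per coordinate, px
    p_missing: float = 0.02       # per label: detection dropped (low confidence)
    p_mislabel: float = 0.002     # per frame+view: two digit identities swapped
    conf_good: tuple[float, float] = (0.95, 1.0)     # confidence range, detected
    conf_missing: tuple[float, float] = (0.0, 0.4)   # confidence range, dropped

    def __post_init__(self) -> None:
        if self.px_sd < 0:
            raise ValueError("px_sd must be non-negative")
        for p in (self.p_missing, self.p_mislabel):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def project_and_degrade(positions_pellet: np.ndarray, rig: CameraRig,
                        noise: NoiseConfig | None = None,
                        seed: int | np.random.Generator | None = None,
                        ) -> Pose2DSeries:
    """Render pellet-frame ground truth (n_frames, n_parts, 3) to 2D labels.

    Points projecting outside the image (or behind a camera) are marked
    missing.  Mislabels swap the pixel labels of two random digit tips in
    one view for one frame, leaving confidence high — detectable only
    through reconstruction geometry.
    """
    noise = noise or NoiseConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts_cam = pellet_to_camera(positions_pellet)
    n_frames, n_parts = pts_cam.shape[:2]
    digit_idx = [BODYPART_INDEX[f"digit{i}"] for i in (1, 2, 3, 4)]

    views: dict[str, np.ndarray] = {}
    for view in ("direct", "mirror"):
        px = rig.project(pts_cam, view)
        visible = rig.in_image(px) & (rig.depth(pts_cam, view) > 0)
        if noise.px_sd > 0:
            px = px + rng.normal(0.0, noise.px_sd, px.shape)
        dropped = rng.random((n_frames, n_parts)) < noise.p_missing
        missing = dropped | ~visible
        conf = rng.uniform(*noise.conf_good, (n_frames, n_parts))
        conf[missing] = rng.uniform(*noise.conf_missing, int(missing.sum()))
        px[~visible] = np.nan

        swap_frames = np.flatnonzero(rng.random(n_frames) < noise.p_mislabel)
        for f in swap_frames:
            i, j = rng.choice(digit_idx, size=2, replace=False)
            px[f, [i, j]] = px[f, [j, i]]
        views[view] = np.concatenate([px, conf[..., None]], axis=2)
    return Pose2DSeries(views=views)
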