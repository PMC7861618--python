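"""Synthetic mirror-stereo camera rig.

A single real camera views the reaching chamber directly; a planar mirror to
the side provides a second, 'virtual' viewpoint: the mirror view of a world
point X is the real camera's image of X reflected across the mirror plane.
Equivalently it is the image of X through the virtual camera obtained by
reflecting the real camera across the plane (an improper rigid transform).

The world frame coincides with the real camera frame (camera center at the
origin, z along the optical axis into the scene), matching the convention of
deriving camera matrices in a coordinate system centered at the camera lens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

DEFAULT_IMAGE_SIZE: tuple[int, int] = (2400, 1024)   # (width, height), px


def reflect_points(points: np.ndarray, normal: np.ndarray, offset: float) -> np.ndarray:
    """Reflect 3D points across the plane ``normal . X = offset``.

    ``normal`` must be unit length.  Works on ``(..., 3)`` arrays.
    """
    normal = np.asarray(normal, dtype=float)
    d = points @ normal - offset
    return points - 2.0 * d[..., None] * normal


def reflection_matrix(normal: np.ndarray, offset: float) -> np.ndarray:
    """Homogeneous 4x4 matrix of the reflection across ``normal . X = offset``."""
    n = np.asarray(normal, dtype=float)
    H = np.eye(4)
    H[:3, :3] = np.eye(3) - 2.0 * np.outer(n, n)
    H[:3, 3] = 2.0 * offset * n
    return H


@dataclass
class CameraRig:
    """Pinhole camera plus planar mirror defining the two-view geometry.

    ``real_rotation``/``real_center`` give the direct camera's pose in the
    world frame (world -> camera: ``x_cam = R (X - C)``); the default rig
    keeps the camera at the origin with identity orientation so the world
    frame *is* the camera frame.  ``mirror_normal``/``mirror_offset`` define
    the mirror plane ``n . X = d`` in mm.
    """

    intrinsics: np.ndarray
    mirror_normal: np.ndarray
    mirror_offset: float
    real_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    real_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE

    def __post_init__(self) -> None:
        K = np.asarray(self.intrinsics, dtype=float)
        if K.shape != (3, 3):
            raise ValueError("intrinsics must be 3x3")
        if not np.allclose(K, np.triu(K)) or K[0, 0] <= 0 or K[1, 1] <= 0:
            raise ValueError("intrinsics must be upper-triangular with positive focal terms")
        self.intrinsics = K
        n = np.asarray(self.mirror_normal, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-8):
            raise ValueError("mirror normal must be unit length")
        self.mirror_normal = n
        self.real_rotation = np.asarray(self.real_rotation, dtype=float)
        self.real_center = np.asarray(self.real_center, dtype=float)
        # The camera must sit on the negative side of the mirror plane
        # (otherwise it would be behind its own mirror image).
        if self.real_center @ n - self.mirror_offset >= 0:
            raise ValueError("camera center lies on or behind the mirror plane")

    # -- camera centers ----------------------------------------------------
    @property
    def virtual_center(self) -> np.ndarray:
        """Center of the virtual camera: mirror image of the real center."""
        return reflect_points(self.real_center[None, :],
                              self.mirror_normal, self.mirror_offset)[0]

    # -- projection --------------------------------------------------------
    def _camera_coords(self, points: np.ndarray) -> np.ndarray:
        return (points - self.real_center) @ self.real_rotation.T

    def project_direct(self, points: np.ndarray) -> np.ndarray:
        """Project world points (..., 3) to direct-view pixels (..., 2)."""
        pc = self._camera_coords(np.asarray(points, dtype=float))
        K = self.intrinsics
        with np.errstate(divide="ignore", invalid="ignore"):
            u = K[0, 0] * pc[..., 0] / pc[..., 2] + K[0, 1] * pc[..., 1] / pc[..., 2] + K[0, 2]
            v = K[1, 1] * pc[..., 1] / pc[..., 2] + K[1, 2]
        return np.stack([u, v], axis=-1)

    def project_mirror(self, points: np.ndarray) -> np.ndarray:
        """Project world points into the mirror view.

        The mirror view of X is the direct image of X reflected across the
        mirror plane.
        """
        refl = reflect_points(np.asarray(points, dtype=float),
                              self.mirror_normal, self.mirror_offset)
        return self.project_direct(refl)

    def project(self, points: np.ndarray, view: str) -> np.ndarray:
        if view == "direct":
            return self.project_direct(points)
        if view == "mirror":
            return self.project_mirror(points)
        raise ValueError(f"unknown view {view!r}")

    def depth(self, points: np.ndarray, view: str) -> np.ndarray:
        """Depth along the optical axis of the (real or virtual) camera."""
        pts = np.asarray(points, dtype=float)
        if view == "mirror":
            pts = reflect_points(pts, self.mirror_normal, self.mirror_offset)
        return self._camera_coords(pts)[..., 2]

    def in_image(self, pixels: np.ndarray) -> np.ndarray:
        w, h = self.image_size
        u, v = pixels[..., 0], pixels[..., 1]
        return (u >= 0) & (u < w) & (v >= 0) & (v < h) & np.isfinite(u) & np.isfinite(v)

    # -- ground-truth two-view geometry (for oracles) ----------------------
    def true_relative_pose(self) -> tuple[np.ndarray, np.ndarray]:
        """Proper (R, t) of the flipped mirror view relative to the direct view.

        After the handedness flip ``u -> 2*cx - u`` applied to mirror-view
        pixels, the mirror camera becomes a proper pinhole camera with the
        same intrinsics K and extrinsics ``[R|t] = D [H|h]`` where ``[H|h]``
        is the mirror reflection and ``D = diag(-1, 1, 1)``.
        """
        if not np.allclose(self.real_rotation, np.eye(3)) or not np.allclose(self.real_center, 0):
            raise NotImplementedError("ground-truth pose assumes the default camera-at-origin rig")
        n, d = self.mirror_normal, self.mirror_offset
        H = np.eye(3) - 2.0 * np.outer(n, n)
        h = 2.0 * d * n
        D = np.diag([-1.0, 1.0, 1.0])
        return D @ H, D @ h


def make_camera_rig(config: dict | None = None) -> CameraRig:
    """Build a camera rig from a configuration mapping.

    Recognized keys (all optional): ``focal_px``, ``principal_point``,
    ``mirror_normal`` (need not be normalized unless ``strict_normal``),
    ``mirror_offset_mm``, ``image_size``.  Defaults model a 2400x1024 px
    high-speed camera facing the reaching slot with a side mirror ~12 cm
    away angled to view the paw laterally.
    """
    cfg = dict(config or {})
    w, h = cfg.get("image_size", DEFAULT_IMAGE_SIZE)
    f = float(cfg.get("focal_px", 1700.0))
    cx, cy = cfg.get("principal_point", (w / 2.0, h / 2.0))
    K = np.array([[f, 0.0, cx], [0.0, f, cy], [0.0, 0.0, 1.0]])
    n = np.asarray(cfg.get("mirror_normal", (1.0, 0.0, 0.3)), dtype=float)
    if cfg.get("strict_normal", False):
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-8):
            raise ValueError("mirror normal must be unit length")
    else:
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("mirror normal must be nonzero")
        n = n / norm
    d = float(cfg.get("mirror_offset_mm", 120.0))
    return CameraRig(intrinsics=K, mirror_normal=n, mirror_offset=d,
                     image_size=(int(w), int(h)))


# ---------------------------------------------------------------------------
# Calibration target
# ---------------------------------------------------------------------------

@dataclass
class CorrespondenceSet:
    """Matched direct/mirror 2D points, optionally with 3D ground truth.

    ``direct``/``mirror`` are (n, 2) pixel arrays.  ``adjacency`` lists index
    pairs of physically adjacent corners whose true spacing is
    ``square_size_mm`` (used to fix the metric scale; the first pair is the
    anchor).  ``points3d`` is ground truth in mm when known (synthetic data).
    """

    direct: np.ndarray
    mirror: np.ndarray
    adjacency: list[tuple[int, int]] = field(default_factory=list)
    square_size_mm: float | None = None
    points3d: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.direct = np.asarray(self.direct, dtype=float)
        self.mirror = np.asarray(self.mirror, dtype=float)
        if self.direct.shape != self.mirror.shape or self.direct.ndim != 2 \
                or self.direct.shape[1] != 2:
            raise ValueError("direct/mirror must be matching (n, 2) arrays")
        if not (np.isfinite(self.direct).all() and np.isfinite(self.mirror).all()):
            raise ValueError("correspondences must be finite")

    def __len__(self) -> int:
        return self.direct.shape[0]


def _cube_corners(center: np.ndarray, square_size_mm: float,
                  squares_per_side: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Checkerboard-corner grid on three camera-facing faces of a cube.

    Returns world-frame corners and grid-adjacent index pairs (spacing =
    one square).
    """
    m = squares_per_side  # corners per edge
    side = square_size_mm * (m - 1)
    half = side / 2.0
    corners: list[np.ndarray] = []
    adjacency: list[tuple[int, int]] = []
    coords = np.linspace(-half, half, m)

    def add_face(base: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> None:
        start = len(corners)
        for i, j in product(range(m), range(m)):
            corners.append(base + coords[i] * e1 + coords[j] * e2)
        for i, j in product(range(m), range(m)):
            k = start + i * m + j
            if i + 1 < m:
                adjacency.append((k, k + m))
            if j + 1 < m:
                adjacency.append((k, k + 1))

    ex, ey, ez = np.eye(3)
    # front face (toward camera), top face, and the mirror-side face
    add_face(center + np.array([0, 0, -half]), ex, ey)
    add_face(center + np.array([0, -half, 0]), ex, ez)
    add_face(center + np.array([half, 0, 0]), ey, ez)
    return np.array(corners), adjacency


def generate_calibration_set(rig: CameraRig, square_size_mm: float = 4.0,
                             seed: int | None = None, *,
                             center: tuple[float, float, float] = (0.0, 40.0, 250.0),
                             squares_per_side: int = 4,
                             noise_px: float = 0.0,
                             min_corners: int = 20) -> CorrespondenceSet:
    """Checkerboard-cube corner correspondences seen in both views.

    Emulates imaging a calibration cube with checkerboard faces (4 x 4 mm
    squares by default) placed near the pellet before each session.  Corners
    invisible in either view are dropped; fewer than ``min_corners``
    surviving pairs is an error.
    """
    if square_size_mm <= 0:
        raise ValueError("square_size_mm must be positive")
    rng = np.random.default_rng(seed)
    pts3d, adjacency = _cube_corners(np.asarray(center, dtype=float),
                                     square_size_mm, squares_per_side)
    direct = rig.project_direct(pts3d)
    mirror = rig.project_mirror(pts3d)
    visible = (rig.in_image(direct) & rig.in_image(mirror)
               & (rig.depth(pts3d, "direct") > 0) & (rig.depth(pts3d, "mirror") > 0))
    if visible.sum() < min_corners:
        raise ValueError(
            f"only {int(visible.sum())} corners visible in both views (need {min_corners})")
    remap = -np.ones(len(pts3d), dtype=int)
    remap[visible] = np.arange(int(visible.sum()))
    adjacency = [(remap[a], remap[b]) for a, b in adjacency
                 if visible[a] and visible[b]]
    direct, mirror, pts3d = direct[visible], mirror[visible], pts3d[visible]
    if noise_px > 0:
        direct = direct + rng.normal(0.0, noise_px, direct.shape)
        mirror = mirror + rng.normal(0.0, noise_px, mirror.shape)
    return CorrespondenceSet(direct=direct, mirror=mirror, adjacency=adjacency,
                             square_size_mm=square_size_mm, points3d=pts3d)
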