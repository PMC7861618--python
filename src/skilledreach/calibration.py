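"""Two-view geometry between the direct camera and its mirror image.

The mirror provides a second viewpoint, but a reflected one: the 'virtual'
camera behind the mirror is an improper (left-handed) pinhole camera.  All
two-view machinery here therefore first flips the mirror view's horizontal
pixel coordinate about the principal-point column (``u -> 2*cx - u``), which
turns the virtual camera into a proper camera sharing the direct view's
intrinsic matrix K.  The fundamental matrix F is then estimated with the
Hartley-normalized eight-point algorithm, upgraded to the essential matrix
E = K'FK, decomposed into a relative pose by cheirality, and given a metric
scale by requiring a designated pair of adjacent checkerboard corners to
span the known square size (4 mm in the original rig).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synth.camera import CorrespondenceSet

__all__ = [
    "FundamentalMatrix", "CameraPair",
    "flip_mirror_u", "estimate_fundamental", "derive_camera_pair",
    "triangulate_linear", "epipolar_distances",
]


def flip_mirror_u(pixels: np.ndarray, cx: float) -> np.ndarray:
    """Flip the horizontal pixel coordinate about the principal column.

    Applied to mirror-view labels before any two-view computation; converts
    the left-handed virtual camera into a proper right-handed one with
    unchanged intrinsics.  The map is an involution and a pixel-space
    isometry, so distances (e.g. reprojection errors) are preserved.
    """
    out = np.array(pixels, dtype=float, copy=True)
    out[..., 0] = 2.0 * cx - out[..., 0]
    return out


@dataclass
class FundamentalMatrix:
    """Rank-2 fundamental matrix (unit Frobenius norm) with diagnostics."""

    matrix: np.ndarray
    median_epipolar_px: float = float("nan")

    def __post_init__(self) -> None:
        F = np.asarray(self.matrix, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        norm = np.linalg.norm(F)
        if norm == 0:
            raise ValueError("F is zero")
        self.matrix = F / norm
        if np.linalg.matrix_rank(self.matrix, tol=1e-10) != 2:
            raise ValueError("F must have rank 2")


def _hartley_normalize(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Translate to centroid and scale to mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = np.sqrt(2.0) / d if d > 0 else 1.0
    T = np.array([[s, 0.0, -s * centroid[0]],
                  [0.0, s, -s * centroid[1]],
                  [0.0, 0.0, 1.0]])
    homog = np.column_stack([pts, np.ones(len(pts))]) @ T.T
    return homog, T


def epipolar_distances(F: np.ndarray, direct: np.ndarray,
                       mirror_flipped: np.ndarray) -> np.ndarray:
    """Symmetric point-to-epipolar-line distance (px) per correspondence."""
    x1 = np.column_stack([direct, np.ones(len(direct))])
    x2 = np.column_stack([mirror_flipped, np.ones(len(mirror_flipped))])
    l2 = x1 @ F.T          # epipolar lines in the flipped-mirror image
    l1 = x2 @ F            # epipolar lines in the direct image
    num = np.abs(np.sum(x2 * l2, axis=1))
    d2 = num / np.hypot(l2[:, 0], l2[:, 1])
    d1 = num / np.hypot(l1[:, 0], l1[:, 1])
    return 0.5 * (d1 + d2)


def estimate_fundamental(corr: CorrespondenceSet, cx: float,
                         *, condition_max: float = 1e12) -> FundamentalMatrix:
    """Hartley-normalized eight-point estimate of F.

    ``cx`` is the principal-point column used for the mirror handedness
    flip.  All pairs enter the least-squares fit (calibration corners are
    curated, so no robust loop by default).  Rank 2 is enforced by zeroing
    the smallest singular value.
    """
    if len(corr) < 8:
        raise ValueError(f"need >= 8 correspondences, got {len(corr)}")
    x1h, T1 = _hartley_normalize(corr.direct)
    x2h, T2 = _hartley_normalize(flip_mirror_u(corr.mirror, cx))
    # each row: x2^T F x1 = 0 with F raveled row-major
    A = np.einsum("ni,nj->nij", x2h, x1h).reshape(len(corr), 9)
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] <= 0 or sv[0] / sv[-2] > condition_max:
        raise ValueError("degenerate correspondence configuration for the eight-point algorithm")
    F = Vt[-1].reshape(3, 3)
    U, s, Vt = np.linalg.svd(F)
    F = U @ np.diag([s[0], s[1], 0.0]) @ Vt
    F = T2.T @ F @ T1
    F /= np.linalg.norm(F)
    med = float(np.median(epipolar_distances(F, corr.direct,
                                             flip_mirror_u(corr.mirror, cx))))
    return FundamentalMatrix(matrix=F, median_epipolar_px=med)


def triangulate_linear(P1: np.ndarray, P2: np.ndarray,
                       x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Batched linear (DLT) triangulation of pixel correspondences.

    Solves the inhomogeneous 4x3 system per point by normal equations,
    which is exact for noise-free data and fast for millions of points.
    ``x1``/``x2`` are (..., 2); returns (..., 3).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    rows = np.stack([
        x1[..., 0, None] * P1[2] - P1[0],
        x1[..., 1, None] * P1[2] - P1[1],
        x2[..., 0, None] * P2[2] - P2[0],
        x2[..., 1, None] * P2[2] - P2[1],
    ], axis=-2)                                   # (..., 4, 4)
    A = rows[..., :3]
    b = -rows[..., 3]
    At = np.swapaxes(A, -1, -2)
    AtA = At @ A
    Atb = (At @ b[..., None])
    return np.linalg.solve(AtA, Atb)[..., 0]


@dataclass
class CameraPair:
    """Metric camera pair for the direct and (flipped) mirror views.

    ``P_direct = K [I|0]``; ``P_mirror = K [R|t]`` with unit-norm t and
    det(R) = +1 after the handedness flip.  ``scale_mm`` converts
    reconstruction units to mm.  ``principal_cx`` records the column used
    for the mirror flip.
    """

    intrinsics: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray
    scale_mm: float
    principal_cx: float
    mirror_flip: bool = True

    def __post_init__(self) -> None:
        K = np.asarray(self.intrinsics, dtype=float)
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if K.shape != (3, 3) or R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("bad matrix shapes")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det +1); apply the mirror flip first")
        if self.scale_mm <= 0:
            raise ValueError("scale must be positive")
        self.intrinsics, self.rotation, self.translation = K, R, t

    @property
    def P_direct(self) -> np.ndarray:
        return self.intrinsics @ np.hstack([np.eye(3), np.zeros((3, 1))])

    @property
    def P_mirror(self) -> np.ndarray:
        return self.intrinsics @ np.hstack([self.rotation, self.translation[:, None]])

    def triangulate_mm(self, direct_px: np.ndarray, mirror_px: np.ndarray,
                       *, flip: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Triangulate raw pixel labels into mm plus reprojection errors.

        Returns ``(points_mm, reproj_err_px)`` where the error is the mean
        over the two views of the pixel distance between the observed and
        reprojected labels.  The mirror flip is an isometry, so errors
        measured in flipped coordinates equal those in raw coordinates.
        """
        m = flip_mirror_u(mirror_px, self.principal_cx) if (flip and self.mirror_flip) \
            else np.asarray(mirror_px, dtype=float)
        d = np.asarray(direct_px, dtype=float)
        X = triangulate_linear(self.P_direct, self.P_mirror, d, m)
        err = 0.5 * (np.linalg.norm(self._reproject(X, self.P_direct) - d, axis=-1)
                     + np.linalg.norm(self._reproject(X, self.P_mirror) - m, axis=-1))
        return X * self.scale_mm, err

    @staticmethod
    def _reproject(X: np.ndarray, P: np.ndarray) -> np.ndarray:
        Xh = np.concatenate([X, np.ones(X.shape[:-1] + (1,))], axis=-1)
        proj = Xh @ P.T
        return proj[..., :2] / proj[..., 2:3]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "intrinsics": self.intrinsics.tolist(),
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "scale_mm": float(self.scale_mm),
            "principal_cx": float(self.principal_cx),
            "mirror_flip": bool(self.mirror_flip),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "CameraPair":
        return cls(intrinsics=np.array(d["intrinsics"]),
                   rotation=np.array(d["rotation"]),
                   translation=np.array(d["translation"]),
                   scale_mm=float(d["scale_mm"]),
                   principal_cx=float(d["principal_cx"]),
                   mirror_flip=bool(d.get("mirror_flip", True)))

    @classmethod
    def load(cls, path: str | Path) -> "CameraPair":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _pose_candidates(E: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """The four (R, t) decompositions of an essential matrix (|t| = 1)."""
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    t = U[:, 2]
    return [(U @ W @ Vt, t), (U @ W @ Vt, -t),
            (U @ W.T @ Vt, t), (U @ W.T @ Vt, -t)]


def derive_camera_pair(F: FundamentalMatrix, K: np.ndarray,
                       corr: CorrespondenceSet,
                       square_size_mm: float | None = None) -> CameraPair:
    """Upgrade F to a metric camera pair using known intrinsics.

    Forms E = K'FK, picks the (R, t) candidate placing the calibration
    points in front of both cameras (cheirality), and fixes the mm scale so
    the first listed adjacent-corner pair spans ``square_size_mm``.
    """
    K = np.asarray(K, dtype=float)
    if abs(np.linalg.det(K)) < 1e-12:
        raise ValueError("intrinsics must be invertible")
    square = square_size_mm if square_size_mm is not None else corr.square_size_mm
    if square is None or square <= 0:
        raise ValueError("a positive checkerboard square size is required to fix the scale")
    if not corr.adjacency:
        raise ValueError("correspondence set has no adjacency pairs for scale fixing")
    cx = K[0, 2]
    E = K.T @ F.matrix @ K
    # project onto the essential manifold: two equal singular values, one zero
    U, s, Vt = np.linalg.svd(E)
    E = U @ np.diag([(s[0] + s[1]) / 2.0, (s[0] + s[1]) / 2.0, 0.0]) @ Vt

    d_px = corr.direct
    m_px = flip_mirror_u(corr.mirror, cx)
    P1 = K @ np.hstack([np.eye(3), np.zeros((3, 1))])
    best: tuple[int, np.ndarray, np.ndarray, np.ndarray] | None = None
    for R, t in _pose_candidates(E):
        P2 = K @ np.hstack([R, t[:, None]])
        X = triangulate_linear(P1, P2, d_px, m_px)
        z1 = X[:, 2]
        z2 = (X @ R.T + t)[:, 2]
        n_front = int(np.sum((z1 > 0) & (z2 > 0)))
        if best is None or n_front > best[0]:
            best = (n_front, R, t, X)
    assert best is not None
    n_front, R, t, X = best
    if n_front < 0.75 * len(corr):
        raise ValueError(
            "no pose candidate places the calibration points in front of both cameras; "
            "check that the mirror handedness flip was applied")

    a, b = corr.adjacency[0]
    anchor = np.linalg.norm(X[a] - X[b])
    if anchor <= 0 or not np.isfinite(anchor):
        raise ValueError("degenerate scale-anchor pair")
    return CameraPair(intrinsics=K, rotation=R, translation=t,
                      scale_mm=square / anchor, principal_cx=cx)
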