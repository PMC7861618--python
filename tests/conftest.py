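"""Shared fixtures: the default synthetic rig, calibration, and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from skilledreach.calibration import derive_camera_pair, estimate_fundamental
from skilledreach.synth import generate_calibration_set, make_camera_rig
from skilledreach.types import Provenance, Trajectory3D


@pytest.fixture(scope="session")
def rig():
    return make_camera_rig()


@pytest.fixture(scope="session")
def calib(rig):
    """Noiseless checkerboard-cube correspondences."""
    return generate_calibration_set(rig, 4.0, seed=0)


@pytest.fixture(scope="session")
def campair(rig, calib):
    F = estimate_fundamental(calib, cx=rig.intrinsics[0, 2])
    return derive_camera_pair(F, rig.intrinsics, calib)


def truth_trajectory(positions: np.ndarray, paw_side: str = "right") -> Trajectory3D:
    """Wrap pellet-frame ground-truth positions as a reconstructed trajectory."""
    n, p = positions.shape[:2]
    prov = np.where(np.isfinite(positions).all(axis=2),
                    np.int8(Provenance.TRIANGULATED), np.int8(Provenance.MISSING))
    return Trajectory3D(positions=positions.astype(float),
                        reproj_err=np.zeros((n, p)),
                        provenance=prov, paw_side=paw_side, in_pellet_frame=True)


@pytest.fixture(scope="session")
def make_truth_traj():
    return truth_trajectory
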