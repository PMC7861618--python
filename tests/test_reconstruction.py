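"""Reconstruction: triangulation, filtering, gap estimation, pellet frame."""

import numpy as np
import pytest

from skilledreach.reconstruction import (
    estimate_missing_points, filter_by_reprojection, to_pellet_frame,
    triangulate_series,
)
from skilledreach.synth import NoiseConfig, ReachGenParams, project_and_degrade
from skilledreach.synth.experiment import TrialSpec, render_trial
from skilledreach.types import BODYPART_INDEX, Provenance


def make_trial(seed=11, endpoint=3.0):
    spec = TrialSpec(trial=0, kind="reach", laser=False,
                     params=ReachGenParams(), endpoint_z=endpoint,
                     second_endpoint_z=None, start_frame=295, second_gap=50,
                     paw_through_slot=False, seed=seed)
    return render_trial(spec)


def clean_noise():
    return NoiseConfig(px_sd=0.0, p_missing=0.0, p_mislabel=0.0)


class TestTriangulateSeries:
    def test_noiseless_recovers_ground_truth(self, rig, campair):
        gt = make_trial()
        pose = project_and_degrade(gt, rig, clean_noise(), seed=0)
        traj = triangulate_series(pose, campair)
        assert np.nanmax(np.abs(traj.positions - (gt @ np.diag([-1, 1, -1])
                                                  + [0, 40, 250]))) < 1e-6
        assert np.nanmax(traj.reproj_err) < 1e-9

    def test_low_confidence_becomes_missing(self, rig, campair):
        gt = make_trial()
        pose = project_and_degrade(gt, rig, clean_noise(), seed=0)
        pose.views["mirror"][10, 2, 2] = 0.1     # digit3, frame 10, one view
        traj = triangulate_series(pose, campair)
        assert traj.provenance[10, 2] == Provenance.MISSING
        assert np.isnan(traj.positions[10, 2]).all()

    def test_swapped_digits_produce_large_reprojection_error(self, rig, campair):
        gt = make_trial()
        pose = project_and_degrade(gt, rig, clean_noise(), seed=0)
        f = 310                                   # mid-reach, digits spread
        i, j = BODYPART_INDEX["digit1"], BODYPART_INDEX["digit4"]
        m = pose.views["mirror"]
        m[f, [i, j], :2] = m[f, [j, i], :2]
        traj = triangulate_series(pose, campair)
        assert traj.reproj_err[f, i] > 5.0
        assert traj.reproj_err[f, j] > 5.0


class TestFilterByReprojection:
    def test_identity_when_all_errors_below_threshold(self, rig, campair):
        pose = project_and_degrade(make_trial(), rig, clean_noise(), seed=0)
        traj = triangulate_series(pose, campair)
        out, removed = filter_by_reprojection(traj, threshold_px=3.0)
        assert removed == 0
        assert np.array_equal(out.positions, traj.positions, equal_nan=True)

    def test_tiny_threshold_removes_all_noisy_points(self, rig, campair):
        pose = project_and_degrade(make_trial(), rig,
                                   NoiseConfig(px_sd=0.5, p_missing=0.0,
                                               p_mislabel=0.0), seed=1)
        traj = triangulate_series(pose, campair)
        out, removed = filter_by_reprojection(traj, threshold_px=1e-9)
        n_valid = int((traj.provenance == Provenance.TRIANGULATED).sum())
        assert removed == n_valid
        assert not (out.provenance == Provenance.TRIANGULATED).any()

    def test_exactly_the_swapped_points_removed(self, rig, campair):
        """Mislabel fixture: digit identities swapped in one view for one
        frame; threshold 3 px must remove exactly those two points."""
        pose = project_and_degrade(make_trial(), rig, clean_noise(), seed=0)
        f = 312
        i, j = BODYPART_INDEX["digit1"], BODYPART_INDEX["digit4"]
        m = pose.views["mirror"]
        m[f, [i, j], :2] = m[f, [j, i], :2]
        traj = triangulate_series(pose, campair)
        out, removed = filter_by_reprojection(traj, threshold_px=3.0)
        assert removed == 2
        gone = (traj.provenance == Provenance.TRIANGULATED) \
            & (out.provenance == Provenance.MISSING)
        assert set(zip(*np.nonzero(gone))) == {(f, i), (f, j)}


class TestEstimateMissingPoints:
    def test_single_frame_gap_recovered_exactly_on_linear_motion(self, rig, campair):
        gt = make_trial()
        pose = project_and_degrade(gt, rig, clean_noise(), seed=0)
        f, p = 50, BODYPART_INDEX["pawdorsum"]    # pre-reach hold: linear track
        pose.views["mirror"][f, p, 2] = 0.0       # lost in one view only
        traj = triangulate_series(pose, campair)
        assert traj.provenance[f, p] == Provenance.MISSING
        filled = estimate_missing_points(traj, pose, campair)
        assert filled.provenance[f, p] == Provenance.ESTIMATED
        expected = gt[f, p] @ np.diag([-1, 1, -1]) + [0, 40, 250]
        assert np.abs(filled.positions[f, p] - expected).max() < 1e-6

    def test_gap_longer_than_max_gap_stays_missing(self, rig, campair):
        pose = project_and_degrade(make_trial(), rig, clean_noise(), seed=0)
        p = BODYPART_INDEX["digit2"]
        pose.views["mirror"][40:47, p, 2] = 0.0   # 7-frame gap > max_gap 5
        traj = triangulate_series(pose, campair)
        filled = estimate_missing_points(traj, pose, campair, max_gap=5)
        assert (filled.provenance[40:47, p] == Provenance.MISSING).all()

    def test_estimate_violating_single_view_label_rejected(self, rig, campair):
        """A jump fixture: the observed single-view label is displaced far
        from where the interpolated track projects, so the estimate must be
        rejected."""
        pose = project_and_degrade(make_trial(), rig, clean_noise(), seed=0)
        f, p = 50, BODYPART_INDEX["pawdorsum"]
        pose.views["mirror"][f, p, 2] = 0.0
        pose.views["direct"][f, p, 0] += 25.0     # fake jump in the kept view
        traj = triangulate_series(pose, campair)
        filled = estimate_missing_points(traj, pose, campair, tol_px=3.0)
        assert filled.provenance[f, p] == Provenance.MISSING


class TestPelletFrame:
    def test_pellet_maps_to_origin(self, rig, campair):
        pose = project_and_degrade(make_trial(), rig, clean_noise(), seed=0)
        traj = triangulate_series(pose, campair)
        out = to_pellet_frame(traj, "right")
        pellet = out.part("pellet")[:300]
        assert np.nanmax(np.abs(np.nanmedian(pellet, axis=0))) < 1e-9

    def test_left_paw_x_negation(self, rig, campair):
        gt = make_trial()
        pose = project_and_degrade(gt, rig, clean_noise(), seed=0)
        traj = triangulate_series(pose, campair)
        right = to_pellet_frame(traj, "right")
        left = to_pellet_frame(traj, "left")
        # same physical point: +2 mm right of pellet for a right-pawed rat
        # shows as -2 mm for a left-pawed session
        assert np.allclose(left.positions[..., 0], -right.positions[..., 0],
                           equal_nan=True)
        assert np.allclose(left.positions[..., 1:], right.positions[..., 1:],
                           equal_nan=True)

    def test_rigid_transform_preserves_distances(self, rig, campair):
        pose = project_and_degrade(make_trial(), rig, clean_noise(), seed=0)
        traj = triangulate_series(pose, campair)
        out = to_pellet_frame(traj, "right")
        f = 320
        d_before = np.linalg.norm(traj.positions[f, 0] - traj.positions[f, 3])
        d_after = np.linalg.norm(out.positions[f, 0] - out.positions[f, 3])
        assert np.isclose(d_before, d_after, atol=1e-9)

    def test_pellet_never_tracked_is_error(self, rig, campair):
        pose = project_and_degrade(make_trial(), rig, clean_noise(), seed=0)
        pose.views["direct"][:, BODYPART_INDEX["pellet"], 2] = 0.0
        traj = triangulate_series(pose, campair)
        with pytest.raises(ValueError, match="pellet"):
            to_pellet_frame(traj, "right")


class TestNoiseDegradation:
    def test_rmse_non_decreasing_in_label_noise(self, rig, campair):
        gt = make_trial()
        cam_gt = gt @ np.diag([-1, 1, -1]) + [0, 40, 250]
        rmses = []
        for sd in (0.0, 0.5, 2.0):
            pose = project_and_degrade(
                gt, rig, NoiseConfig(px_sd=sd, p_missing=0.0, p_mislabel=0.0),
                seed=7)
            traj = triangulate_series(pose, campair)
            err = traj.positions - cam_gt
            rmses.append(np.sqrt(np.nanmean(np.sum(err**2, axis=2))))
        assert rmses[0] < 1e-6
        assert rmses[0] <= rmses[1] <= rmses[2]
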