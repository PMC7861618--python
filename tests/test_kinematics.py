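"""Kinematic measures and advancement-coordinate profiles."""

import numpy as np
import pytest

from skilledreach.kinematics import (
    EXTENT_GRID, aperture, orientation, profile_by_extent, reach_kinematics,
    sample_profile, speed_series,
)
from skilledreach.reach_events import detect_reaches
from skilledreach.synth import ReachGenParams, simulate_reach
from skilledreach.types import BODYPART_INDEX, BODYPARTS, ReachEvent
from tests.conftest import truth_trajectory


def frame_with_tips(d1, d4):
    pts = np.zeros((len(BODYPARTS), 3))
    pts[BODYPART_INDEX["digit1"]] = d1
    pts[BODYPART_INDEX["digit4"]] = d4
    return pts


class TestAperture:
    def test_known_distance(self):
        assert aperture(frame_with_tips((-2, 0, 5), (2, 0, 5))) == 4.0

    def test_coincident_tips_zero(self):
        assert aperture(frame_with_tips((1, 2, 3), (1, 2, 3))) == 0.0

    def test_missing_tip_propagates_nan(self):
        assert np.isnan(aperture(frame_with_tips((np.nan,) * 3, (2, 0, 5))))

    def test_invariant_under_rigid_pellet_frame_change(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(len(BODYPARTS), 3))
        # arbitrary rotation + translation (the pellet-frame change is rigid)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        moved = pts @ R.T + [3.0, -2.0, 10.0]
        assert np.isclose(aperture(pts), aperture(moved), atol=1e-12)


class TestOrientation:
    def test_horizontal_line_is_zero_degrees(self):
        assert orientation(frame_with_tips((0, 0, 5), (4, 0, 5))) == 0.0

    def test_vertical_line_is_ninety_degrees(self):
        assert orientation(frame_with_tips((0, 0, 5), (0, -4, 5))) == 90.0

    def test_left_paw_mirror_symmetry(self):
        """A left-paw configuration mirrored in x has the same orientation
        as its right-paw twin."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            d1, d4 = rng.normal(size=(2, 3)) * 5
            right = frame_with_tips(d1, d4)
            mirrored = right.copy()
            mirrored[:, 0] *= -1
            assert np.isclose(orientation(right, "right"),
                              orientation(mirrored, "left"), atol=1e-12)

    def test_coincident_projection_undefined(self):
        # tips differ only in z: frontal-plane projection collapses
        assert np.isnan(orientation(frame_with_tips((1, 1, 0), (1, 1, 9))))


class TestSpeed:
    def test_one_mm_per_frame_is_300_mm_per_s(self):
        pos = np.zeros((5, len(BODYPARTS), 3))
        pos[:, BODYPART_INDEX["pawdorsum"], 2] = np.arange(5)  # 1 mm steps
        s = speed_series(truth_trajectory(pos))
        assert np.allclose(s, 300.0)

    def test_stationary_dorsum_zero(self):
        pos = np.ones((4, len(BODYPARTS), 3))
        assert np.allclose(speed_series(truth_trajectory(pos)), 0.0)

    def test_constant_velocity_flat_series(self):
        v = np.array([1.0, -2.0, 0.5])  # mm/frame
        pos = np.zeros((10, len(BODYPARTS), 3))
        pos[:, BODYPART_INDEX["pawdorsum"], :] = np.arange(10)[:, None] * v
        s = speed_series(truth_trajectory(pos))
        assert np.allclose(s, np.linalg.norm(v) * 300.0, atol=1e-9)

    def test_gap_gives_nan_not_bridged(self):
        pos = np.zeros((6, len(BODYPARTS), 3))
        pos[:, BODYPART_INDEX["pawdorsum"], 2] = np.arange(6)
        pos[3, BODYPART_INDEX["pawdorsum"], :] = np.nan
        s = speed_series(truth_trajectory(pos))
        assert np.isnan(s[2]) and np.isnan(s[3])
        assert np.isfinite(s[0])


class TestExtentProfile:
    def test_grid_has_351_points(self):
        assert len(EXTENT_GRID) == 351
        assert EXTENT_GRID[0] == -20.0 and EXTENT_GRID[-1] == 15.0
        assert np.allclose(np.diff(EXTENT_GRID), 0.1)

    def test_linear_digit_motion_interpolated_exactly(self):
        # digit positions linear in z_digit2: cubic Hermite reproduces them
        n = 20
        z = np.linspace(-18, 10, n)
        pos = np.zeros((n, len(BODYPARTS), 3))
        for i in range(1, 5):
            pos[:, BODYPART_INDEX[f"digit{i}"], 0] = 2.0 * z + i
            pos[:, BODYPART_INDEX[f"digit{i}"], 1] = -0.5 * z
            pos[:, BODYPART_INDEX[f"digit{i}"], 2] = z
        traj = truth_trajectory(pos)
        prof = profile_by_extent(traj, ReachEvent(0, 0, 0, n - 1))
        on = prof.mask
        assert np.allclose(prof.digits[0, on, 0], 2.0 * EXTENT_GRID[on] + 1, atol=1e-9)
        assert np.allclose(prof.digits[3, on, 1], -0.5 * EXTENT_GRID[on], atol=1e-9)

    def test_mask_covers_observed_range_only(self):
        n = 15
        z = np.linspace(-12, 3, n)
        pos = np.zeros((n, len(BODYPARTS), 3))
        pos[:, :, 2] = z[:, None]
        prof = profile_by_extent(truth_trajectory(pos), ReachEvent(0, 0, 0, n - 1))
        assert np.array_equal(prof.mask, (EXTENT_GRID >= -12) & (EXTENT_GRID <= 3))
        assert np.isnan(prof.aperture[~prof.mask]).all()

    def test_too_few_frames_empty_profile(self):
        pos = np.zeros((3, len(BODYPARTS), 3))
        pos[:, :, 2] = [[-10], [-5], [0]]
        prof = profile_by_extent(truth_trajectory(pos), ReachEvent(0, 0, 0, 2))
        assert not prof.mask.any()

    def test_no_overshoot_on_monotone_segments(self):
        """Shape-preserving interpolation: aperture stays within the range
        of its generating logistic (no cubic overshoot)."""
        r = simulate_reach(ReachGenParams(), seed=2, endpoint_z=5.0)
        traj = truth_trajectory(r.positions)
        (event,) = detect_reaches(traj)
        prof = profile_by_extent(traj, event)
        a_min, a_max = 5.0, 14.0
        assert np.nanmin(prof.aperture) >= a_min - 1e-6
        assert np.nanmax(prof.aperture) <= a_max + 1e-6

    def test_generator_z_half_recovered_within_tenth_mm(self):
        """Round trip: refitting a logistic to the interpolated aperture
        curve recovers the generator's z_half at zero noise."""
        from scipy.optimize import curve_fit
        from scipy.special import expit

        p = ReachGenParams(aperture_profile=(5.0, 14.0, -7.0, 0.8))
        r = simulate_reach(p, seed=3, endpoint_z=6.0)
        traj = truth_trajectory(r.positions)
        (event,) = detect_reaches(traj)
        prof = profile_by_extent(traj, event)
        on = prof.mask

        def logistic(z, lo, hi, z_half, slope):
            return lo + (hi - lo) * expit(slope * (z - z_half))

        popt, _ = curve_fit(logistic, EXTENT_GRID[on], prof.aperture[on],
                            p0=(4.0, 12.0, -5.0, 1.0))
        assert abs(popt[2] - (-7.0)) < 0.1


class TestSampleProfile:
    def _profiles(self, endpoints, seed=4):
        rng = np.random.default_rng(seed)
        out = []
        for ez in endpoints:
            r = simulate_reach(ReachGenParams(), rng, endpoint_z=ez)
            traj = truth_trajectory(r.positions)
            (event,) = detect_reaches(traj)
            out.append(profile_by_extent(traj, event))
        return out

    def test_all_reaches_covering_counts_all(self):
        profs = self._profiles([4.0, 5.0, 6.0])
        vals, mean, n = sample_profile(profs, -7.0)
        assert n == 3
        assert np.isclose(mean, np.nanmean(vals))

    def test_short_reaches_excluded_from_average(self):
        # half the reaches end before the query point: only covering half counts
        profs = self._profiles([4.0, 4.5, -10.0, -11.0])
        vals, mean, n = sample_profile(profs, 1.0)
        assert n == 2
        assert np.isnan(vals[2]) and np.isnan(vals[3])

    def test_mean_matches_bruteforce_over_interpolated_arrays(self):
        profs = self._profiles([3.0, 5.0, -2.0, 6.0])
        j = int(np.argmin(np.abs(EXTENT_GRID - (-5.0))))
        brute = np.nanmean([p.aperture[j] for p in profs if p.mask[j]])
        _, mean, _ = sample_profile(profs, -5.0)
        assert np.isclose(mean, brute, atol=1e-12)

    def test_off_grid_query_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            sample_profile(self._profiles([4.0]), -7.03)

    def test_no_covering_reach_undefined(self):
        vals, mean, n = sample_profile(self._profiles([-12.0]), 10.0)
        assert n == 0 and np.isnan(mean)


class TestReachKinematics:
    def test_summary_fields_consistent(self):
        r = simulate_reach(ReachGenParams(), seed=5, endpoint_z=4.0)
        traj = truth_trajectory(r.positions)
        (event,) = detect_reaches(traj)
        k = reach_kinematics(traj, event)
        assert np.isclose(k.max_extent, traj.z_digit2()[event.end_frame])
        assert k.end_aperture >= 0
        assert 0 <= k.end_orientation <= 90
        assert k.max_velocity > 0
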