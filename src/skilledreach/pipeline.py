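"""End-to-end file-based pipeline: poses -> trajectories -> analysis tables.

`run_pipeline` consumes a session manifest plus calibration artifacts and
executes reconstruct -> segment -> kinematics -> session metrics -> stats,
writing every intermediate as a plain text table together with a run log
recording seeds, versions, and each threshold actually used.  Stage
failures abort with a stage-tagged message.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CameraPair, derive_camera_pair, estimate_fundamental
from .config import DEFAULT_CONFIG, load_config
from .io import (
    events_to_frame, read_correspondences, read_manifest, read_pose_table,
    write_trajectory,
)
from .kinematics import profile_by_extent, reach_kinematics
from .reach_events import detect_reaches
from .reconstruction import (
    estimate_missing_points, filter_by_reprojection, to_pellet_frame,
    triangulate_series,
)
from .summaries import group_laser_lmm, normalized_success, session_summary
from .types import Pose2DSeries, Trajectory3D

__all__ = ["calibrate_from_file", "analyze_trial", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised with a stage-tagged message when any stage fails."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def calibrate_from_file(corr_path: str | Path, intrinsics: np.ndarray,
                        square_size_mm: float) -> CameraPair:
    corr = read_correspondences(corr_path)
    F = estimate_fundamental(corr, cx=float(np.asarray(intrinsics)[0, 2]))
    return derive_camera_pair(F, intrinsics, corr, square_size_mm)


def analyze_trial(pose: Pose2DSeries, pair: CameraPair, paw_side: str,
                  cfg: dict | None = None, trial: int = 0):
    """Reconstruct and segment one trial.

    Returns ``(trajectory, events, kinematics_rows, profiles)`` where the
    trajectory is in the pellet frame.
    """
    cfg = cfg or DEFAULT_CONFIG
    traj = triangulate_series(pose, pair, conf_min=cfg["conf_min"])
    traj, _ = filter_by_reprojection(traj, threshold_px=cfg["reproj_threshold_px"])
    traj = estimate_missing_points(traj, pose, pair, conf_min=cfg["conf_min"],
                                   max_gap=cfg["max_gap_frames"],
                                   tol_px=cfg["estimate_tol_px"])
    traj = to_pellet_frame(traj, paw_side,
                           pellet_window=cfg["pellet_window_frames"],
                           min_pellet_frames=cfg["min_pellet_frames"])
    events = detect_reaches(traj, slot_z=cfg["slot_z_mm"], trial=trial,
                            min_advance_mm=cfg["min_advance_mm"],
                            min_frames=cfg["min_reach_frames"],
                            retract_hysteresis_mm=cfg["retract_hysteresis_mm"],
                            max_gap=cfg["max_gap_frames"])
    kin_rows = [asdict(reach_kinematics(traj, e)) for e in events]
    profiles = [profile_by_extent(traj, e) for e in events if e.is_first_reach]
    return traj, events, kin_rows, profiles


def run_pipeline(manifest_path: str | Path, out_dir: str | Path,
                 config_path: str | Path | None = None,
                 intrinsics: np.ndarray | None = None) -> dict:
    """Execute the full analysis for every session in a manifest.

    The manifest (YAML) lists rats with group/paw-side and per-session
    stage, pose-table files and a correspondence file for calibration; see
    the synthetic writer in :mod:`skilledreach.cli`.  Writes trajectories,
    reach events, per-reach kinematics, the rat-session summary, per-group
    mixed-model coefficient tables, and ``run_log.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)
    try:
        manifest = read_manifest(manifest_path, check_files=True)
    except (FileNotFoundError, ValueError) as exc:
        raise PipelineError("manifest", str(exc)) from exc
    base = Path(manifest_path).parent
    if intrinsics is None:
        intrinsics = np.asarray(manifest["intrinsics"], dtype=float)

    all_kin: list[dict] = []
    trial_rows: list[dict] = []
    for rat in manifest["rats"]:
        for sess in rat["sessions"]:
            try:
                pair = calibrate_from_file(base / sess["correspondences"],
                                           intrinsics, cfg["square_size_mm"])
            except (ValueError, OSError) as exc:
                raise PipelineError("calibrate", f"{sess['correspondences']}: {exc}") from exc
            outcomes = sess.get("outcomes", [])
            for t, (fd, fm) in enumerate(zip(sess["poses_direct"], sess["poses_mirror"])):
                try:
                    pose = read_pose_table(base / fd, base / fm)
                except ValueError as exc:
                    raise PipelineError("read_poses", str(exc)) from exc
                try:
                    traj, events, kin_rows, _ = analyze_trial(
                        pose, pair, rat["paw_side"], cfg, trial=t)
                except ValueError:
                    traj, events, kin_rows = None, [], []
                tag = f"{rat['id']}_s{sess['session']:02d}_t{t:03d}"
                if traj is not None:
                    write_trajectory(traj, out / f"traj_{tag}.csv", trial=t)
                if events:
                    events_to_frame(events).to_csv(out / f"events_{tag}.csv", index=False)
                first = kin_rows[0] if kin_rows else {}
                trial_rows.append({
                    "rat": rat["id"], "group": rat["group"], "stage": sess["stage"],
                    "session": sess["session"], "trial": t,
                    "outcome": outcomes[t] if t < len(outcomes) else -1,
                    "laser": int(sess["stage"] == "laser_on"),
                    "paw_through_slot": bool(events and events[0].paw_through_slot),
                    "max_extent": first.get("max_extent", np.nan),
                    "end_aperture": first.get("end_aperture", np.nan),
                    "end_orientation": first.get("end_orientation", np.nan),
                    "max_velocity": first.get("max_velocity", np.nan),
                })
                for row in kin_rows:
                    all_kin.append({"rat": rat["id"], "session": sess["session"], **row})

    trials = pd.DataFrame(trial_rows)
    trials.to_csv(out / "trials.csv", index=False)
    pd.DataFrame(all_kin).to_csv(out / "reach_kinematics.csv", index=False)
    summary = session_summary(trials)
    summary = normalized_success(summary)
    summary.to_csv(out / "session_summary.csv", index=False)

    coef_tables = {}
    skipped_models: list[str] = []
    for group in summary["group"].unique():
        sub = summary[summary["group"] == group]
        if sub["rat"].nunique() >= 2 and sub["session"].nunique() >= 2:
            try:
                fit = group_laser_lmm(summary, "mean_max_extent", group)
            except (ValueError, np.linalg.LinAlgError) as exc:
                # degenerate designs (e.g. a single laser session makes
                # laser and laser:session collinear) are recorded, not fatal
                skipped_models.append(f"{group}: {exc}")
                continue
            tab = fit.coef_table()
            tab.to_csv(out / f"lmm_max_extent_{group}.csv", index=False)
            coef_tables[group] = tab

    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": cfg,
        "manifest": str(manifest_path),
        "seeds": manifest.get("seeds", {}),
        "n_trials": len(trials),
        "skipped_models": skipped_models,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return {"trials": trials, "summary": summary, "lmm": coef_tables, "log": log}
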