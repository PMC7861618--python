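"""Readers and writers for the pipeline's file formats.

* Pose tables use the markerless-tracking CSV dialect: three header rows
  (scorer / bodyparts / coords) with x, y, likelihood triplets per body
  part and a leading frame-index column (0-based), one file per view per
  trial — drop-in compatible with deposited tracking output.
* Camera pairs serialize to JSON (see
  :meth:`skilledreach.calibration.CameraPair.save`).
* Correspondences, trajectories, reach events and kinematics are plain
  columnar CSV; the session manifest is YAML.

All numeric writers round-trip at full float precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import BODYPARTS, Pose2DSeries, Provenance, Trajectory3D, ReachEvent

__all__ = [
    "write_pose_table", "read_pose_table",
    "write_correspondences", "read_correspondences",
    "write_trajectory", "read_trajectory",
    "events_to_frame", "write_manifest", "read_manifest",
]

_COORDS = ("x", "y", "likelihood")
_SCORER = "synthetic"


def write_pose_table(pose: Pose2DSeries, view: str, path: str | Path,
                     scorer: str = _SCORER) -> None:
    """Write one view of a pose series in the tracking-table dialect."""
    arr = pose.views[view]
    n = arr.shape[0]
    cols = pd.MultiIndex.from_product([[scorer], pose.bodyparts, _COORDS],
                                      names=["scorer", "bodyparts", "coords"])
    flat = arr.reshape(n, -1)
    pd.DataFrame(flat, columns=cols, index=pd.RangeIndex(n, name="frame")
                 ).to_csv(path, float_format="%.17g")


def read_pose_table(direct_path: str | Path, mirror_path: str | Path,
                    bodyparts: tuple[str, ...] = BODYPARTS) -> Pose2DSeries:
    """Read a direct/mirror pair of pose tables into a series.

    Validates the three-row header, rejects unknown body parts, requires
    both views to cover the same frames, and clips confidences to [0, 1].
    """
    views: dict[str, np.ndarray] = {}
    n_ref: int | None = None
    for view, path in (("direct", direct_path), ("mirror", mirror_path)):
        try:
            df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                             float_precision="round_trip")
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"{path}: malformed pose-table header: {exc}") from exc
        if df.columns.nlevels != 3:
            raise ValueError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
        names = [n.lower() if isinstance(n, str) else n for n in df.columns.names]
        if "coords" not in names:
            raise ValueError(f"{path}: header missing the 'coords' row")
        found = list(dict.fromkeys(df.columns.get_level_values(1)))
        unknown = [b for b in found if b not in bodyparts]
        if unknown:
            raise ValueError(f"{path}: unknown body parts {unknown}")
        missing = [b for b in bodyparts if b not in found]
        if missing:
            raise ValueError(f"{path}: body parts absent from table: {missing}")
        n = len(df)
        arr = np.full((n, len(bodyparts), 3), np.nan)
        for bi, bp in enumerate(bodyparts):
            for ci, coord in enumerate(_COORDS):
                col = df.xs((bp, coord), axis=1, level=(1, 2))
                vals = pd.to_numeric(col.iloc[:, 0], errors="coerce")
                bad = vals.isna() & col.iloc[:, 0].notna() \
                    & (col.iloc[:, 0].astype(str).str.strip() != "")
                if bad.any():
                    row = int(np.flatnonzero(bad)[0])
                    raise ValueError(
                        f"{path}: non-numeric cell at frame {df.index[row]}, "
                        f"column ({bp}, {coord})")
                arr[:, bi, ci] = vals.to_numpy()
        arr[:, :, 2] = np.clip(np.nan_to_num(arr[:, :, 2], nan=0.0), 0.0, 1.0)
        if n_ref is None:
            n_ref = n
        elif n != n_ref:
            raise ValueError("direct and mirror tables cover different frame counts")
        views[view] = arr
    return Pose2DSeries(views=views, bodyparts=bodyparts)


# -- correspondences ---------------------------------------------------------

def write_correspondences(corr, path: str | Path) -> None:
    """Columnar text table: pair_id, u_direct, v_direct, u_mirror, v_mirror."""
    df = pd.DataFrame({
        "pair_id": np.arange(len(corr)),
        "u_direct": corr.direct[:, 0], "v_direct": corr.direct[:, 1],
        "u_mirror": corr.mirror[:, 0], "v_mirror": corr.mirror[:, 1],
    })
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {"square_size_mm": corr.square_size_mm,
            "adjacency": [[int(a), int(b)] for a, b in corr.adjacency]}
    Path(path).with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta))


def read_correspondences(path: str | Path):
    from .synth.camera import CorrespondenceSet

    df = pd.read_csv(path, float_precision="round_trip")
    meta_path = Path(path).with_suffix(".meta.yaml")
    adjacency, square = [], None
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        adjacency = [tuple(p) for p in meta.get("adjacency", [])]
        square = meta.get("square_size_mm")
    return CorrespondenceSet(
        direct=df[["u_direct", "v_direct"]].to_numpy(),
        mirror=df[["u_mirror", "v_mirror"]].to_numpy(),
        adjacency=adjacency, square_size_mm=square)


# -- trajectories ------------------------------------------------------------

def write_trajectory(traj: Trajectory3D, path: str | Path, trial: int = 0) -> None:
    """Long-format table: trial, frame, bodypart, x/y/z (mm), error, provenance."""
    n, p = traj.positions.shape[:2]
    frames = np.repeat(np.arange(n), p)
    parts = np.tile(np.array(traj.bodyparts), n)
    pd.DataFrame({
        "trial": trial, "frame": frames, "bodypart": parts,
        "x_mm": traj.positions[:, :, 0].ravel(),
        "y_mm": traj.positions[:, :, 1].ravel(),
        "z_mm": traj.positions[:, :, 2].ravel(),
        "reproj_err_px": traj.reproj_err.ravel(),
        "provenance": [Provenance(v).name.lower() for v in traj.provenance.ravel()],
    }).to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path: str | Path, paw_side: str = "right",
                    in_pellet_frame: bool = True) -> Trajectory3D:
    df = pd.read_csv(path, float_precision="round_trip")
    parts = tuple(dict.fromkeys(df["bodypart"]))
    n = df["frame"].nunique()
    pos = df[["x_mm", "y_mm", "z_mm"]].to_numpy().reshape(n, len(parts), 3)
    err = df["reproj_err_px"].to_numpy().reshape(n, len(parts))
    prov = np.array([Provenance[p.upper()] for p in df["provenance"]],
                    dtype=np.int8).reshape(n, len(parts))
    return Trajectory3D(positions=pos, reproj_err=err, provenance=prov,
                        bodyparts=parts, paw_side=paw_side,
                        in_pellet_frame=in_pellet_frame)


def events_to_frame(events: list[ReachEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial": e.trial, "reach_idx": e.reach_idx,
        "start_frame": e.start_frame, "end_frame": e.end_frame,
        "is_first_reach": e.is_first_reach,
        "paw_through_slot": e.paw_through_slot, "truncated": e.truncated,
    } for e in events])


# -- manifest ----------------------------------------------------------------

def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path: str | Path, *, check_files: bool = True) -> dict:
    """Load and validate a session manifest.

    Checks group labels against the closed five-group set and (optionally)
    that every referenced file exists.
    """
    from .synth.experiment import GROUPS

    manifest = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    for rat in manifest.get("rats", []):
        if rat.get("group") not in GROUPS:
            raise ValueError(f"manifest: unknown group {rat.get('group')!r}")
        if rat.get("paw_side") not in ("left", "right"):
            raise ValueError(f"manifest: bad paw_side for rat {rat.get('id')}")
        if check_files:
            for sess in rat.get("sessions", []):
                for key in ("poses_direct", "poses_mirror"):
                    for f in sess.get(key, []):
                        if not (base / f).exists():
                            raise FileNotFoundError(f"manifest references missing file: {f}")
    return manifest
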