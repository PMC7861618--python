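"""Default analysis configuration.

Every tunable threshold in the pipeline lives here; a YAML file with the
same keys overrides any subset.  Units: mm for distances, px for image
thresholds, frames for temporal windows.
"""

from __future__ import annotations

from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    # reconstruction
    "conf_min": 0.9,                 # 2D label confidence cutoff
    "reproj_threshold_px": 3.0,      # large-reprojection-error exclusion
    "max_gap_frames": 5,             # longest bridgeable missing-point gap
    "estimate_tol_px": 3.0,          # single-view check for estimated points
    "pellet_window_frames": 100,     # pre-trigger frames for the pellet origin
    "min_pellet_frames": 10,
    # reach segmentation
    "slot_z_mm": -15.0,              # reaching-slot plane (pellet frame)
    "min_advance_mm": 2.0,           # jitter rejection: advance beyond slot
    "min_reach_frames": 3,
    "retract_hysteresis_mm": 0.5,    # sustained-retraction threshold
    # calibration
    "square_size_mm": 4.0,           # checkerboard square edge
    # kinematics
    "end_frame_search": 2,           # fallback window for missing end-frame tips
}


def load_config(path: str | Path | None = None) -> dict:
    """Defaults overlaid with an optional YAML file; unknown keys rejected."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
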