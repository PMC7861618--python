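"""Segmentation of trials into discrete reaches.

A reach is found by locating the first frame in which the second digit tip
is outside the box (its advancement coordinate crosses the reaching-slot
plane, ``slot_z``), walking backwards until the paw dorsum started moving
forward, and ending at the frame where z_digit2 begins to retract — the
maximum reach extent.  Multiple reaches can occur in one trial; a new reach
requires the digit to first retract back behind the slot.  Trials whose
video starts with the paw already through the slot are flagged.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import ReachEvent, Trajectory3D

__all__ = ["detect_reaches", "DEFAULT_SLOT_Z"]

#: Reaching-slot plane: the slot sits 15 mm on the chamber side of the pellet.
DEFAULT_SLOT_Z = -15.0


def detect_reaches(traj: Trajectory3D, slot_z: float = DEFAULT_SLOT_Z,
                   *, trial: int = 0,
                   min_advance_mm: float = 2.0,
                   min_frames: int = 3,
                   retract_hysteresis_mm: float = 0.5,
                   max_gap: int = 5) -> list[ReachEvent]:
    """Segment one trial's trajectory into reach events.

    ``min_advance_mm`` and ``min_frames`` suppress noise-level slot
    crossings (a reach must advance at least that far beyond the slot and
    span at least that many frames).  ``retract_hysteresis_mm`` defines
    sustained retraction: the reach ends at the frame of maximum z_digit2
    before z first drops that far below the running maximum; on clean data
    this is exactly the frame at which the digit begins to retract (for a
    plateau, its last frame).  A run of more than ``max_gap`` missing
    z_digit2 frames at the putative end marks the event truncated.
    """
    z_all = traj.z_digit2()
    valid = np.isfinite(z_all)
    if not valid.any():
        warnings.warn("no valid z_digit2 samples; no reaches detected")
        return []
    vidx = np.flatnonzero(valid)          # original frame numbers
    z = z_all[vidx]
    dorsum_z = traj.part("pawdorsum")[:, 2]

    paw_through_slot = z[0] > slot_z
    events: list[ReachEvent] = []
    i = 0
    n = len(z)
    while i < n:
        # next outward crossing of the slot plane
        if z[i] <= slot_z:
            i += 1
            continue
        if i == 0 and paw_through_slot:
            crossing = 0
        else:
            crossing = i
        # --- walk back: find when the paw dorsum started moving forward ---
        start = crossing
        while start > 0:
            prev_f, cur_f = vidx[start - 1], vidx[start]
            dz = dorsum_z[cur_f] - dorsum_z[prev_f]
            if np.isfinite(dz) and dz <= 0:
                break
            if not np.isfinite(dz) and cur_f - prev_f > max_gap:
                break
            start -= 1
        # --- walk forward: reach ends when z_digit2 begins to retract ---
        running_max = z[crossing]
        end = crossing
        j = crossing
        truncated = False
        while j + 1 < n:
            if vidx[j + 1] - vidx[j] > max_gap:
                truncated = True
                break
            j += 1
            if z[j] >= running_max:
                running_max = z[j]
                end = j
            elif running_max - z[j] >= retract_hysteresis_mm:
                break
        else:
            truncated = True

        advance_ok = running_max >= slot_z + min_advance_mm
        span_ok = (vidx[end] - vidx[start] + 1) >= min_frames and end > start
        if advance_ok and span_ok:
            events.append(ReachEvent(trial=trial, reach_idx=len(events),
                                     start_frame=int(vidx[start]),
                                     end_frame=int(vidx[end]),
                                     is_first_reach=not events,
                                     paw_through_slot=paw_through_slot,
                                     truncated=truncated))
        # a further reach requires full retraction behind the slot first
        i = end + 1
        while i < n and z[i] > slot_z:
            i += 1
    return events
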