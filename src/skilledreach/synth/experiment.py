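"""Ground-truthed synthetic skilled-reaching experiments.

Emulates the study design: rats assigned to optogenetic groups
(stimulation or inhibition of dopamine neurons, delivered during or
between reaches, plus fluorophore-only controls) run one session per day —
retraining, then ten sessions with the laser on, then ten with the light
path occluded.  Trials are 30 frames/s-video-triggered reaches (1300
frames at 300 fps each); outcome codes emerge mechanistically from the
programmed kinematics via a grasp rule, so programmed kinematic drift
produces the success-rate collapse seen with during-reach stimulation.

Effect schedules:

* ``gradual`` — cumulative per-session drift of reach parameters on
  laser-on sessions of during-reach groups (progressive kinematic change),
  reverting toward baseline during occlusion at a configurable rate.
* ``abrupt_blocks`` — the laser alternates off/on every ``block_length``
  trials within a session and the kinematic shift follows the laser state
  trial-by-trial (state-dependent, no drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..types import (
    BODYPART_INDEX, BODYPARTS, FRAMES_PER_TRIAL, TRIGGER_FRAME, Outcome,
)
from .. import kinematics as kin
from ..reach_events import DEFAULT_SLOT_Z
from .camera import CameraRig
from .reach import GroundTruthReach, ReachGenParams, simulate_reach
from .render import NoiseConfig, project_and_degrade

__all__ = [
    "EffectSchedule", "GraspRule", "TrialSpec", "SyntheticSession",
    "ExperimentDesign", "GROUPS", "generate_experiment",
    "generate_alternating_session", "render_trial", "render_session",
]

GROUPS: tuple[str, ...] = (
    "stim_during", "stim_between", "inhibit_during", "inhibit_between", "control",
)

_DRIFT_KEYS = ("extent_mean", "aperture_z_half", "orientation_z_half", "peak_speed")

#: During-reach laser: on from the beam break (before the video) until 3 s
#: after the trigger; between-reach laser: from 4 s after the trigger for
#: 5 s (outside the 1300 saved frames).
LASER_EPOCH_DURING: tuple[int, int] = (0, TRIGGER_FRAME + 900)
LASER_EPOCH_BETWEEN: tuple[int, int] = (TRIGGER_FRAME + 1200, TRIGGER_FRAME + 2700)


@dataclass
class EffectSchedule:
    """How a dopamine manipulation reshapes reach parameters over time.

    ``per_session_drift`` maps parameter names (``extent_mean``,
    ``aperture_z_half``, ``orientation_z_half``, ``peak_speed``) to
    additive changes.  In ``gradual`` mode the drift accumulates across
    stimulated sessions and ``per_trial_drift`` adds within-session drift;
    occlusion sessions shrink the accumulated state by ``recovery_rate``.
    In ``abrupt_blocks`` mode ``per_session_drift`` is instead the
    state-dependent shift applied on laser-on trials (with
    ``per_trial_drift`` scaling by the trial index within a block), and
    the laser alternates every ``block_length`` trials starting off.
    """

    mode: str = "none"
    per_session_drift: dict[str, float] = field(default_factory=dict)
    per_trial_drift: dict[str, float] = field(default_factory=dict)
    block_length: int = 5
    recovery_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "gradual", "abrupt_blocks"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        for d in (self.per_session_drift, self.per_trial_drift):
            for k, v in d.items():
                if k not in _DRIFT_KEYS:
                    raise ValueError(f"unknown drift parameter {k!r}")
                if not np.isfinite(v):
                    raise ValueError(f"drift {k} must be finite")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        if not 0.0 <= self.recovery_rate <= 1.0:
            raise ValueError("recovery_rate must lie in [0, 1]")


#: Default schedules per experimental group.  During-reach stimulation
#: progressively shortens reaches, opens the aperture and pronates the paw
#: earlier (smaller z_half), and slows the reach; during-reach inhibition
#: delays aperture opening; between-reach and control groups are unaffected
#: kinematically.
DEFAULT_SCHEDULES: dict[str, EffectSchedule] = {
    "stim_during": EffectSchedule(
        mode="gradual",
        per_session_drift={"extent_mean": -1.5, "aperture_z_half": -0.8,
                           "orientation_z_half": -0.8, "peak_speed": -40.0},
        per_trial_drift={"extent_mean": -0.01}),
    "inhibit_during": EffectSchedule(
        mode="gradual", per_session_drift={"aperture_z_half": 0.8}),
    "stim_between": EffectSchedule(mode="none"),
    "inhibit_between": EffectSchedule(mode="none"),
    "control": EffectSchedule(mode="none"),
}


@dataclass
class GraspRule:
    """Mechanistic outcome scoring for synthetic reaches.

    A first reach succeeds (code 1) when its maximum extent lands in the
    grasp window [lo, hi] mm past the pellet with the digits spread at
    least one pellet diameter at z = 0.  Short reaches leave the pellet on
    the shelf (7); reaches through/past the window, or with too narrow a
    grasp, knock it off (4); a later reach capturing the pellet scores 2.
    """

    grasp_lo: float = 0.0
    grasp_hi: float = 6.0
    pellet_diameter: float = 3.0

    def first_reach_code(self, max_z: float, aperture_at_pellet: float) -> int:
        if max_z < self.grasp_lo:
            return Outcome.PELLET_REMAINED
        if aperture_at_pellet < self.pellet_diameter:
            return Outcome.KNOCKED_OFF
        if max_z > self.grasp_hi:
            return Outcome.KNOCKED_OFF
        return Outcome.FIRST_SUCCESS


@dataclass
class TrialSpec:
    """Deterministic recipe for re-rendering one trial's ground truth."""

    trial: int
    kind: str                      # 'reach' | 'trigger_error' | 'no_pellet'
    laser: bool
    params: ReachGenParams | None
    endpoint_z: float | None
    second_endpoint_z: float | None
    start_frame: int
    second_gap: int
    paw_through_slot: bool
    seed: int


@dataclass
class SyntheticSession:
    """One synthetic 30-min session: trial table plus re-render recipes.

    ``trials`` has one row per trial with the outcome code, laser flag and
    ground-truth kinematic summaries; ``specs`` allows deterministic
    re-rendering of full 1300-frame trajectories and pose tables.
    """

    rat: str
    group: str
    paw_side: str
    stage: str                     # retraining | laser_on | occlusion | alternating
    session_index: int
    trials: pd.DataFrame
    specs: list[TrialSpec]
    laser_epoch: tuple[int, int] | None

    @property
    def outcomes(self) -> np.ndarray:
        return self.trials["outcome"].to_numpy(dtype=int)


@dataclass
class ExperimentDesign:
    """Group roster and per-rat session layout for a synthetic experiment."""

    groups: tuple[str, ...] = ("stim_during", "stim_between", "control")
    rats_per_group: int = 6
    trials_per_session: int = 60
    retraining_sessions: int = 2
    laser_sessions: int = 10
    occlusion_sessions: int = 10
    base_params: ReachGenParams = field(default_factory=ReachGenParams)
    grasp_rule: GraspRule = field(default_factory=GraspRule)
    schedules: dict[str, EffectSchedule] = field(default_factory=dict)
    p_trigger_error: float = 0.03
    p_no_pellet: float = 0.02
    p_paw_through_slot: float = 0.01
    p_second_reach: float = 0.15

    def __post_init__(self) -> None:
        for g in self.groups:
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}; expected one of {GROUPS}")

    def schedule_for(self, group: str) -> EffectSchedule:
        return self.schedules.get(group, DEFAULT_SCHEDULES[group])

    def stages(self) -> list[tuple[str, int]]:
        out = [("retraining", i + 1) for i in range(self.retraining_sessions)]
        out += [("laser_on", i + 1) for i in range(self.laser_sessions)]
        out += [("occlusion", i + 1) for i in range(self.occlusion_sessions)]
        return out


def _shifted_params(base: ReachGenParams, shifts: dict[str, float]) -> ReachGenParams:
    return base.shifted(
        extent_mean=shifts.get("extent_mean", 0.0),
        aperture_z_half=shifts.get("aperture_z_half", 0.0),
        orientation_z_half=shifts.get("orientation_z_half", 0.0),
        peak_speed=shifts.get("peak_speed", 0.0),
    )


def _reach_summary(reach: GroundTruthReach) -> tuple[float, float, float, float]:
    """(max_extent, end_aperture, end_orientation, max_velocity) of a reach."""
    end = reach.positions[reach.endpoint_frame]
    ap = kin.aperture(end)
    ori = kin.orientation(end)
    dorsum = reach.part("pawdorsum")
    speed = np.linalg.norm(np.diff(dorsum, axis=0), axis=1) * reach.params.frame_rate
    return reach.endpoint_z, float(ap), float(ori), float(speed.max())


def _simulate_trial(t: int, params: ReachGenParams, rule: GraspRule,
                    laser: bool, design: ExperimentDesign,
                    rng: np.random.Generator) -> tuple[TrialSpec, dict]:
    """Draw one trial: kind, reach endpoints, outcome, and summaries."""
    trial_seed = int(rng.integers(2**31))
    u = rng.random()
    if u < design.p_no_pellet:
        kind, code = "no_pellet", int(Outcome.NO_PELLET)
    elif u < design.p_no_pellet + design.p_trigger_error:
        kind, code = "trigger_error", int(Outcome.TRIGGER_ERROR)
    else:
        kind = "reach"
        code = -1
    paw_through = kind == "reach" and rng.random() < design.p_paw_through_slot
    if paw_through:
        sp = list(params.start_position)
        sp[2] = DEFAULT_SLOT_Z + 0.5   # video triggered late: paw already out
        params = replace(params, start_position=tuple(sp))

    if kind != "reach":
        spec = TrialSpec(trial=t, kind=kind, laser=laser, params=None,
                         endpoint_z=None, second_endpoint_z=None,
                         start_frame=TRIGGER_FRAME, second_gap=0,
                         paw_through_slot=False, seed=trial_seed)
        summary = dict(trial=t, outcome=code, laser=laser, paw_through_slot=False,
                       n_reaches=0, max_extent=np.nan, end_aperture=np.nan,
                       end_orientation=np.nan, max_velocity=np.nan)
        return spec, summary

    endpoint = float(rng.normal(params.extent_mean, params.extent_sd))
    reach = simulate_reach(params, trial_seed, endpoint_z=endpoint)
    max_z, ap_end, ori_end, vmax = _reach_summary(reach)
    ap_pellet = float(params.aperture_at(0.0))
    code = rule.first_reach_code(max_z, ap_pellet)

    second_z: float | None = None
    n_reaches = 1
    if code != Outcome.FIRST_SUCCESS and rng.random() < design.p_second_reach:
        second_z = float(rng.normal(params.extent_mean, params.extent_sd))
        n_reaches = 2
        if rule.first_reach_code(second_z, ap_pellet) == Outcome.FIRST_SUCCESS:
            code = int(Outcome.MULTI_TRY_SUCCESS)

    start = TRIGGER_FRAME - 5 + int(rng.integers(0, 11))
    spec = TrialSpec(trial=t, kind="reach", laser=laser, params=params,
                     endpoint_z=max_z, second_endpoint_z=second_z,
                     start_frame=start, second_gap=int(rng.integers(30, 81)),
                     paw_through_slot=paw_through, seed=trial_seed)
    summary = dict(trial=t, outcome=int(code), laser=laser,
                   paw_through_slot=paw_through, n_reaches=n_reaches,
                   max_extent=max_z, end_aperture=ap_end,
                   end_orientation=ori_end, max_velocity=vmax)
    return spec, summary


def _make_session(rat: str, group: str, paw_side: str, stage: str,
                  session_index: int, trial_shifts, laser_flags,
                  design: ExperimentDesign, rng: np.random.Generator,
                  ) -> SyntheticSession:
    specs: list[TrialSpec] = []
    rows: list[dict] = []
    for t in range(design.trials_per_session):
        params = _shifted_params(design.base_params, trial_shifts(t))
        spec, summary = _simulate_trial(t, params, design.grasp_rule,
                                        bool(laser_flags(t)), design, rng)
        specs.append(spec)
        rows.append(summary)
    if stage == "laser_on" or stage == "alternating":
        epoch = LASER_EPOCH_DURING if group.endswith("_during") or stage == "alternating" \
            else LASER_EPOCH_BETWEEN
    else:
        epoch = None
    return SyntheticSession(rat=rat, group=group, paw_side=paw_side, stage=stage,
                            session_index=session_index,
                            trials=pd.DataFrame(rows), specs=specs,
                            laser_epoch=epoch)


def generate_experiment(design: ExperimentDesign | None = None,
                        seed: int | None = None) -> list[SyntheticSession]:
    """Simulate every session of a multi-rat, multi-group experiment.

    Sessions run retraining -> laser-on -> occlusion per rat.  Gradual
    schedules accumulate only on laser-on sessions of during-reach groups
    and decay toward baseline during occlusion.  Identical design and seed
    reproduce the experiment exactly.
    """
    design = design or ExperimentDesign()
    root = np.random.SeedSequence(seed)
    sessions: list[SyntheticSession] = []
    for gi, group in enumerate(design.groups):
        schedule = design.schedule_for(group)
        for ri in range(design.rats_per_group):
            rng = np.random.default_rng(root.spawn(1)[0])
            rat = f"{group}_r{ri + 1}"
            paw_side = "right" if ri % 2 == 0 else "left"
            state = {k: 0.0 for k in _DRIFT_KEYS}
            for si, (stage, k_in_stage) in enumerate(design.stages(), start=1):
                stimulated = (stage == "laser_on" and group.endswith("_during")
                              and schedule.mode == "gradual")
                if stimulated:
                    for k, v in schedule.per_session_drift.items():
                        state[k] += v
                elif stage == "occlusion":
                    for k in state:
                        state[k] *= (1.0 - schedule.recovery_rate)

                def shifts(t: int, _state=dict(state), _stim=stimulated) -> dict:
                    if not _stim:
                        return _state
                    return {k: _state[k] + t * schedule.per_trial_drift.get(k, 0.0)
                            for k in _state}

                laser = stage == "laser_on"
                sessions.append(_make_session(
                    rat, group, paw_side, stage, si,
                    trial_shifts=shifts, laser_flags=lambda t, _l=laser: _l,
                    design=design, rng=rng))
    return sessions


def generate_alternating_session(rat: str, group: str, seed: int | None = None,
                                 *, design: ExperimentDesign | None = None,
                                 schedule: EffectSchedule | None = None,
                                 session_index: int = 1,
                                 paw_side: str = "right") -> SyntheticSession:
    """One 5-off/5-on alternating-block session.

    The laser alternates between off and on every ``block_length`` trials
    (starting off); the kinematic shift follows the current laser state
    (constant within a block up to ``per_trial_drift``), modeling rats
    whose reaches switch between normal and impaired within one trial.
    """
    design = design or ExperimentDesign()
    schedule = schedule or EffectSchedule(
        mode="abrupt_blocks",
        per_session_drift={"extent_mean": -3.0, "aperture_z_half": -1.5})
    if schedule.mode != "abrupt_blocks":
        raise ValueError("alternating sessions need an abrupt_blocks schedule")
    rng = np.random.default_rng(seed)
    L = schedule.block_length

    def laser_flags(t: int) -> bool:
        return (t // L) % 2 == 1

    def shifts(t: int) -> dict:
        if not laser_flags(t):
            return {k: 0.0 for k in _DRIFT_KEYS}
        within = t % L
        return {k: schedule.per_session_drift.get(k, 0.0)
                + within * schedule.per_trial_drift.get(k, 0.0)
                for k in _DRIFT_KEYS}

    return _make_session(rat, group, paw_side, "alternating", session_index,
                         trial_shifts=shifts, laser_flags=laser_flags,
                         design=design, rng=rng)


# ---------------------------------------------------------------------------
# Rendering stored trial recipes back into full trajectories / pose tables
# ---------------------------------------------------------------------------

def render_trial(spec: TrialSpec, paw_side: str = "right") -> np.ndarray:
    """Re-render one trial's (1300, n_parts, 3) pellet-frame ground truth.

    The paw holds its start posture behind the slot for the pre-trigger
    frames, reaches (and possibly reaches again) after the trigger, then
    holds its final posture.  Left-paw trials are mirrored in x.
    """
    n_parts = len(BODYPARTS)
    gt = np.empty((FRAMES_PER_TRIAL, n_parts, 3))
    if spec.kind != "reach":
        hold = simulate_reach(ReachGenParams(), spec.seed, endpoint_z=3.0).positions[0]
        gt[:] = hold
        if spec.kind == "no_pellet":
            gt[:, BODYPART_INDEX["pellet"], :] = np.nan
    else:
        assert spec.params is not None
        reach = simulate_reach(spec.params, spec.seed, endpoint_z=spec.endpoint_z)
        gt[:] = reach.positions[0]
        f0 = spec.start_frame
        f1 = min(f0 + reach.n_frames, FRAMES_PER_TRIAL)
        gt[f0:f1] = reach.positions[:f1 - f0]
        gt[f1:] = reach.positions[-1]
        if spec.second_endpoint_z is not None:
            reach2 = simulate_reach(spec.params, spec.seed + 1,
                                    endpoint_z=spec.second_endpoint_z)
            g0 = min(f1 + spec.second_gap, FRAMES_PER_TRIAL)
            g1 = min(g0 + reach2.n_frames, FRAMES_PER_TRIAL)
            gt[g0:g1] = reach2.positions[:g1 - g0]
            gt[g1:] = reach2.positions[-1]
    if paw_side == "left":
        gt = gt.copy()
        gt[..., 0] *= -1.0
    return gt


def render_session(session: SyntheticSession, rig: CameraRig,
                   noise: NoiseConfig | None = None,
                   seed: int | None = None,
                   ) -> tuple[list, list[np.ndarray]]:
    """Render a session's pose tables (both views) and ground truth.

    Returns ``(pose_series_per_trial, ground_truth_per_trial)``; rendering
    is deterministic given the session (whose specs carry trial seeds) and
    ``seed`` for the degradation noise.
    """
    rng = np.random.default_rng(seed)
    poses, truths = [], []
    for spec in session.specs:
        gt = render_trial(spec, session.paw_side)
        poses.append(project_and_degrade(gt, rig, noise, rng))
        truths.append(gt)
    return poses, truths
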