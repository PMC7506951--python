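"""Synthetic patient simulator.

Stands in for the child and the depth camera: given a target posture it
produces a per-tick joint-angle trajectory for both limbs.  The behavioural
model is deliberately simple — a reaction latency, a linear ramp from a rest
pose toward the target clamped to the limb's range of motion (ROM), then
Gaussian jitter whose scale shrinks with repeated attempts — plus an
occasional "distraction" in which the patient wanders to an unrelated far
posture.  Presets qualitatively mimic common impairment patterns (one-sided
ROM deficit, dystonia-like tremor, global restriction); they are test
harness material, not clinical models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .kinematics import ANGLE_NAMES, JointAngles, TargetPose
from .session import STAGES, AttemptTrajectory, Exercise, Responder, SessionConfig

__all__ = [
    "JOINT_ENVELOPES",
    "POSE_LIBRARY",
    "PatientProfile",
    "PRESET_KINDS",
    "make_preset_profile",
    "simulate_response",
    "responder_from_profile",
    "make_session_plan",
    "load_profile",
    "dump_profile",
]

#: Per-joint anatomical envelopes (radians): openings are non-negative.
JOINT_ENVELOPES: dict[str, tuple[float, float]] = {
    "shoulder_rotation": (-math.pi, math.pi),
    "shoulder_opening": (0.0, math.pi),
    "elbow_rotation": (-math.pi, math.pi),
    "elbow_opening": (0.0, math.pi),
}

_PI = math.pi


def _angles(sr: float, so: float, er: float, eo: float) -> JointAngles:
    return JointAngles(sr, so, er, eo)


#: Library of named reachable arm postures (left, right), the source of
#: session plans and classifier targets.  Angles in radians under the
#: torso-centred convention (opening 0 = arm down, rotation 0 = forward).
POSE_LIBRARY: dict[str, tuple[JointAngles, JointAngles]] = {
    "arms_down": (_angles(0.0, 0.05, 0.0, _PI - 0.05), _angles(0.0, 0.05, 0.0, _PI - 0.05)),
    "both_forward": (_angles(0.0, _PI / 2, 0.0, _PI - 0.1), _angles(0.0, _PI / 2, 0.0, _PI - 0.1)),
    "t_pose": (_angles(_PI / 2, _PI / 2, 0.0, _PI - 0.1), _angles(-_PI / 2, _PI / 2, 0.0, _PI - 0.1)),
    "both_up": (_angles(_PI / 2, 2.8, 0.0, _PI - 0.15), _angles(-_PI / 2, 2.8, 0.0, _PI - 0.15)),
    "left_forward": (_angles(0.0, _PI / 2, 0.0, _PI - 0.1), _angles(0.0, 0.1, 0.0, _PI - 0.1)),
    "right_forward": (_angles(0.0, 0.1, 0.0, _PI - 0.1), _angles(0.0, _PI / 2, 0.0, _PI - 0.1)),
    "left_side_raise": (_angles(_PI / 2, 1.9, 0.0, _PI - 0.1), _angles(0.0, 0.1, 0.0, _PI - 0.1)),
    "right_side_raise": (_angles(0.0, 0.1, 0.0, _PI - 0.1), _angles(-_PI / 2, 1.9, 0.0, _PI - 0.1)),
    "cactus": (_angles(_PI / 2, _PI / 2, 1.2, _PI / 2), _angles(-_PI / 2, _PI / 2, -1.2, _PI / 2)),
    "hands_front_bent": (_angles(0.0, 1.0, 0.6, _PI / 3), _angles(0.0, 1.0, -0.6, _PI / 3)),
    "left_reach_up": (_angles(0.4, 2.6, 0.0, _PI - 0.2), _angles(0.0, 0.3, 0.0, _PI - 0.1)),
    "right_reach_up": (_angles(0.0, 0.3, 0.0, _PI - 0.1), _angles(-0.4, 2.6, 0.0, _PI - 0.2)),
    "touch_shoulders": (_angles(0.0, 0.4, 0.3, 0.5), _angles(0.0, 0.4, -0.3, 0.5)),
}

#: Rest posture: arms hanging down, elbows straight.
REST_POSE: dict[str, JointAngles] = {
    "left": _angles(0.0, 0.05, 0.0, _PI - 0.05),
    "right": _angles(0.0, 0.05, 0.0, _PI - 0.05),
}

_SIDES = ("left", "right")
RomMap = dict[str, dict[str, tuple[float, float]]]


@dataclass(frozen=True)
class PatientProfile:
    """Per-limb impairment model driving the simulator.

    Attributes
    ----------
    rom
        ``{side: {joint: (min, max)}}`` range-of-motion limits in radians;
        targets are clamped into this box before the patient approaches them.
    noise_scale
        ``{side: s.d.}`` of the per-joint per-tick Gaussian jitter (radians).
    learning_rate
        Fractional shrink of the noise per repeated attempt at the same pose:
        the s.d. on attempt k is ``noise_scale * (1 - learning_rate)**(k-1)``.
    distraction_probability
        Probability that an attempt is non-compliant (the patient wanders to
        a far posture instead of the target).
    reaction_ticks
        Latency (ticks) spent at the rest pose before approaching the target.
    """

    patient_id: str
    rom: RomMap
    noise_scale: dict[str, float] = field(default_factory=lambda: {"left": 0.0, "right": 0.0})
    learning_rate: float = 0.0
    distraction_probability: float = 0.0
    reaction_ticks: int = 3
    ramp_ticks: int = 6

    def __post_init__(self) -> None:
        for side in _SIDES:
            if side not in self.rom:
                raise ValueError(f"rom missing side {side!r}")
            for joint in ANGLE_NAMES:
                lo, hi = self.rom[side][joint]
                if not lo < hi:
                    raise ValueError(f"ROM min must be < max for {side}/{joint}, got ({lo}, {hi})")
            if self.noise_scale[side] < 0:
                raise ValueError("noise scale must be >= 0")
        if not 0 <= self.learning_rate < 1:
            raise ValueError("learning_rate must lie in [0, 1)")
        if not 0 <= self.distraction_probability <= 1:
            raise ValueError("distraction_probability must lie in [0, 1]")
        if self.reaction_ticks < 0 or self.ramp_ticks < 1:
            raise ValueError("reaction_ticks must be >= 0 and ramp_ticks >= 1")

    def clamp(self, side: str, angles: JointAngles) -> JointAngles:
        """Clamp a target into this limb's ROM (and the anatomical envelope)."""
        vals = []
        for joint in ANGLE_NAMES:
            lo, hi = self.rom[side][joint]
            elo, ehi = JOINT_ENVELOPES[joint]
            vals.append(float(np.clip(getattr(angles, joint), max(lo, elo), min(hi, ehi))))
        return JointAngles.from_array(vals)


def _full_rom() -> RomMap:
    return {side: {j: JOINT_ENVELOPES[j] for j in ANGLE_NAMES} for side in _SIDES}


PRESET_KINDS = ("unimpaired", "right_arm_deficit", "dystonia_like", "global_impairment")


def make_preset_profile(kind: str) -> PatientProfile:
    """Return a documented preset profile.

    * ``unimpaired`` — full ROM, zero noise: a perfect imitator.
    * ``right_arm_deficit`` — right shoulder elevation capped at 0.9 rad
      (the left limb is unrestricted), mild noise.
    * ``dystonia_like`` — full ROM but strong jitter that barely shrinks
      with repetition.
    * ``global_impairment`` — both limbs' shoulder and elbow ranges reduced,
      moderate noise.
    """
    if kind == "unimpaired":
        return PatientProfile(patient_id="unimpaired", rom=_full_rom())
    if kind == "right_arm_deficit":
        rom = _full_rom()
        rom["right"] = dict(rom["right"])
        rom["right"]["shoulder_opening"] = (0.0, 0.9)
        rom["right"]["shoulder_rotation"] = (-0.9, 0.9)
        return PatientProfile(
            patient_id="right_arm_deficit",
            rom=rom,
            noise_scale={"left": 0.03, "right": 0.06},
            learning_rate=0.15,
            distraction_probability=0.05,
        )
    if kind == "dystonia_like":
        return PatientProfile(
            patient_id="dystonia_like",
            rom=_full_rom(),
            noise_scale={"left": 0.25, "right": 0.25},
            learning_rate=0.05,
            distraction_probability=0.1,
        )
    if kind == "global_impairment":
        rom = _full_rom()
        for side in _SIDES:
            rom[side] = dict(rom[side])
            rom[side]["shoulder_opening"] = (0.0, 1.6)
            rom[side]["elbow_opening"] = (0.7, math.pi)
        return PatientProfile(
            patient_id="global_impairment",
            rom=rom,
            noise_scale={"left": 0.12, "right": 0.12},
            learning_rate=0.1,
            distraction_probability=0.1,
        )
    raise ValueError(f"unknown preset kind {kind!r}; expected one of {PRESET_KINDS}")


def _far_target(target: JointAngles, rng: np.random.Generator) -> JointAngles:
    """A posture guaranteed far from the target: shift every joint by 1 rad
    toward whichever envelope side has room."""
    vals = []
    for joint in ANGLE_NAMES:
        v = getattr(target, joint)
        lo, hi = JOINT_ENVELOPES[joint]
        step = 1.0 if hi - v >= v - lo else -1.0
        vals.append(float(np.clip(v + step, lo, hi)))
    return JointAngles.from_array(vals)


def simulate_response(
    profile: PatientProfile,
    target: TargetPose,
    attempt_index: int,
    theta_context: float,
    rng: np.random.Generator,
    n_ticks: int = 40,
) -> AttemptTrajectory:
    """Produce one imitation attempt as a per-tick two-limb trajectory.

    Trajectory shape: ``reaction_ticks`` at rest, a linear ramp of
    ``ramp_ticks`` toward the ROM-clamped target, then holding with
    zero-mean Gaussian jitter of s.d.
    ``noise_scale * (1 - learning_rate)**(attempt_index - 1)``, clamped back
    into the ROM.  With probability ``distraction_probability`` the attempt
    is non-compliant: the patient ramps to a far posture instead.
    """
    if attempt_index < 1:
        raise ValueError("attempt_index is 1-based and must be >= 1")
    events: list[str] = []
    distracted = rng.random() < profile.distraction_probability
    if distracted:
        events.append("distraction")

    goals: dict[str, np.ndarray] = {}
    sds: dict[str, float] = {}
    for side in _SIDES:
        tgt = getattr(target, side)
        goal = _far_target(tgt, rng) if distracted else profile.clamp(side, tgt)
        goals[side] = goal.as_array()
        sds[side] = profile.noise_scale[side] * (1.0 - profile.learning_rate) ** (attempt_index - 1)

    rest = {side: REST_POSE[side].as_array() for side in _SIDES}
    ticks: list[tuple[JointAngles, JointAngles]] = []
    for t in range(n_ticks):
        pair = {}
        for side in _SIDES:
            if t < profile.reaction_ticks:
                pos = rest[side]
            elif t < profile.reaction_ticks + profile.ramp_ticks:
                frac = (t - profile.reaction_ticks + 1) / profile.ramp_ticks
                pos = rest[side] + frac * (goals[side] - rest[side])
            else:
                pos = goals[side]
                if sds[side] > 0:
                    pos = pos + rng.normal(0.0, sds[side], size=4)
            pair[side] = profile.clamp(side, JointAngles.from_array(np.clip(pos, -_PI, _PI)))
        ticks.append((pair["left"], pair["right"]))
    return AttemptTrajectory(ticks=tuple(ticks), events=tuple(events))


def responder_from_profile(profile: PatientProfile, cfg: SessionConfig | None = None) -> Responder:
    """Adapt a profile to the session engine's responder callback."""
    cfg = cfg or SessionConfig()

    def respond(target: TargetPose, attempt_index: int, theta: float, rng: np.random.Generator) -> AttemptTrajectory:
        return simulate_response(profile, target, attempt_index, theta, rng, n_ticks=cfg.window_ticks)

    return respond


def make_session_plan(
    n_poses: int,
    stage_mix: tuple[float, float, float] = (0.25, 0.5, 0.25),
    difficulty: int = 1,
    rng_seed: int = 0,
    hold_required: float = 2.0,
) -> list[Exercise]:
    """Draw a session plan from the pose library.

    The plan is split into warm-up / middle / relax exercises according to
    ``stage_mix``; poses are sampled with replacement, deterministically by
    seed.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    if len(stage_mix) != 3 or any(w < 0 for w in stage_mix) or sum(stage_mix) <= 0:
        raise ValueError("stage_mix must be three non-negative weights")
    rng = np.random.default_rng(rng_seed)
    names = sorted(POSE_LIBRARY)
    counts = [int(round(n_poses * w / sum(stage_mix))) for w in stage_mix]
    counts[1] = n_poses - counts[0] - counts[2]
    if counts[1] < 0:
        counts = [n_poses, 0, 0]

    exercises = []
    pose_counter = 0
    for stage, count in zip(STAGES, counts):
        if count <= 0:
            continue
        poses = []
        for _ in range(count):
            name = names[int(rng.integers(len(names)))]
            left, right = POSE_LIBRARY[name]
            poses.append(
                TargetPose(pose_id=f"pose-{pose_counter:03d}-{name}", left=left, right=right, hold_required=hold_required)
            )
            pose_counter += 1
        exercises.append(
            Exercise(
                exercise_id=f"ex-{stage}",
                stage=stage,
                intensity=difficulty,
                difficulty=difficulty,
                poses=tuple(poses),
            )
        )
    return exercises


# ---------------------------------------------------------------------------
# Profile files


def dump_profile(profile: PatientProfile, path) -> None:
    doc = {
        "patient_id": profile.patient_id,
        "rom": {s: {j: list(profile.rom[s][j]) for j in ANGLE_NAMES} for s in _SIDES},
        "noise_scale": dict(profile.noise_scale),
        "learning_rate": profile.learning_rate,
        "distraction_probability": profile.distraction_probability,
        "reaction_ticks": profile.reaction_ticks,
        "ramp_ticks": profile.ramp_ticks,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_profile(path) -> PatientProfile:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    rom = {s: {j: tuple(map(float, doc["rom"][s][j])) for j in ANGLE_NAMES} for s in _SIDES}
    return PatientProfile(
        patient_id=str(doc["patient_id"]),
        rom=rom,
        noise_scale={s: float(v) for s, v in doc["noise_scale"].items()},
        learning_rate=float(doc.get("learning_rate", 0.0)),
        distraction_probability=float(doc.get("distraction_probability", 0.0)),
        reaction_ticks=int(doc.get("reaction_ticks", 3)),
        ramp_ticks=int(doc.get("ramp_ticks", 6)),
    )
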