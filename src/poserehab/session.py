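"""Adaptive pose-imitation session engine.

A session presents a sequence of target postures.  The patient gets up to
``max_attempts`` attempts per posture; an attempt succeeds when both limbs
stay within the tolerance ``theta`` continuously for the required hold time
inside the attempt window.  After each posture the shared tolerance adapts:

* success on the first attempt  -> theta decreases by ``update_rate`` (2%),
* skip after all attempts fail  -> theta increases by ``update_rate``,
* success on a later attempt    -> theta unchanged,

always clamped to ``[theta_min, theta_max]`` (default [0.28, 0.4], starting
at the strict end 0.28).  Time is simulated in discrete ticks (default
10 Hz) so runs are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .kinematics import ANGLE_NAMES, FormulaFlag, JointAngles, TargetPose, evaluate_pose, pose_distance

__all__ = [
    "SessionConfig",
    "Exercise",
    "PoseRecord",
    "AngleRow",
    "SessionLog",
    "AttemptTrajectory",
    "update_threshold",
    "run_session",
    "summarize_session",
    "write_log_jsonl",
    "read_log_jsonl",
    "write_angles_csv",
    "read_angles_csv",
    "load_plan",
    "dump_plan",
]

STAGES = ("warm_up", "middle", "relax")
OUTCOMES = ("first_attempt_success", "later_success", "skipped")


@dataclass(frozen=True)
class SessionConfig:
    """Tunable session parameters; defaults are the deployed clinical values."""

    theta_init: float = 0.28
    theta_min: float = 0.28
    theta_max: float = 0.4
    update_rate: float = 0.02
    max_attempts: int = 3
    hold_seconds: float = 2.0
    attempt_timeout_seconds: float = 4.0
    tick_hz: int = 10
    formula: FormulaFlag = "as_printed"
    update_mode: str = "multiplicative"  # or "additive"

    def __post_init__(self) -> None:
        if not (0 < self.theta_min <= self.theta_init <= self.theta_max < 1):
            raise ValueError("require 0 < theta_min <= theta_init <= theta_max < 1")
        if not 0 < self.update_rate < 1:
            raise ValueError("update_rate must lie in (0, 1)")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if not self.hold_seconds > 0:
            raise ValueError("hold_seconds must be > 0")
        if self.attempt_timeout_seconds < self.hold_seconds:
            raise ValueError("attempt_timeout_seconds must be >= hold_seconds")
        if self.tick_hz < 1:
            raise ValueError("tick_hz must be >= 1")
        if self.update_mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")

    @property
    def hold_ticks(self) -> int:
        return int(round(self.hold_seconds * self.tick_hz))

    @property
    def window_ticks(self) -> int:
        return int(round(self.attempt_timeout_seconds * self.tick_hz))


@dataclass(frozen=True)
class Exercise:
    """A block of target poses with a stage and intensity/difficulty labels."""

    exercise_id: str
    stage: str
    intensity: int
    difficulty: int
    poses: tuple[TargetPose, ...]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if not self.poses:
            raise ValueError("an exercise needs at least one pose")
        object.__setattr__(self, "poses", tuple(self.poses))


@dataclass(frozen=True)
class AttemptTrajectory:
    """Per-tick (left, right) joint angles produced by a patient for one attempt."""

    ticks: tuple[tuple[JointAngles, JointAngles], ...]
    events: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ticks", tuple(tuple(t) for t in self.ticks))
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class PoseRecord:
    """Outcome of one target pose within a session."""

    pose_id: str
    attempts_used: int
    outcome: str  # "accepted" | "skipped"
    attempt_distances: tuple[tuple[float | None, float | None], ...]
    theta_before: float
    theta_after: float
    accepted_on_first_attempt: bool


@dataclass(frozen=True)
class AngleRow:
    """One raw angle sample: a tick of one limb during one attempt."""

    pose_id: str
    attempt: int
    tick: int
    side: str
    shoulder_rotation: float
    shoulder_opening: float
    elbow_rotation: float
    elbow_opening: float
    in_tolerance: bool
    held: bool


@dataclass
class SessionLog:
    """Full record of a session: per-pose outcomes, raw angles and events."""

    session_id: str
    patient_id: str
    config: SessionConfig
    records: list[PoseRecord] = field(default_factory=list)
    angle_rows: list[AngleRow] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    complete: bool = True

    def angles_frame(self) -> pd.DataFrame:
        cols = ["pose_id", "attempt", "tick", "side", *ANGLE_NAMES, "in_tolerance", "held"]
        return pd.DataFrame([dataclasses.asdict(r) for r in self.angle_rows], columns=cols)

    def theta_trajectory(self) -> list[float]:
        return [self.config.theta_init] + [r.theta_after for r in self.records]


def update_threshold(theta: float, outcome: str, cfg: SessionConfig) -> float:
    """Apply one per-pose threshold update and clamp to the configured band."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if not (cfg.theta_min - 1e-12 <= theta <= cfg.theta_max + 1e-12):
        raise ValueError(f"theta={theta} outside [{cfg.theta_min}, {cfg.theta_max}]")
    if outcome == "later_success":
        return theta
    if cfg.update_mode == "multiplicative":
        factor = 1.0 + cfg.update_rate if outcome == "skipped" else 1.0 - cfg.update_rate
        new = theta * factor
    else:
        step = cfg.update_rate
        new = theta + step if outcome == "skipped" else theta - step
    return min(cfg.theta_max, max(cfg.theta_min, new))


# Responder: (target, attempt_index (1-based), theta, rng) -> AttemptTrajectory
Responder = Callable[[TargetPose, int, float, np.random.Generator], AttemptTrajectory]


def _hold_accepted(flags: Sequence[bool], hold_ticks: int) -> tuple[bool, list[bool]]:
    """Return (accepted, per-tick held mask) for a sequence of in-tolerance flags.

    A tick is *held* when it belongs to a run of >= hold_ticks consecutive
    in-tolerance ticks; the attempt is accepted when any such run exists.
    """
    held = [False] * len(flags)
    run_start = None
    accepted = False
    for i, ok in enumerate(list(flags) + [False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if i - run_start >= hold_ticks:
                accepted = True
                for j in range(run_start, i):
                    held[j] = True
            run_start = None
    return accepted, held


def run_session(
    plan: Sequence[Exercise],
    responder: Responder,
    cfg: SessionConfig | None = None,
    seed: int = 0,
    session_id: str = "session-0",
    patient_id: str = "patient-0",
) -> SessionLog:
    """Run an adaptive session over a plan, driven by a patient responder.

    The responder is called once per attempt and returns a timed trajectory;
    every tick is evaluated against the current tolerance on both limbs
    simultaneously (an in-tolerance tick needs *both* limb distances <= theta).
    Determinism: with identical seed, plan, config and responder, the log is
    identical.
    """
    cfg = cfg or SessionConfig()
    if not plan:
        raise ValueError("plan must contain at least one exercise")
    rng = np.random.default_rng(seed)
    log = SessionLog(session_id=session_id, patient_id=patient_id, config=cfg)
    theta = cfg.theta_init

    for exercise in plan:
        for target in exercise.poses:
            theta_before = theta
            attempts: list[tuple[float | None, float | None]] = []
            accepted_attempt = 0
            for attempt in range(1, cfg.max_attempts + 1):
                try:
                    traj = responder(target, attempt, theta, rng)
                except Exception as exc:  # responder failure aborts with partial log
                    log.complete = False
                    log.events.append(
                        {"type": "responder_failure", "pose_id": target.pose_id, "attempt": attempt, "detail": str(exc)}
                    )
                    return log
                for ev in traj.events:
                    log.events.append({"type": ev, "pose_id": target.pose_id, "attempt": attempt})

                ticks = traj.ticks[: cfg.window_ticks]
                side_flags: dict[str, list[bool]] = {"left": [], "right": []}
                best: tuple[float, float] | None = None
                for left, right in ticks:
                    dl = pose_distance(left, target.left, cfg.formula)
                    dr = pose_distance(right, target.right, cfg.formula)
                    side_flags["left"].append(evaluate_pose(dl, theta) == "correct")
                    side_flags["right"].append(evaluate_pose(dr, theta) == "correct")
                    if best is None or max(dl, dr) < max(best[0], best[1]):
                        best = (dl, dr)
                # attempt acceptance needs BOTH limbs within theta for the hold;
                # the held mask is per limb (limbs are assessed individually)
                both = [l and r for l, r in zip(side_flags["left"], side_flags["right"])]
                accepted, _ = _hold_accepted(both, cfg.hold_ticks)
                held = {side: _hold_accepted(side_flags[side], cfg.hold_ticks)[1] for side in ("left", "right")}
                attempts.append(best if best is not None else (None, None))
                for i, (left, right) in enumerate(ticks):
                    for side, ang in (("left", left), ("right", right)):
                        log.angle_rows.append(
                            AngleRow(
                                target.pose_id, attempt, i, side, *ang.as_array().tolist(),
                                side_flags[side][i], held[side][i],
                            )
                        )
                if accepted:
                    accepted_attempt = attempt
                    break

            if accepted_attempt:
                outcome = "first_attempt_success" if accepted_attempt == 1 else "later_success"
                record_outcome = "accepted"
                attempts_used = accepted_attempt
            else:
                outcome = "skipped"
                record_outcome = "skipped"
                attempts_used = cfg.max_attempts
            theta = update_threshold(theta, outcome, cfg)
            log.records.append(
                PoseRecord(
                    pose_id=target.pose_id,
                    attempts_used=attempts_used,
                    outcome=record_outcome,
                    attempt_distances=tuple(attempts),
                    theta_before=theta_before,
                    theta_after=theta,
                    accepted_on_first_attempt=accepted_attempt == 1,
                )
            )
    return log


def summarize_session(log: SessionLog) -> pd.DataFrame:
    """Aligned per-pose series behind the two-panel monitoring plot.

    Columns: pose_index, pose_id, theta_after, attempts_used, outcome; one
    row per pose record (empty log -> empty frame).
    """
    rows = [
        {
            "pose_index": i,
            "pose_id": r.pose_id,
            "theta_after": r.theta_after,
            "attempts_used": r.attempts_used,
            "outcome": r.outcome,
        }
        for i, r in enumerate(log.records)
    ]
    return pd.DataFrame(rows, columns=["pose_index", "pose_id", "theta_after", "attempts_used", "outcome"])


# ---------------------------------------------------------------------------
# Serialization


def _config_to_dict(cfg: SessionConfig) -> dict:
    return dataclasses.asdict(cfg)


def write_log_jsonl(log: SessionLog, path) -> None:
    """Write a session log as JSON-lines: a header, one line per pose, events."""
    with open(path, "w", encoding="utf-8") as fh:
        header = {
            "type": "header",
            "session_id": log.session_id,
            "patient_id": log.patient_id,
            "config": _config_to_dict(log.config),
            "complete": log.complete,
        }
        fh.write(json.dumps(header) + "\n")
        for r in log.records:
            rec = dataclasses.asdict(r)
            rec["type"] = "pose"
            fh.write(json.dumps(rec) + "\n")
        for ev in log.events:
            fh.write(json.dumps({"type": "event", "event": ev}) + "\n")


def read_log_jsonl(path, angles_csv=None) -> SessionLog:
    """Read a JSON-lines session log; optionally attach the companion angle CSV."""
    records: list[PoseRecord] = []
    events: list[dict] = []
    header = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            obj = json.loads(line)
            kind = obj.pop("type")
            if kind == "header":
                header = obj
            elif kind == "pose":
                obj["attempt_distances"] = tuple(tuple(a) for a in obj["attempt_distances"])
                records.append(PoseRecord(**obj))
            elif kind == "event":
                events.append(obj["event"])
            else:
                raise ValueError(f"unknown log line type {kind!r}")
    if header is None:
        raise ValueError("log file has no header line")
    log = SessionLog(
        session_id=header["session_id"],
        patient_id=header["patient_id"],
        config=SessionConfig(**header["config"]),
        records=records,
        events=events,
        complete=header["complete"],
    )
    if angles_csv is not None:
        log.angle_rows = read_angles_csv(angles_csv)
    return log


def write_angles_csv(log: SessionLog, path) -> None:
    """Write the per-attempt raw angle samples as a companion CSV."""
    # 17 significant digits so float64 angles round-trip exactly
    log.angles_frame().to_csv(path, index=False, float_format="%.17g")


def read_angles_csv(path) -> list[AngleRow]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        AngleRow(
            str(row.pose_id),
            int(row.attempt),
            int(row.tick),
            str(row.side),
            float(row.shoulder_rotation),
            float(row.shoulder_opening),
            float(row.elbow_rotation),
            float(row.elbow_opening),
            bool(row.in_tolerance),
            bool(row.held),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Plan files (YAML/JSON)


def dump_plan(plan: Iterable[Exercise], path) -> None:
    """Write a session plan as YAML (poses as 8 named angles per pose)."""
    doc = {
        "exercises": [
            {
                "exercise_id": ex.exercise_id,
                "stage": ex.stage,
                "intensity": ex.intensity,
                "difficulty": ex.difficulty,
                "poses": [
                    {
                        "pose_id": p.pose_id,
                        "hold_required": p.hold_required,
                        "left": p.left.as_dict(),
                        "right": p.right.as_dict(),
                    }
                    for p in ex.poses
                ],
            }
            for ex in plan
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_plan(path) -> list[Exercise]:
    """Load a session plan from a YAML (or JSON) document."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    exercises = []
    for ex in doc["exercises"]:
        poses = tuple(
            TargetPose(
                pose_id=p["pose_id"],
                left=JointAngles(**{k: float(v) for k, v in p["left"].items()}),
                right=JointAngles(**{k: float(v) for k, v in p["right"].items()}),
                hold_required=float(p.get("hold_required", 2.0)),
            )
            for p in ex["poses"]
        )
        exercises.append(
            Exercise(
                exercise_id=str(ex["exercise_id"]),
                stage=ex["stage"],
                intensity=int(ex.get("intensity", 1)),
                difficulty=int(ex.get("difficulty", 1)),
                poses=poses,
            )
        )
    return exercises
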