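"""Shared fixtures: reference responders and small session plans.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from poserehab.kinematics import JointAngles, TargetPose
from poserehab.session import AttemptTrajectory, SessionConfig
from poserehab.simulate import POSE_LIBRARY, _far_target, make_session_plan


@pytest.fixture
def cfg() -> SessionConfig:
    return SessionConfig()


@pytest.fixture
def small_plan():
    return make_session_plan(10, rng_seed=7)


def perfect_responder(target: TargetPose, attempt_index: int, theta: float, rng: np.random.Generator) -> AttemptTrajectory:
    """Imitates the target exactly at every tick of the attempt window."""
    return AttemptTrajectory(ticks=tuple((target.left, target.right) for _ in range(40)))


def hopeless_responder(target: TargetPose, attempt_index: int, theta: float, rng: np.random.Generator) -> AttemptTrajectory:
    """Always holds a posture far from the target (distance ~0.8 per limb)."""
    left = _far_target(target.left, rng)
    right = _far_target(target.right, rng)
    return AttemptTrajectory(ticks=tuple((left, right) for _ in range(40)))


@pytest.fixture
def target_pose() -> TargetPose:
    left, right = POSE_LIBRARY["both_forward"]
    return TargetPose(pose_id="fixture-both_forward", left=left, right=right)


def ja(sr=0.0, so=0.0, er=0.0, eo=0.0) -> JointAngles:
    return JointAngles(sr, so, er, eo)
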