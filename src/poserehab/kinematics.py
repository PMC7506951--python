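"""Upper-limb pose representation and the normalized pose distance.

A limb pose is described by four joint angles (radians): shoulder rotation,
shoulder opening, elbow rotation and elbow opening.  The distance between a
requested pose and an imitated pose aggregates the squared per-angle
differences and maps them into the unit interval,

    d(a_human, a_robot) = 1 - 1 / (1 + D),

where D is the sum of squared angle differences (``formula="as_printed"``,
the default) or its square root (``formula="euclidean"``).  Both variants are
identical at D = 1 and share the fixed point d = 0 at identity.

Skeleton-to-angle conversion uses a torso-centred convention, documented on
:func:`angles_from_skeleton`, that is invariant under global translation and
uniform scaling of the skeleton.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "ANGLE_NAMES",
    "JointAngles",
    "LimbPose",
    "TargetPose",
    "Skeleton",
    "DegenerateSkeletonError",
    "pose_distance",
    "evaluate_pose",
    "angles_from_skeleton",
    "skeleton_from_angles",
    "read_angle_csv",
    "write_angle_csv",
    "read_skeleton_csv",
]

#: Canonical order of the four joint angles of one limb.
ANGLE_NAMES = ("shoulder_rotation", "shoulder_opening", "elbow_rotation", "elbow_opening")

#: Default anatomical envelope (radians) applied to every joint angle.
DEFAULT_ENVELOPE = (-math.pi, math.pi)

FormulaFlag = Literal["as_printed", "euclidean"]

_SIDES = ("left", "right")


class DegenerateSkeletonError(ValueError):
    """Raised when a skeleton has a zero-length limb segment."""


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class JointAngles:
    """The four joint angles of one upper limb, in radians.

    Angles must be finite and lie within the anatomical envelope
    (default ``[-pi, pi]``, overridable via ``envelope``).
    """

    shoulder_rotation: float
    shoulder_opening: float
    elbow_rotation: float
    elbow_opening: float
    envelope: tuple[float, float] = field(default=DEFAULT_ENVELOPE, compare=False, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.envelope
        for name in ANGLE_NAMES:
            v = _check_finite(name, getattr(self, name))
            object.__setattr__(self, name, v)
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValueError(f"{name}={v:.6g} outside anatomical envelope [{lo:.6g}, {hi:.6g}]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in ANGLE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float], envelope: tuple[float, float] = DEFAULT_ENVELOPE) -> "JointAngles":
        vals = list(values)
        if len(vals) != 4:
            raise ValueError(f"expected 4 angles, got {len(vals)}")
        return cls(*vals, envelope=envelope)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in ANGLE_NAMES}


@dataclass(frozen=True)
class LimbPose:
    """One limb's pose: which side it is and its joint angles."""

    side: str
    angles: JointAngles

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")


@dataclass(frozen=True)
class TargetPose:
    """A requested posture: both limbs' target angles plus the hold requirement."""

    pose_id: str
    left: JointAngles
    right: JointAngles
    hold_required: float = 2.0

    def __post_init__(self) -> None:
        if not self.hold_required > 0:
            raise ValueError(f"hold_required must be > 0, got {self.hold_required}")


_SKELETON_JOINTS = (
    "spine",
    "shoulder_center",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
)


@dataclass(frozen=True)
class Skeleton:
    """3-D joint positions (metres) for both upper limbs plus torso references.

    The torso frame is derived from the two reference points: the downward
    axis points from the shoulder centre toward the spine point; the frontal
    (anterior) direction is the global +y axis orthogonalized against the
    downward axis.  Both derivations are invariant under global translation
    and uniform scaling.
    """

    spine: np.ndarray
    shoulder_center: np.ndarray
    left_shoulder: np.ndarray
    left_elbow: np.ndarray
    left_wrist: np.ndarray
    right_shoulder: np.ndarray
    right_elbow: np.ndarray
    right_wrist: np.ndarray

    def __post_init__(self) -> None:
        for name in _SKELETON_JOINTS:
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"skeleton joint {name} has non-finite coordinates: {p}")
            object.__setattr__(self, name, p)

    def torso_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (down, front, lateral) unit axes of the torso frame."""
        down = self.spine - self.shoulder_center
        n = np.linalg.norm(down)
        if n <= 1e-12:
            raise DegenerateSkeletonError("spine and shoulder_center coincide")
        down = down / n
        front = np.array([0.0, 1.0, 0.0]) - np.dot(np.array([0.0, 1.0, 0.0]), down) * down
        fn = np.linalg.norm(front)
        if fn <= 1e-12:
            raise DegenerateSkeletonError("torso axis parallel to the frontal reference axis")
        front = front / fn
        lateral = np.cross(down, front)
        return down, front, lateral


def pose_distance(
    human: JointAngles,
    robot: JointAngles,
    formula: FormulaFlag = "as_printed",
) -> float:
    """Normalized pose distance between two limb poses, in ``[0, 1)``.

    Parameters
    ----------
    human, robot
        The imitated and the requested joint angles.
    formula
        ``"as_printed"`` uses the raw sum of squared differences;
        ``"euclidean"`` takes its square root before normalizing.

    Returns
    -------
    float
        ``1 - 1/(1 + D)``; zero iff all four angles coincide.
    """
    if formula not in ("as_printed", "euclidean"):
        raise ValueError(f"unknown formula flag {formula!r}")
    diff = human.as_array() - robot.as_array()
    d_sq = float(np.dot(diff, diff))
    agg = math.sqrt(d_sq) if formula == "euclidean" else d_sq
    return 1.0 - 1.0 / (1.0 + agg)


def evaluate_pose(d: float, theta: float) -> str:
    """Classify a pose distance against the tolerance: ``d <= theta`` is correct.

    The boundary is inclusive: a distance exactly at the threshold counts as
    a correct imitation.
    """
    d = _check_finite("distance", d)
    theta = _check_finite("theta", theta)
    if not 0.0 <= d < 1.0:
        raise ValueError(f"distance must lie in [0, 1), got {d}")
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    return "correct" if d <= theta else "incorrect"


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n <= 1e-12:
        raise DegenerateSkeletonError(f"zero-length segment: {what}")
    return v / n


def angles_from_skeleton(skeleton: Skeleton, side: str) -> JointAngles:
    """Convert one limb of a skeleton to the four joint angles.

    Convention (torso frame: down / front / lateral, see
    :meth:`Skeleton.torso_axes`):

    * ``shoulder_opening`` — angle between the shoulder-to-elbow vector and the
      torso's downward axis (0 = arm hanging down, pi/2 = horizontal).
    * ``shoulder_rotation`` — azimuth of that vector about the downward axis,
      measured from the frontal plane (0 = straight forward, +pi/2 = lateral);
      defined as 0 when the arm is colinear with the torso axis.
    * ``elbow_opening`` — interior angle of the shoulder–elbow–wrist triangle
      (pi = straight arm).
    * ``elbow_rotation`` — rotation of the forearm about the upper-arm axis,
      measured from the projection of the torso's downward axis; 0 when the
      arm is straight.
    """
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}, got {side!r}")
    down, front, lateral = skeleton.torso_axes()
    shoulder = getattr(skeleton, f"{side}_shoulder")
    elbow = getattr(skeleton, f"{side}_elbow")
    wrist = getattr(skeleton, f"{side}_wrist")

    u = _unit(elbow - shoulder, f"{side} shoulder-elbow")
    w = _unit(wrist - elbow, f"{side} elbow-wrist")

    cos_open = float(np.clip(np.dot(u, down), -1.0, 1.0))
    shoulder_opening = math.acos(cos_open)

    # Azimuth in the plane orthogonal to the torso axis.
    proj = u - np.dot(u, down) * down
    if np.linalg.norm(proj) <= 1e-9:
        shoulder_rotation = 0.0
    else:
        shoulder_rotation = math.atan2(float(np.dot(proj, lateral)), float(np.dot(proj, front)))

    cos_elbow = float(np.clip(np.dot(-u, w), -1.0, 1.0))
    elbow_opening = math.acos(cos_elbow)

    # Forearm azimuth about the upper arm, referenced to the torso-down axis.
    ref = down - np.dot(down, u) * u
    if np.linalg.norm(ref) <= 1e-9:
        ref = front - np.dot(front, u) * u
    ref = _unit(ref, "elbow reference axis")
    s_axis = np.cross(u, ref)
    w_perp = w - np.dot(w, u) * u
    if np.linalg.norm(w_perp) <= 1e-9:
        elbow_rotation = 0.0
    else:
        elbow_rotation = math.atan2(float(np.dot(w_perp, s_axis)), float(np.dot(w_perp, ref)))

    return JointAngles(shoulder_rotation, shoulder_opening, elbow_rotation, elbow_opening)


def skeleton_from_angles(
    left: JointAngles,
    right: JointAngles,
    upper_arm: float = 0.26,
    forearm: float = 0.25,
    shoulder_half_width: float = 0.15,
    torso_length: float = 0.45,
) -> Skeleton:
    """Build a synthetic skeleton realizing the given joint angles.

    Inverse of :func:`angles_from_skeleton` under the documented convention;
    the torso frame is the canonical one (down = -z, front = +y, lateral = +x)
    with the shoulder centre at the origin.
    """
    if upper_arm <= 0 or forearm <= 0:
        raise ValueError("segment lengths must be positive")
    down = np.array([0.0, 0.0, -1.0])
    front = np.array([0.0, 1.0, 0.0])
    lateral = np.cross(down, front)

    shoulder_center = np.zeros(3)
    spine = shoulder_center + torso_length * down
    positions: dict[str, np.ndarray] = {"spine": spine, "shoulder_center": shoulder_center}

    for side, angles, sign in (("left", left, +1.0), ("right", right, -1.0)):
        shoulder = shoulder_center + sign * shoulder_half_width * lateral
        so, sr = angles.shoulder_opening, angles.shoulder_rotation
        u = math.cos(so) * down + math.sin(so) * (math.cos(sr) * front + math.sin(sr) * lateral)
        elbow = shoulder + upper_arm * u

        ref = down - np.dot(down, u) * u
        if np.linalg.norm(ref) <= 1e-9:
            ref = front - np.dot(front, u) * u
        ref = ref / np.linalg.norm(ref)
        s_axis = np.cross(u, ref)
        bend = math.pi - angles.elbow_opening
        er = angles.elbow_rotation
        w = math.cos(bend) * u + math.sin(bend) * (math.cos(er) * ref + math.sin(er) * s_axis)
        wrist = elbow + forearm * w

        positions[f"{side}_shoulder"] = shoulder
        positions[f"{side}_elbow"] = elbow
        positions[f"{side}_wrist"] = wrist

    return Skeleton(**positions)


# ---------------------------------------------------------------------------
# CSV interfaces


def write_angle_csv(rows: pd.DataFrame, path) -> None:
    """Write a joint-angle time series (timestamp_s, side, 4 angle columns)."""
    required = ["timestamp_s", "side", *ANGLE_NAMES]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise ValueError(f"angle table missing columns: {missing}")
    rows.loc[:, required].to_csv(path, index=False)


def read_angle_csv(path) -> pd.DataFrame:
    """Read a joint-angle time series CSV written by :func:`write_angle_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["timestamp_s", "side", *ANGLE_NAMES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"angle CSV missing columns: {missing}")
    return df


def read_skeleton_csv(path) -> list[Skeleton]:
    """Read skeleton frames from a CSV with ``<joint>_{x,y,z}`` columns."""
    df = pd.read_csv(path)
    frames = []
    for _, row in df.iterrows():
        kwargs = {}
        for joint in _SKELETON_JOINTS:
            kwargs[joint] = np.array([row[f"{joint}_x"], row[f"{joint}_y"], row[f"{joint}_z"]])
        frames.append(Skeleton(**kwargs))
    return frames
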