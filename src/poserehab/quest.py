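"""Automatic QUEST dissociated-movement scoring from session logs.

The Quality of Upper Extremity Skills Test (QUEST) scores upper-limb
movement quality in children.  This module scores the four
dissociated-movement items this system can observe per limb — shoulder
flexion, shoulder abduction, elbow flexion and elbow extension — from the
raw joint-angle record of a session.  An item earns 2 points when the
defining angle reached the criterion during a posture held for the required
time, and 1 point when the movement could not be completed or was not
tested.  Raw points over the 8 items therefore span [8, 16]; the normalized
score maps that range affinely onto [0, 100].

The per-item criterion angles are configurable; defaults follow the
full-range reading of the QUEST manual and are documented on
``DEFAULT_CRITERIA``.  A therapist can override any item score; overrides
are recorded and totals recomputed.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
from dataclasses import dataclass, field

from .session import AngleRow, SessionLog

__all__ = [
    "ITEM_IDS",
    "DEFAULT_CRITERIA",
    "MissingAngleDataError",
    "QuestItem",
    "QuestReport",
    "extract_range_of_motion",
    "score_item",
    "build_report",
    "apply_override",
    "render_report",
    "parse_report_json",
]

#: The four dissociated-movement items scored per limb.
ITEM_IDS = ("shoulder_flexion", "shoulder_abduction", "elbow_flexion", "elbow_extension")

_SIDES = ("left", "right")

#: Default per-item criterion angles (radians): the achieved angle must reach
#: the criterion during a held posture to score 2.  Shoulder items require a
#: horizontal raise (pi/2); elbow flexion requires 3pi/4 of flexion (opening
#: closed to pi/4); elbow extension requires near-full opening (17pi/18).
DEFAULT_CRITERIA: dict[str, float] = {
    "shoulder_flexion": math.pi / 2,
    "shoulder_abduction": math.pi / 2,
    "elbow_flexion": 3 * math.pi / 4,
    "elbow_extension": 17 * math.pi / 18,
}


class MissingAngleDataError(ValueError):
    """Raised when a log has no raw angle records to score items from."""

    def __init__(self, items: tuple[str, ...]):
        self.items = items
        super().__init__(f"log has no angle records; items not testable: {', '.join(items)}")


@dataclass(frozen=True)
class QuestItem:
    """One scored item: 2 = achieved, 1 = could not be completed or not tested."""

    item_id: str
    side: str
    score: int
    tested: bool
    achieved_angle: float | None = None

    def __post_init__(self) -> None:
        if self.item_id not in ITEM_IDS:
            raise ValueError(f"unknown item {self.item_id!r}")
        if self.side not in _SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.score not in (1, 2):
            raise ValueError("score must be 1 or 2")
        if self.score == 2 and not self.tested:
            raise ValueError("score 2 requires the item to have been tested")


@dataclass(frozen=True)
class QuestReport:
    """The 8 dissociated-movement items plus totals and therapist overrides."""

    patient_id: str
    session_id: str
    items: tuple[QuestItem, ...]
    overrides: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        keys = {(i.item_id, i.side) for i in self.items}
        expected = {(iid, s) for iid in ITEM_IDS for s in _SIDES}
        if keys != expected:
            raise ValueError("report must contain exactly the 8 item/side combinations")

    @property
    def raw_points(self) -> int:
        return sum(i.score for i in self.items)

    @property
    def normalized_score(self) -> float:
        return 100.0 * (self.raw_points - 8) / (16 - 8)

    def item(self, item_id: str, side: str) -> QuestItem:
        for it in self.items:
            if it.item_id == item_id and it.side == side:
                return it
        raise KeyError((item_id, side))


def _item_angle(item_id: str, row: AngleRow) -> float:
    """The defining angle of an item for one raw sample.

    Shoulder elevation is decomposed by azimuth: the forward (flexion)
    component is ``opening * cos(rotation)`` and the lateral (abduction)
    component ``opening * |sin(rotation)|``; elbow flexion is the closing
    angle ``pi - opening`` and elbow extension the opening itself.
    """
    if item_id == "shoulder_flexion":
        return max(0.0, row.shoulder_opening * math.cos(row.shoulder_rotation))
    if item_id == "shoulder_abduction":
        return row.shoulder_opening * abs(math.sin(row.shoulder_rotation))
    if item_id == "elbow_flexion":
        return math.pi - row.elbow_opening
    if item_id == "elbow_extension":
        return row.elbow_opening
    raise ValueError(f"unknown item {item_id!r}")


def extract_range_of_motion(log: SessionLog, side: str) -> dict[str, float | None]:
    """Per-item maximum achieved angle over all *held* samples of one limb.

    Only samples belonging to a continuously-in-tolerance run of at least the
    hold time are considered, so the maxima reflect postures the patient
    actually sustained.  Items with no held sample map to ``None``
    (not tested).  A log without any angle records raises
    :class:`MissingAngleDataError` naming all items.
    """
    if side not in _SIDES:
        raise ValueError(f"unknown side {side!r}")
    if not log.angle_rows:
        raise MissingAngleDataError(ITEM_IDS)
    maxima: dict[str, float | None] = {iid: None for iid in ITEM_IDS}
    for row in log.angle_rows:
        if row.side != side or not row.held:
            continue
        for iid in ITEM_IDS:
            v = _item_angle(iid, row)
            if maxima[iid] is None or v > maxima[iid]:
                maxima[iid] = v
    return maxima


def score_item(achieved: float | None, criterion: float, tested: bool) -> int:
    """2 if tested and the achieved angle reached the criterion (inclusive), else 1."""
    if not criterion > 0:
        raise ValueError("criterion must be > 0")
    if tested and achieved is not None and achieved >= criterion:
        return 2
    return 1


def build_report(
    log: SessionLog,
    criteria: dict[str, float] | None = None,
    patient_id: str | None = None,
) -> QuestReport:
    """Score all 8 items from a session log.

    Missing angle data never aborts: the affected items are marked not
    tested and score 1.
    """
    criteria = {**DEFAULT_CRITERIA, **(criteria or {})}
    items = []
    for side in _SIDES:
        try:
            maxima = extract_range_of_motion(log, side)
        except MissingAngleDataError:
            maxima = {iid: None for iid in ITEM_IDS}
        for iid in ITEM_IDS:
            achieved = maxima[iid]
            tested = achieved is not None
            items.append(
                QuestItem(
                    item_id=iid,
                    side=side,
                    score=score_item(achieved, criteria[iid], tested),
                    tested=tested,
                    achieved_angle=achieved,
                )
            )
    return QuestReport(
        patient_id=patient_id or log.patient_id,
        session_id=log.session_id,
        items=tuple(items),
    )


def apply_override(report: QuestReport, item_id: str, side: str, score: int, note: str = "") -> QuestReport:
    """Return a new report with one item's score replaced by the therapist.

    The override is recorded (item, side, new score, note) and totals are
    recomputed through the ``raw_points``/``normalized_score`` properties.
    """
    if score not in (1, 2):
        raise ValueError("override score must be 1 or 2")
    report.item(item_id, side)  # raises KeyError on unknown item
    new_items = []
    for it in report.items:
        if it.item_id == item_id and it.side == side:
            new_items.append(
                QuestItem(item_id=item_id, side=side, score=score, tested=True if score == 2 else it.tested,
                          achieved_angle=it.achieved_angle)
            )
        else:
            new_items.append(it)
    overrides = report.overrides + ({"item_id": item_id, "side": side, "score": score, "note": note},)
    return QuestReport(
        patient_id=report.patient_id,
        session_id=report.session_id,
        items=tuple(new_items),
        overrides=overrides,
    )


def render_report(report: QuestReport, format: str = "json") -> str:
    """Serialize a report as ``json`` (lossless), ``csv`` or ``markdown``."""
    if format == "json":
        doc = {
            "schema_version": 1,
            "patient_id": report.patient_id,
            "session_id": report.session_id,
            "items": [dataclasses.asdict(i) for i in report.items],
            "overrides": list(report.overrides),
            "raw_points": report.raw_points,
            "normalized_score": report.normalized_score,
        }
        return json.dumps(doc, indent=2)
    if format == "csv":
        buf = io.StringIO()
        buf.write("item_id,side,score,tested,achieved_angle\n")
        for it in report.items:
            ach = "" if it.achieved_angle is None else f"{it.achieved_angle:.6f}"
            buf.write(f"{it.item_id},{it.side},{it.score},{it.tested},{ach}\n")
        buf.write(f"raw_points,,{report.raw_points},,\n")
        buf.write(f"normalized_score,,{report.normalized_score},,\n")
        return buf.getvalue()
    if format == "markdown":
        lines = [
            f"# QUEST dissociated movements — patient {report.patient_id}",
            f"Session: {report.session_id}",
            "",
            "| Item | Side | Score | Tested | Achieved (rad) |",
            "| --- | --- | --- | --- | --- |",
        ]
        for it in report.items:
            ach = "-" if it.achieved_angle is None else f"{it.achieved_angle:.3f}"
            lines.append(f"| {it.item_id} | {it.side} | {it.score} | {'yes' if it.tested else 'no'} | {ach} |")
        lines += [
            "",
            f"Raw points: **{report.raw_points}** (range 8–16)",
            f"Normalized score: **{report.normalized_score:.1f} / 100**",
        ]
        if report.overrides:
            lines.append("")
            lines.append("Therapist overrides:")
            for ov in report.overrides:
                lines.append(f"- {ov['item_id']} ({ov['side']}) -> {ov['score']}: {ov['note']}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")


def parse_report_json(text: str) -> QuestReport:
    """Inverse of ``render_report(..., 'json')``; preserves overrides."""
    doc = json.loads(text)
    items = tuple(QuestItem(**{k: v for k, v in it.items()}) for it in doc["items"])
    return QuestReport(
        patient_id=doc["patient_id"],
        session_id=doc["session_id"],
        items=items,
        overrides=tuple(doc.get("overrides", [])),
    )
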