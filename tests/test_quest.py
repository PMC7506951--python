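"""QUEST dissociated-movement scoring from session logs."""

import math

import numpy as np
import pandas as pd
import pytest

from poserehab.kinematics import TargetPose
from poserehab.quest import (
    DEFAULT_CRITERIA,
    ITEM_IDS,
    MissingAngleDataError,
    QuestItem,
    QuestReport,
    apply_override,
    build_report,
    extract_range_of_motion,
    parse_report_json,
    render_report,
    score_item,
)
from poserehab.session import Exercise, SessionConfig, SessionLog, run_session
from poserehab.simulate import POSE_LIBRARY, make_preset_profile, make_session_plan, responder_from_profile

from conftest import ja, perfect_responder


def full_range_plan():
    """A plan whose poses meet every default criterion on both limbs."""
    poses = [
        TargetPose("p-forward", *POSE_LIBRARY["both_forward"]),
        TargetPose("p-tpose", *POSE_LIBRARY["t_pose"]),
        TargetPose("p-down", *POSE_LIBRARY["arms_down"]),  # near-full elbow extension
        TargetPose("p-curl", ja(0.0, 0.4, 0.0, 0.6), ja(0.0, 0.4, 0.0, 0.6)),  # deep elbow flexion
    ]
    return [Exercise("ex-full", "middle", 1, 1, tuple(poses))]


class TestScoreItem:
    @pytest.mark.parametrize(
        "achieved,tested,expected",
        [
            (math.pi / 2, True, 2),  # boundary inclusive
            (math.pi / 2 - 1e-6, True, 1),
            (None, False, 1),  # not tested
            (math.pi, False, 1),
        ],
    )
    def test_scoring_rule(self, achieved, tested, expected):
        assert score_item(achieved, math.pi / 2, tested) == expected

    def test_criterion_must_be_positive(self):
        with pytest.raises(ValueError):
            score_item(1.0, 0.0, True)


class TestExtraction:
    def test_noiseless_run_recovers_target_component_exactly(self, cfg):
        log = run_session(full_range_plan(), perfect_responder, cfg, seed=0)
        maxima = extract_range_of_motion(log, "left")
        # both_forward: opening pi/2 at rotation 0 -> flexion component = pi/2
        assert maxima["shoulder_flexion"] == pytest.approx(math.pi / 2)
        assert maxima["elbow_extension"] == pytest.approx(math.pi - 0.05)
        assert maxima["elbow_flexion"] == pytest.approx(math.pi - 0.6)

    def test_log_without_angles_raises_naming_items(self, cfg):
        log = SessionLog("s", "p", cfg)
        with pytest.raises(MissingAngleDataError) as exc:
            extract_range_of_motion(log, "left")
        assert set(exc.value.items) == set(ITEM_IDS)

    def test_maxima_match_full_scan_oracle(self, cfg):
        plan = make_session_plan(10, rng_seed=3)
        profile = make_preset_profile("dystonia_like")
        log = run_session(plan, responder_from_profile(profile, cfg), cfg, seed=3)
        df = log.angles_frame()
        held = df[df["held"]]
        for side in ("left", "right"):
            sub = held[held["side"] == side]
            maxima = extract_range_of_motion(log, side)
            if len(sub) == 0:
                assert all(v is None for v in maxima.values())
                continue
            flex = np.maximum(0.0, sub["shoulder_opening"] * np.cos(sub["shoulder_rotation"]))
            abd = sub["shoulder_opening"] * np.abs(np.sin(sub["shoulder_rotation"]))
            assert maxima["shoulder_flexion"] == pytest.approx(float(flex.max()))
            assert maxima["shoulder_abduction"] == pytest.approx(float(abd.max()))
            assert maxima["elbow_flexion"] == pytest.approx(float((math.pi - sub["elbow_opening"]).max()))
            assert maxima["elbow_extension"] == pytest.approx(float(sub["elbow_opening"].max()))


class TestBuildReport:
    def test_full_range_session_scores_maximum(self, cfg):
        log = run_session(full_range_plan(), perfect_responder, cfg, seed=0)
        report = build_report(log)
        assert report.raw_points == 16
        assert report.normalized_score == 100.0

    def test_empty_log_scores_minimum(self, cfg):
        report = build_report(SessionLog("s", "p", cfg))
        assert report.raw_points == 8
        assert report.normalized_score == 0.0
        assert all(not it.tested and it.score == 1 for it in report.items)

    def test_eight_items_two_per_item_type(self, cfg):
        log = run_session(full_range_plan(), perfect_responder, cfg, seed=0)
        report = build_report(log)
        assert len(report.items) == 8
        for iid in ITEM_IDS:
            assert sum(1 for it in report.items if it.item_id == iid) == 2

    def test_right_arm_deficit_fails_right_shoulder_items(self, cfg):
        # right shoulder capped at 0.9 rad < pi/2 criterion; left unrestricted
        profile = make_preset_profile("right_arm_deficit")
        log = run_session(full_range_plan(), responder_from_profile(profile, cfg), cfg, seed=4)
        report = build_report(log)
        for iid in ("shoulder_flexion", "shoulder_abduction"):
            assert report.item(iid, "right").score == 1
            assert report.item(iid, "left").score == 2

    def test_score_bounds_and_normalization_identity_on_random_logs(self, cfg):
        for seed in range(12):
            plan = make_session_plan(6, rng_seed=seed)
            profile = make_preset_profile(["dystonia_like", "global_impairment"][seed % 2])
            log = run_session(plan, responder_from_profile(profile, cfg), cfg, seed=seed)
            report = build_report(log)
            assert 8 <= report.raw_points <= 16
            assert report.normalized_score == pytest.approx(100 * (report.raw_points - 8) / 8)

    def test_enlarging_rom_never_decreases_scores(self, cfg):
        plan = full_range_plan()
        narrow = make_preset_profile("global_impairment")
        wide = make_preset_profile("unimpaired")
        for seed in range(5):
            r_narrow = build_report(run_session(plan, responder_from_profile(narrow, cfg), cfg, seed=seed))
            r_wide = build_report(run_session(plan, responder_from_profile(wide, cfg), cfg, seed=seed))
            for it in r_narrow.items:
                assert r_wide.item(it.item_id, it.side).score >= it.score
            assert r_wide.raw_points >= r_narrow.raw_points


class TestOverrides:
    def make_report(self, cfg):
        log = run_session(full_range_plan(), perfect_responder, cfg, seed=0)
        return build_report(log)

    def test_same_value_override_logged_but_totals_unchanged(self, cfg):
        report = self.make_report(cfg)
        out = apply_override(report, "elbow_flexion", "left", 2, note="confirmed")
        assert out.raw_points == report.raw_points
        assert len(out.overrides) == 1

    def test_upgrade_increases_raw_points_by_one(self, cfg):
        log = run_session(full_range_plan(), responder_from_profile(make_preset_profile("right_arm_deficit"), cfg), cfg, seed=4)
        report = build_report(log)
        assert report.item("shoulder_flexion", "right").score == 1
        out = apply_override(report, "shoulder_flexion", "right", 2, note="therapist saw it")
        assert out.raw_points == report.raw_points + 1

    def test_unknown_item_rejected(self, cfg):
        report = self.make_report(cfg)
        with pytest.raises(KeyError):
            apply_override(report, "wrist_extension", "left", 2)

    def test_round_trip_preserves_overrides(self, cfg):
        report = apply_override(self.make_report(cfg), "elbow_flexion", "left", 1, note="uncertain")
        back = parse_report_json(render_report(report, "json"))
        assert back.overrides == report.overrides
        assert back.raw_points == report.raw_points


class TestRendering:
    def test_json_round_trip_equal(self, cfg):
        log = run_session(full_range_plan(), perfect_responder, cfg, seed=0)
        report = build_report(log)
        assert parse_report_json(render_report(report, "json")) == report

    def test_markdown_contains_all_item_labels(self, cfg):
        md = render_report(build_report(SessionLog("s", "p", cfg)), "markdown")
        for iid in ITEM_IDS:
            assert iid in md

    def test_csv_has_eight_item_rows_plus_two_summary_rows(self, cfg):
        csv = render_report(build_report(SessionLog("s", "p", cfg)), "csv")
        lines = [ln for ln in csv.strip().splitlines() if ln]
        assert len(lines) == 1 + 8 + 2  # header + items + summaries

    def test_unknown_format_rejected(self, cfg):
        with pytest.raises(ValueError):
            render_report(build_report(SessionLog("s", "p", cfg)), "pdf")


class TestAgreementWithHandScoring:
    def test_automatic_scores_equal_hand_computed_scores_on_50_sessions(self, cfg):
        """Oracle agreement: recompute every item from the raw angle table."""
        agree = 0
        total = 0
        for seed in range(50):
            plan = make_session_plan(6, rng_seed=seed)
            kind = ["unimpaired", "right_arm_deficit", "dystonia_like", "global_impairment"][seed % 4]
            log = run_session(plan, responder_from_profile(make_preset_profile(kind), cfg), cfg, seed=seed)
            report = build_report(log)
            df = log.angles_frame()
            held = df[df["held"]]
            for side in ("left", "right"):
                sub = held[held["side"] == side]
                for iid in ITEM_IDS:
                    if len(sub) == 0:
                        hand = 1
                    else:
                        if iid == "shoulder_flexion":
                            v = float(np.maximum(0.0, sub["shoulder_opening"] * np.cos(sub["shoulder_rotation"])).max())
                        elif iid == "shoulder_abduction":
                            v = float((sub["shoulder_opening"] * np.abs(np.sin(sub["shoulder_rotation"]))).max())
                        elif iid == "elbow_flexion":
                            v = float((math.pi - sub["elbow_opening"]).max())
                        else:
                            v = float(sub["elbow_opening"].max())
                        hand = 2 if v >= DEFAULT_CRITERIA[iid] else 1
                    total += 1
                    agree += int(hand == report.item(iid, side).score)
        assert total == 50 * 8
        assert agree == total  # 100% agreement required


class TestQuestItemInvariants:
    def test_score_two_requires_tested(self):
        with pytest.raises(ValueError):
            QuestItem("elbow_flexion", "left", score=2, tested=False)

    def test_report_requires_exactly_eight_items(self):
        items = tuple(
            QuestItem(iid, side, 1, False) for iid in ITEM_IDS for side in ("left", "right")
        )
        QuestReport("p", "s", items)  # ok
        with pytest.raises(ValueError):
            QuestReport("p", "s", items[:7])
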