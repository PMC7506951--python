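"""End-to-end pipeline (plan -> session -> report -> classifier) with a run manifest.

Every pipeline run records a manifest — tool version, SHA-256 digests of the
input files, the master seed and the per-stage seeds derived from it, and
the output paths — sufficient to reproduce every artifact bit-for-bit.
Stage seeds are fanned out from the master seed through named substreams so
that stages are reproducible independently of one another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classifier import generate_training_corpus, extract_rules, rules_to_json, sweep_min_leaf, train_tree
from .quest import build_report, render_report
from .session import SessionConfig, dump_plan, load_plan, run_session, summarize_session, write_angles_csv, write_log_jsonl
from .simulate import PRESET_KINDS, load_profile, make_preset_profile, make_session_plan, responder_from_profile

__all__ = ["RunManifest", "run_pipeline", "derive_seed"]

_STAGE_ORDER = ("plan", "session", "report", "corpus", "tree", "sweep")


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed (below 2**31)."""
    idx = _STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    version: str
    master_seed: int
    stage_seeds: dict[str, int]
    input_digests: dict[str, str]
    outputs: dict[str, str]
    started_at: float
    finished_at: float | None = None
    failed_stage: str | None = None
    config: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2), encoding="utf-8")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def run_pipeline(config_path) -> RunManifest:
    """Run the demo pipeline described by a YAML config.

    Config keys: ``out_dir``; ``seed``; either ``plan`` (file) or ``n_poses``;
    either ``profile`` (file) or ``preset``; optional ``criteria`` (file of
    per-item angles); optional ``classifier`` block (``n_examples``,
    ``min_leaf``, ``leaf_values``, ``runs``).  Missing referenced files fail
    fast; if a stage fails, earlier outputs are retained and the manifest
    marks the failed stage.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise FileNotFoundError(f"pipeline config not found: {config_path}")
    cfg = yaml.safe_load(config_path.read_text(encoding="utf-8")) or {}

    out_dir = Path(cfg.get("out_dir", "pipeline_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg.get("seed", 0))

    digests = {str(config_path): _digest(config_path)}
    for key in ("plan", "profile", "criteria"):
        if key in cfg and cfg[key]:
            p = Path(cfg[key])
            if not p.exists():
                raise FileNotFoundError(f"pipeline input {key!r} not found: {p}")
            digests[str(p)] = _digest(p)

    manifest = RunManifest(
        version=__version__,
        master_seed=master_seed,
        stage_seeds={stage: derive_seed(master_seed, stage) for stage in _STAGE_ORDER},
        input_digests=digests,
        outputs={},
        started_at=time.time(),
        config=cfg,
    )
    manifest_path = out_dir / "manifest.json"

    stage = "plan"
    try:
        if cfg.get("plan"):
            plan = load_plan(cfg["plan"])
        else:
            plan = make_session_plan(int(cfg.get("n_poses", 24)), rng_seed=manifest.stage_seeds["plan"])
            plan_path = out_dir / "plan.yaml"
            dump_plan(plan, plan_path)
            manifest.outputs["plan"] = str(plan_path)

        stage = "session"
        if cfg.get("profile"):
            profile = load_profile(cfg["profile"])
        else:
            preset = cfg.get("preset", "unimpaired")
            if preset not in PRESET_KINDS:
                raise ValueError(f"unknown preset {preset!r}; expected one of {PRESET_KINDS}")
            profile = make_preset_profile(preset)
        session_cfg = SessionConfig(**cfg.get("session", {}))
        log = run_session(
            plan,
            responder_from_profile(profile, session_cfg),
            session_cfg,
            seed=manifest.stage_seeds["session"],
            session_id=f"pipeline-{master_seed}",
            patient_id=profile.patient_id,
        )
        log_path = out_dir / "log.jsonl"
        angles_path = out_dir / "angles.csv"
        summary_path = out_dir / "summary.csv"
        write_log_jsonl(log, log_path)
        write_angles_csv(log, angles_path)
        summarize_session(log).to_csv(summary_path, index=False)
        manifest.outputs.update(log=str(log_path), angles=str(angles_path), summary=str(summary_path))

        stage = "report"
        criteria = None
        if cfg.get("criteria"):
            criteria = {k: float(v) for k, v in yaml.safe_load(Path(cfg["criteria"]).read_text()).items()}
        report = build_report(log, criteria=criteria)
        report_path = out_dir / "quest_report.json"
        report_path.write_text(render_report(report, "json"), encoding="utf-8")
        (out_dir / "quest_report.md").write_text(render_report(report, "markdown"), encoding="utf-8")
        manifest.outputs["quest_report"] = str(report_path)

        clf_cfg = cfg.get("classifier", {})
        if clf_cfg.get("enabled", True):
            stage = "corpus"
            dataset = generate_training_corpus(
                int(clf_cfg.get("n_examples", 2000)),
                theta=float(clf_cfg.get("theta", 0.28)),
                seed=manifest.stage_seeds["corpus"],
            )
            corpus_path = out_dir / "poses.csv"
            dataset.write_csv(corpus_path)
            manifest.outputs["corpus"] = str(corpus_path)

            stage = "tree"
            min_leaf = int(clf_cfg.get("min_leaf", 30))
            model, accuracy = train_tree(dataset, min_leaf, seed=manifest.stage_seeds["tree"])
            model_path = out_dir / "model.json"
            model_path.write_text(rules_to_json(extract_rules(model), min_leaf), encoding="utf-8")
            manifest.outputs["model"] = str(model_path)
            manifest.config.setdefault("results", {})["tree_accuracy"] = accuracy

            if clf_cfg.get("leaf_values"):
                stage = "sweep"
                table = sweep_min_leaf(
                    dataset,
                    [int(v) for v in clf_cfg["leaf_values"]],
                    runs=int(clf_cfg.get("runs", 20)),
                    base_seed=manifest.stage_seeds["sweep"],
                )
                sweep_path = out_dir / "sweep.csv"
                table.to_csv(sweep_path, index=False)
                manifest.outputs["sweep"] = str(sweep_path)
    except Exception:
        manifest.failed_stage = stage
        manifest.finished_at = time.time()
        manifest.write(manifest_path)
        raise

    manifest.finished_at = time.time()
    manifest.write(manifest_path)
    return manifest
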