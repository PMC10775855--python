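"""End-to-end screening pipeline: simulate, score, train, evaluate.

Everything downstream of the configuration is deterministic given the
master seed; every artifact written embeds provenance (seed, config hash,
package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .device import DeviceProfile, GALAXY_TAB_A_2016
from .evalstats import evaluate_screening
from .observer import (CohortConfig, SCORE_COLUMNS, frame_to_matrices,
                       generate_cohort)
from .perceptron import (GradientTrainerConfig, SATrainerConfig,
                         gradient_train, input_significance, overfitting_check,
                         sa_optimize)
from .scoring import apply_pass_criterion
from .stimgen import SessionProtocol, STEREO_CONDITIONS

log = logging.getLogger("stereoscreen")

_CONDITION_COLUMN = dict(zip(STEREO_CONDITIONS, SCORE_COLUMNS))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    device: DeviceProfile = field(default_factory=lambda: GALAXY_TAB_A_2016)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    sa: SATrainerConfig = field(default_factory=SATrainerConfig)
    gradient: GradientTrainerConfig = field(default_factory=GradientTrainerConfig)
    run_significance: bool = True
    master_seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(_serialise(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _serialise(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _serialise(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _serialise(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialise(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def score_sessions(frame: pd.DataFrame, per_test_threshold: int = 3) -> pd.DataFrame:
    """Add pass/fail columns per condition and a session validity flag."""
    from .observer import CorrectionStatus, Group, SessionResult

    out = frame.copy()
    pass_cols: dict = {c: [] for c in STEREO_CONDITIONS}
    valid, combined, combined_pass = [], [], []
    for _, row in frame.iterrows():
        session = SessionResult(
            subject_id=row["subject_id"],
            correction_status=CorrectionStatus(row["correction_status"]),
            scores={c: int(row[_CONDITION_COLUMN[c]]) for c in STEREO_CONDITIONS},
            control_correct=int(row["control_correct"]),
            group=Group(row["group"]))
        report = apply_pass_criterion(session, per_test_threshold)
        for cond in STEREO_CONDITIONS:
            pass_cols[cond].append(report.passed[cond])
        valid.append(report.session_valid)
        combined.append(report.combined_score)
        combined_pass.append(report.combined_passed)
    for cond in STEREO_CONDITIONS:
        out[f"pass_{_CONDITION_COLUMN[cond]}"] = pass_cols[cond]
    out["session_valid"] = valid
    out["combined_score"] = combined
    out["combined_passed"] = combined_pass
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort, score it, train the fusion models and evaluate.

    Writes intermediate CSVs, trained models and evaluation tables under
    ``out_dir`` plus a provenance JSON; returns the output directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"master_seed": config.master_seed,
                  "config_hash": config.config_hash(),
                  "version": __version__}

    stage = "simulate"
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.master_seed)
        cohort = generate_cohort(cohort_cfg, SessionProtocol.default())
        frame = cohort.to_frame()
        frame.to_csv(out_dir / "cohort.csv", index=False)
        log.info("simulated %d sessions (seed %d)", len(frame),
                 config.master_seed)

        stage = "score"
        scored = score_sessions(frame)
        scored.to_csv(out_dir / "cohort_scored.csv", index=False)

        stage = "train"
        X, y_joint = frame_to_matrices(frame, positive="joint")
        _, y_ambl = frame_to_matrices(frame, positive="amblyopia")
        sa_cfg = dataclasses.replace(config.sa, seed=config.master_seed + 1)
        model_aw, _ = sa_optimize(X, y_joint, sa_cfg)
        model_w, _ = sa_optimize(X, y_ambl, dataclasses.replace(
            sa_cfg, seed=config.master_seed + 2))
        model_aw.to_json(out_dir / "model_aw.json", **provenance)
        model_w.to_json(out_dir / "model_w.json", **provenance)

        grad_cfg = dataclasses.replace(config.gradient,
                                       seed=config.master_seed + 3)
        reports = [gradient_train(X, y_joint, None, grad_cfg, run_index=i,
                                  seed=config.master_seed + 100 + i)
                   for i in range(grad_cfg.n_runs)]
        summary = overfitting_check(reports)
        pd.DataFrame([{"run": r.run_index, "train_auc": r.train_auc,
                       "validation_auc": r.validation_auc,
                       "converged": r.converged} for r in reports]
                     ).to_csv(out_dir / "training_runs.csv", index=False)

        if config.run_significance:
            sig = input_significance(X, y_joint, grad_cfg)
            sig.tidy().to_csv(out_dir / "input_subset_aucs.csv", index=False)

        stage = "evaluate"
        from .perceptron import CombineMode, combined_score
        eval_frame = frame.copy()
        eval_frame["ai_sum"] = combined_score(X, CombineMode.SUM)
        eval_frame["ai_w"] = combined_score(X, CombineMode.W, model_w)
        eval_frame["ai_aw"] = combined_score(X, CombineMode.AW, model_aw)
        tables = evaluate_screening(
            eval_frame, list(SCORE_COLUMNS) + ["ai_sum", "ai_w", "ai_aw"])
        for name, tbl in tables.items():
            tbl.to_csv(out_dir / f"report_{name}.csv")

        provenance["overfitting"] = dataclasses.asdict(summary)
        (out_dir / "provenance.json").write_text(
            json.dumps(provenance, indent=2))
    except Exception as exc:                         # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    return out_dir


def validate_session_file(path: str | Path) -> list[str]:
    """Schema and range checks on a session CSV; returns found issues."""
    from .observer import Group

    issues: list[str] = []
    frame = pd.read_csv(path)
    required = {"subject_id", "group", "correction_status",
                "control_correct", *SCORE_COLUMNS}
    missing = required - set(frame.columns)
    if missing:
        issues.append(f"missing columns: {sorted(missing)}")
        return issues
    valid_groups = {g.value for g in Group}
    for i, row in frame.iterrows():
        for col in SCORE_COLUMNS:
            if not 0 <= row[col] <= 5:
                issues.append(f"row {i}: {col}={row[col]} outside [0, 5]")
        if not 0 <= row["control_correct"] <= 4:
            issues.append(f"row {i}: control_correct outside [0, 4]")
        if row["group"] not in valid_groups:
            issues.append(f"row {i}: unknown group {row['group']!r}")
        if row["correction_status"] not in ("NC", "WC"):
            issues.append(f"row {i}: unknown correction status "
                          f"{row['correction_status']!r}")
    dup = frame.duplicated(subset=["subject_id", "correction_status"])
    for i in frame.index[dup]:
        issues.append(f"row {i}: duplicate (subject_id, correction_status) "
                      f"pair {frame.loc[i, 'subject_id']!r}")
    return issues
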