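"""End-to-end pipeline orchestration and run reporting.

``run_pipeline`` executes preprocess -> foot-strike cleanup -> feature
extraction -> selection + LOOCV classification over a directory of trial
CSVs plus a cohort file, writes every intermediate table, and returns a
``RunReport`` (also serialized as JSON and Markdown) whose per-stage counts
make the cleanup heuristics auditable.  Reruns with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gaitconf import __version__ as VERSION
from gaitconf.errors import SchemaError, ValidationError
from gaitconf.features import DEFAULT_FFT_LEN, extract_step_matrix, aggregate_trial
from gaitconf.footstrike import (
    CleanupConfig,
    FootStrikeSeries,
    clean_footstrikes,
    detect_candidates,
    read_strikes_csv,
    write_strikes_csv,
)
from gaitconf.model import ForestConfig, LabeledCohort, loocv
from gaitconf.preprocess import PreprocessConfig, load_trial, preprocess_trial

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    input_dir: str
    output_dir: str
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cleanup: CleanupConfig = field(default_factory=CleanupConfig)
    fft_len: int = DEFAULT_FFT_LEN
    forest: ForestConfig = field(default_factory=ForestConfig)
    selection: str = "global"
    seed: int = 0
    verbosity: int = 1


@dataclass
class TrialStageCounts:
    n_raw_samples: int
    n_uniform_samples: int
    n_candidates: int
    n_removed: int
    n_inserted: int
    n_strikes: int
    n_steps: int


@dataclass
class RunReport:
    config: dict
    version: str
    per_trial: dict[str, TrialStageCounts]
    selected_features: list[str] | None
    confusion: dict
    metrics: dict
    n_models: int

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        lines = [
            "# Pipeline run report",
            "",
            f"- version: {self.version}",
            f"- seed: {self.config.get('seed')}",
            f"- participants: {len(self.per_trial)}",
            f"- LOOCV models trained: {self.n_models}",
            "",
            "## Classification",
            "",
            f"- confusion (positive = high confidence): {self.confusion}",
            f"- metrics (%): {self.metrics}",
            "",
            "## Selected features",
            "",
        ]
        if self.selected_features is None:
            lines.append("(per-fold nested selection; see predictions.csv)")
        else:
            lines += [f"- {name}" for name in self.selected_features]
        lines += ["", "## Per-trial stage counts", ""]
        header = (
            "| participant | raw | uniform | candidates | removed | inserted "
            "| strikes | steps |"
        )
        lines += [header, "|" + "---|" * 8]
        for pid, c in self.per_trial.items():
            lines.append(
                f"| {pid} | {c.n_raw_samples} | {c.n_uniform_samples} | "
                f"{c.n_candidates} | {c.n_removed} | {c.n_inserted} | "
                f"{c.n_strikes} | {c.n_steps} |"
            )
        return "\n".join(lines) + "\n"


def _config_echo(cfg: RunConfig) -> dict:
    echo = dataclasses.asdict(cfg)
    echo["preprocess"]["axis_map"] = dataclasses.asdict(cfg.preprocess.axis_map)
    return echo


def process_trial(
    path,
    cfg: RunConfig,
    candidates: FootStrikeSeries | None = None,
    participant_id: str | None = None,
):
    """Run one trial through preprocess + footstrike + features.

    Returns (trial, strikes, step_matrix, trial_vector, stage_counts).
    Externally supplied candidate labels pass through the same cleanup.
    """
    raw = load_trial(path, cfg.preprocess.axis_map, participant_id=participant_id)
    trial = preprocess_trial(raw, cfg.preprocess)
    cands = candidates if candidates is not None else detect_candidates(trial)
    strikes = clean_footstrikes(cands, trial, cfg.cleanup)
    n_inserted = int(np.sum(strikes.source == "inserted"))
    n_removed = len(cands) - (len(strikes) - n_inserted)
    step_matrix = extract_step_matrix(trial, strikes, cfg.fft_len)
    vector = aggregate_trial(step_matrix)
    counts = TrialStageCounts(
        n_raw_samples=int(raw.timestamps.size),
        n_uniform_samples=trial.n_samples,
        n_candidates=len(cands),
        n_removed=int(n_removed),
        n_inserted=n_inserted,
        n_strikes=len(strikes),
        n_steps=len(step_matrix),
    )
    return trial, strikes, step_matrix, vector, counts


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis over ``cfg.input_dir``.

    Expects ``cohort.csv`` (participant_id, abc_score[, fall_history]) and
    one ``<participant_id>.csv`` trial file per row; optional
    ``<participant_id>_candidates.csv`` files supply external foot-strike
    labels.  Any stage error aborts naming the stage and participant.
    """
    cohort_path = os.path.join(cfg.input_dir, "cohort.csv")
    if not os.path.exists(cohort_path):
        raise ValidationError(f"cohort file not found: {cohort_path}")
    manifest = pd.read_csv(cohort_path)
    if "participant_id" not in manifest.columns or "abc_score" not in manifest.columns:
        raise SchemaError(f"{cohort_path}: needs participant_id and abc_score columns")
    os.makedirs(cfg.output_dir, exist_ok=True)

    vectors, per_trial = {}, {}
    for _, row in manifest.iterrows():
        pid = str(row["participant_id"])
        trial_path = os.path.join(cfg.input_dir, f"{pid}.csv")
        if not os.path.exists(trial_path):
            raise ValidationError(f"participant {pid!r}: trial file {trial_path} missing")
        cand_path = os.path.join(cfg.input_dir, f"{pid}_candidates.csv")
        candidates = read_strikes_csv(cand_path) if os.path.exists(cand_path) else None
        try:
            trial, strikes, step_matrix, vector, counts = process_trial(
                trial_path, cfg, candidates, participant_id=pid
            )
        except ValidationError as exc:
            raise ValidationError(f"participant {pid!r}: {exc}") from exc
        write_strikes_csv(strikes, os.path.join(cfg.output_dir, f"{pid}_strikes.csv"))
        step_matrix.to_csv(os.path.join(cfg.output_dir, f"{pid}_steps.csv"))
        vectors[pid] = vector
        per_trial[pid] = counts
        if cfg.verbosity:
            logger.info(
                "trial %s: %d strikes (%d inserted), %d steps",
                pid, counts.n_strikes, counts.n_inserted, counts.n_steps,
            )

    features = pd.DataFrame(vectors).T
    features.index.name = "participant_id"
    features.to_csv(os.path.join(cfg.output_dir, "features.csv"))

    abc = pd.Series(
        manifest["abc_score"].to_numpy(float),
        index=manifest["participant_id"].astype(str),
    )
    fall = None
    if "fall_history" in manifest.columns:
        fall = pd.Series(
            manifest["fall_history"].to_numpy(),
            index=manifest["participant_id"].astype(str),
        )
    cohort = LabeledCohort(features, abc, fall_history=fall)
    result = loocv(cohort, cfg.forest, selection=cfg.selection)

    result.predictions.rename("predicted").to_frame().assign(
        label=cohort.labels
    ).to_csv(os.path.join(cfg.output_dir, "predictions.csv"))
    if result.selected is not None:
        with open(os.path.join(cfg.output_dir, "selected_features.txt"), "w") as fh:
            fh.write("\n".join(result.selected) + "\n")

    report = RunReport(
        config=_config_echo(cfg),
        version=VERSION,
        per_trial=per_trial,
        selected_features=result.selected,
        confusion=dataclasses.asdict(result.confusion),
        metrics=result.metrics.as_dict(),
        n_models=result.n_models,
    )
    with open(os.path.join(cfg.output_dir, "report.json"), "w") as fh:
        fh.write(report.to_json())
    with open(os.path.join(cfg.output_dir, "report.md"), "w") as fh:
        fh.write(report.to_markdown())
    return report


def features_from_records(
    records,
    preprocess_cfg: PreprocessConfig | None = None,
    cleanup_cfg: CleanupConfig | None = None,
    fft_len: int = DEFAULT_FFT_LEN,
) -> LabeledCohort:
    """In-memory pipeline over synthetic cohort records (no disk IO).

    Runs preprocess -> detection -> cleanup -> features for each record and
    assembles the LabeledCohort the classifier consumes.
    """
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    cleanup_cfg = cleanup_cfg or CleanupConfig()
    vectors, abc = {}, {}
    for rec in records:
        trial = preprocess_trial(rec.raw, preprocess_cfg)
        strikes = clean_footstrikes(detect_candidates(trial), trial, cleanup_cfg)
        step_matrix = extract_step_matrix(trial, strikes, fft_len)
        vectors[rec.participant_id] = aggregate_trial(step_matrix)
        abc[rec.participant_id] = rec.abc_score
    features = pd.DataFrame(vectors).T
    features.index.name = "participant_id"
    return LabeledCohort(features, pd.Series(abc))


def summarize_abc(item_table: pd.DataFrame) -> pd.DataFrame:
    """Per-item ABC summary: mean score, count of 0% and 100% responses.

    ``item_table`` is participants x 16 item scores (0-100 each).
    """
    if item_table.shape[1] != 16:
        raise ValidationError(
            f"ABC item table needs 16 columns, got {item_table.shape[1]}"
        )
    values = item_table.to_numpy(float)
    if np.any(values < 0) or np.any(values > 100):
        raise ValidationError("ABC item scores must lie in [0, 100]")
    return pd.DataFrame(
        {
            "mean_score": values.mean(axis=0),
            "n_zero": (values == 0).sum(axis=0),
            "n_full": (values == 100).sum(axis=0),
        },
        index=pd.Index(item_table.columns, name="item"),
    )
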