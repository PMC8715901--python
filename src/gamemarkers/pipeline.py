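"""One-command orchestration: simulate -> extract -> score -> analyze.

Every stage reads and writes plain files; a JSON run manifest records the
configuration snapshot, seed, package version, SHA-256 digest of each stage
input/output, and the exclusion log, so a run can be audited and re-run
byte-for-byte.  Structured progress goes to stderr; results only to files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import AnalysisReport, run_full_analysis
from .markers import extract_markers
from .questionnaires import score_lsas, score_pis
from .synthetic_cohort import SimulationConfig, simulate_cohort
from .telemetry import (
    ParticipantRecord,
    RoomConfig,
    read_cohort,
    read_room,
    write_cohort,
    write_room,
)

__all__ = [
    "RunManifest",
    "DigestMismatchError",
    "load_simulation_config",
    "stage_simulate",
    "stage_extract",
    "stage_score",
    "stage_analyze",
    "run_pipeline",
]

log = logging.getLogger("gamemarkers")


class DigestMismatchError(RuntimeError):
    """A stage input changed since the manifest recorded it."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest:
    """Per-stage file digests plus config/seed/version, serialized to JSON."""

    def __init__(self, config: dict, seed: int | None):
        self.data: dict = {
            "package_version": __version__,
            "seed": seed,
            "config": config,
            "stages": {},
            "exclusions": {},
            "failed_stage": None,
        }

    def record(self, stage: str, inputs: Sequence[Path], outputs: Sequence[Path]) -> None:
        self.data["stages"][stage] = {
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }

    def verify_inputs(self, stage_producing: str, paths: Sequence[Path]) -> None:
        """Check that files still match the digests the producing stage wrote."""
        recorded = self.data["stages"].get(stage_producing, {}).get("outputs", {})
        for p in paths:
            key = str(p)
            if key in recorded and _sha256(Path(p)) != recorded[key]:
                raise DigestMismatchError(
                    f"{p} was modified after stage '{stage_producing}' wrote it"
                )

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def load_simulation_config(path: str | Path | None, **overrides) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    room_data = data.pop("room", None)
    data.update({k: v for k, v in overrides.items() if v is not None})
    room = (
        RoomConfig(
            npc_position=tuple(room_data["npc_position"]),
            spawn_position=tuple(room_data["spawn_position"]),
            elevator_left=tuple(room_data["elevator_left"]),
            elevator_right=tuple(room_data["elevator_right"]),
            corridor_half_width=float(room_data.get("corridor_half_width", 6.0)),
        )
        if room_data
        else RoomConfig()
    )
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(room=room, **data)


def stage_simulate(cfg: SimulationConfig, out_dir: Path) -> dict[str, Path]:
    cohort = simulate_cohort(cfg)
    log.info("simulate: %d participants, seed %d", cfg.n_participants, cfg.seed)
    paths = write_cohort(cohort, out_dir)
    room_path = out_dir / "room.yaml"
    write_room(cfg.room, room_path)
    paths["room"] = room_path
    return paths


def stage_extract(in_dir: Path, room_path: Path, out_path: Path) -> tuple[Path, dict]:
    cohort, problems = read_cohort(in_dir, strict=False)
    room = read_room(room_path)
    complete = [r for r in cohort if r.complete]
    log.info(
        "extract: %d participants (%d incomplete excluded)",
        len(complete), len(cohort) - len(complete),
    )
    df = extract_markers(complete, room)
    df.to_csv(out_path, index=False, float_format="%.6f")
    return out_path, problems


def stage_score(participants_dir: Path, out_path: Path) -> Path:
    cohort, _ = read_cohort(participants_dir, strict=False)
    rows = []
    for rec in sorted(cohort, key=lambda r: r.participant_id):
        row: dict = {
            "participant_id": rec.participant_id,
            "age": rec.age,
            "gender": rec.gender.value,
        }
        if rec.lsas_responses is not None:
            res = score_lsas(rec.lsas_responses)
            row.update(
                lsas_total=res.total,
                lsas_fear=res.fear_sum,
                lsas_avoidance=res.avoidance_sum,
                lsas_social_interaction=res.social_interaction_sum,
                lsas_performance=res.performance_sum,
                lsas_category=res.category.value,
            )
        if rec.pis_responses:
            for sub, mean in score_pis(rec.pis_responses).items():
                row[f"pis_{sub}_mean"] = mean
        rows.append(row)
    log.info("score: %d participants", len(rows))
    pd.DataFrame(rows).to_csv(out_path, index=False, float_format="%.6f")
    return out_path


def stage_analyze(in_dir: Path, room_path: Path, out_dir: Path, *, holm: bool = False) -> AnalysisReport:
    cohort, _ = read_cohort(in_dir, strict=False)
    room = read_room(room_path)
    report = run_full_analysis(cohort, room, holm=holm)
    report.mancova.to_csv(out_dir / "mancova.csv", index=False, float_format="%.6f")
    report.regressions.to_csv(out_dir / "regressions.csv", index=False, float_format="%.6f")
    results = {
        "n_participants": report.n_participants,
        "n_regression": report.n_regression,
        "conventions": report.conventions,
        "holm_corrected": report.holm_corrected,
        "exclusions": report.exclusions,
        "mancova": report.mancova.to_dict(orient="records"),
        "regressions": report.regressions.to_dict(orient="records"),
    }
    (out_dir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
    log.info(
        "analyze: n=%d, %d regressions, %d mancova rows",
        report.n_regression, len(report.regressions), len(report.mancova),
    )
    return report


def run_pipeline(
    out_dir: str | Path,
    *,
    config_path: str | Path | None = None,
    seed: int | None = None,
    n: int | None = None,
    holm: bool = False,
) -> RunManifest:
    """simulate -> extract -> score -> analyze, with a manifest at the end.

    On a stage failure the partial outputs are kept and the manifest records
    the failure point before the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_simulation_config(config_path, seed=seed, n_participants=n)
    manifest = RunManifest(_cfg_dict(cfg), cfg.seed)
    manifest_path = out / "manifest.json"
    stage = "simulate"
    try:
        paths = stage_simulate(cfg, out)
        manifest.record("simulate", [], list(paths.values()))

        stage = "extract"
        manifest.verify_inputs("simulate", [paths["samples"], paths["trials"]])
        markers_path = out / "markers.csv"
        _, problems = stage_extract(out, paths["room"], markers_path)
        manifest.data["exclusions"]["telemetry"] = problems
        manifest.record("extract", [paths["samples"], paths["trials"]], [markers_path])

        stage = "score"
        manifest.verify_inputs("simulate", [paths["participants"]])
        scores_path = out / "scores.csv"
        stage_score(out, scores_path)
        manifest.record("score", [paths["participants"]], [scores_path])

        stage = "analyze"
        manifest.verify_inputs("extract", [markers_path])
        report = stage_analyze(out, paths["room"], out, holm=holm)
        manifest.data["exclusions"]["analysis"] = report.exclusions
        manifest.record(
            "analyze",
            [markers_path, scores_path],
            [out / "mancova.csv", out / "regressions.csv", out / "results.json"],
        )
    except Exception:
        manifest.data["failed_stage"] = stage
        manifest.save(manifest_path)
        raise
    manifest.save(manifest_path)
    return manifest


def _cfg_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["lsas_item_params"] = {
        "a": np.asarray(cfg.lsas_item_params.a).tolist(),
        "b": np.asarray(cfg.lsas_item_params.b).tolist(),
    }
    return d
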