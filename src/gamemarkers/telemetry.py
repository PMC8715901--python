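"""Domain types and file I/O for avatar-movement telemetry.

The assessment room is modelled on a flat ground plane in meters, with the
NPC (the virtual stranger the player must approach and bypass) at the
origin.  The player spawns in front of the NPC and, after the conversation,
walks past the NPC to one of two elevator doors behind it.  One trial is a
single delivery errand: approach, converse, choose an elevator, rate the
NPC.  A cohort is serialized as three flat CSV tables (participants,
trials, samples) plus a YAML room-geometry file, so that every pipeline
stage can be tested and re-run independently.

Timestamps are integer milliseconds since the trial start; positions after
the conversation sit on an exact 50 ms grid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Phase",
    "Side",
    "Emotion",
    "Gender",
    "RoomConfig",
    "TrajectorySample",
    "TrialLog",
    "ParticipantRecord",
    "ValidationError",
    "CohortParseError",
    "validate_trial",
    "validate_participant",
    "read_cohort",
    "write_cohort",
    "read_room",
    "write_room",
]

SAMPLE_PERIOD_MS = 50
N_TRIALS = 20
EVENT_NAMES = (
    "trial_start",
    "conversation_start",
    "conversation_end",
    "elevator_selected",
    "trial_end",
)

_FLOAT_FMT = "%.6f"


class Phase(str, enum.Enum):
    APPROACH = "approach"
    POST_CONVERSATION = "post_conversation"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Emotion(str, enum.Enum):
    FRIENDLY = "friendly"
    ANGRY = "angry"


class Gender(str, enum.Enum):
    MAN = "man"
    WOMAN = "woman"
    NON_BINARY = "non_binary"


class ValidationError(ValueError):
    """A record violates a telemetry invariant (event order, sample grid...)."""


class CohortParseError(ValueError):
    """A cohort file is malformed; message names the file and row."""


@dataclass(frozen=True)
class RoomConfig:
    """Geometry of the assessment room, meters, NPC at the origin.

    The NPC stands ``npc_elevator_depth_m`` (default 10 m) in front of the
    elevator line and centered between the two doors; the player spawns on
    the opposite side.  Spawn depth and the lateral elevator offset are free
    parameters of the room, defaulting to 10 m and 4 m.
    """

    npc_position: tuple[float, float] = (0.0, 0.0)
    spawn_position: tuple[float, float] = (0.0, -10.0)
    elevator_left: tuple[float, float] = (-4.0, 10.0)
    elevator_right: tuple[float, float] = (4.0, 10.0)
    corridor_half_width: float = 6.0

    def __post_init__(self) -> None:
        npc = np.asarray(self.npc_position, dtype=float)
        el = np.asarray(self.elevator_left, dtype=float)
        er = np.asarray(self.elevator_right, dtype=float)
        sp = np.asarray(self.spawn_position, dtype=float)
        if np.allclose(el, er):
            raise ValueError("elevator doors must be distinct")
        # mirror symmetry of the doors about the spawn->NPC axis
        axis = npc - sp
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("spawn and NPC positions coincide")
        axis = axis / norm
        def _reflect(p: np.ndarray) -> np.ndarray:
            rel = p - npc
            along = np.dot(rel, axis) * axis
            return npc + 2 * along - rel
        if not np.allclose(_reflect(el), er, atol=1e-9):
            raise ValueError(
                "elevator doors are not mirror-symmetric about the spawn-NPC axis"
            )

    @property
    def elevator_depth_m(self) -> float:
        """Perpendicular distance from the NPC to the elevator line."""
        el = np.asarray(self.elevator_left, dtype=float)
        er = np.asarray(self.elevator_right, dtype=float)
        npc = np.asarray(self.npc_position, dtype=float)
        d = er - el
        d = d / np.linalg.norm(d)
        rel = npc - el
        return float(np.linalg.norm(rel - np.dot(rel, d) * d))

    def elevator(self, side: Side) -> tuple[float, float]:
        return self.elevator_left if side is Side.LEFT else self.elevator_right


@dataclass(frozen=True)
class TrajectorySample:
    t_ms: int
    x_m: float
    y_m: float
    phase: Phase

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x_m, self.y_m])


@dataclass
class TrialLog:
    """One delivery trial: lifecycle events plus the sampled trajectory."""

    trial_id: int
    elevator_side: Side
    npc_emotion: Emotion
    team_name: str
    events: dict[str, int]
    samples: list[TrajectorySample] = field(default_factory=list)

    def samples_in_phase(self, phase: Phase) -> list[TrajectorySample]:
        return [s for s in self.samples if s.phase is phase]

    @property
    def post_samples(self) -> list[TrajectorySample]:
        return self.samples_in_phase(Phase.POST_CONVERSATION)


@dataclass
class ParticipantRecord:
    participant_id: str
    age: float
    gender: Gender
    lsas_responses: np.ndarray | None = None  # (24, 2) ints: fear, avoidance
    pis_responses: dict[str, list[int]] = field(default_factory=dict)
    latent_sa: float | None = None  # standardized trait; simulated cohorts only
    trials: list[TrialLog] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return len(self.trials) == N_TRIALS


# ---------------------------------------------------------------------------
# validation

def validate_trial(trial: TrialLog) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    problems: list[str] = []
    missing = [e for e in EVENT_NAMES if e not in trial.events]
    if missing:
        problems.append(f"trial {trial.trial_id}: missing events {missing}")
        return problems
    ev = trial.events
    if not (
        ev["trial_start"] < ev["conversation_start"] <= ev["conversation_end"]
        < ev["elevator_selected"] <= ev["trial_end"]
    ):
        problems.append(
            f"trial {trial.trial_id}: event order violated "
            f"({[ev[e] for e in EVENT_NAMES]})"
        )
    t = np.array([s.t_ms for s in trial.samples])
    if len(t) and np.any(np.diff(t) <= 0):
        problems.append(f"trial {trial.trial_id}: t_ms not strictly increasing")
    post_t = np.array([s.t_ms for s in trial.post_samples])
    if len(post_t) >= 2 and np.any(np.diff(post_t) != SAMPLE_PERIOD_MS):
        problems.append(
            f"trial {trial.trial_id}: post_conversation samples not on the "
            f"{SAMPLE_PERIOD_MS} ms grid"
        )
    if len(post_t) < 2:
        problems.append(
            f"trial {trial.trial_id}: fewer than 2 post_conversation samples"
        )
    return problems


def validate_participant(record: ParticipantRecord) -> list[str]:
    problems: list[str] = []
    if not record.complete:
        problems.append(
            f"participant {record.participant_id}: incomplete "
            f"({len(record.trials)}/{N_TRIALS} trials)"
        )
    for trial in record.trials:
        problems.extend(
            f"participant {record.participant_id}: {p}" for p in validate_trial(trial)
        )
    return problems


# ---------------------------------------------------------------------------
# serialization: three flat tables + room yaml

_LSAS_FEAR = [f"lsas_f{i:02d}" for i in range(1, 25)]
_LSAS_AVOID = [f"lsas_a{i:02d}" for i in range(1, 25)]
PIS_SUBSCALES = ("sim", "emb", "wish")
PIS_ITEMS = {"sim": 6, "emb": 6, "wish": 5}
_PIS_COLS = {
    sub: [f"pis_{sub}_{i}" for i in range(1, PIS_ITEMS[sub] + 1)]
    for sub in PIS_SUBSCALES
}


def _participants_frame(cohort: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        row: dict[str, object] = {
            "participant_id": rec.participant_id,
            "age": rec.age,
            "gender": rec.gender.value,
        }
        lsas = rec.lsas_responses
        for i in range(24):
            row[_LSAS_FEAR[i]] = "" if lsas is None else int(lsas[i, 0])
            row[_LSAS_AVOID[i]] = "" if lsas is None else int(lsas[i, 1])
        for sub in PIS_SUBSCALES:
            vals = rec.pis_responses.get(sub, [])
            for j, col in enumerate(_PIS_COLS[sub]):
                row[col] = int(vals[j]) if j < len(vals) else ""
        row["latent_sa"] = "" if rec.latent_sa is None else f"{rec.latent_sa:.6f}"
        rows.append(row)
    cols = (
        ["participant_id", "age", "gender"]
        + _LSAS_FEAR
        + _LSAS_AVOID
        + [c for sub in PIS_SUBSCALES for c in _PIS_COLS[sub]]
        + ["latent_sa"]
    )
    return pd.DataFrame(rows, columns=cols)


def write_cohort(cohort: Sequence[ParticipantRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write participants/trials/samples CSVs; byte-deterministic for fixed input."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = sorted(cohort, key=lambda r: r.participant_id)

    paths = {
        "participants": out / "participants.csv",
        "trials": out / "trials.csv",
        "samples": out / "samples.csv",
    }
    _participants_frame(cohort).to_csv(
        paths["participants"], index=False, float_format=_FLOAT_FMT
    )

    trial_rows, sample_rows = [], []
    for rec in cohort:
        for trial in sorted(rec.trials, key=lambda t: t.trial_id):
            trial_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "trial_id": trial.trial_id,
                    "elevator_side": trial.elevator_side.value,
                    "npc_emotion": trial.npc_emotion.value,
                    "team_name": trial.team_name,
                    "t_trial_start": trial.events["trial_start"],
                    "t_conv_start": trial.events["conversation_start"],
                    "t_conv_end": trial.events["conversation_end"],
                    "t_elev_selected": trial.events["elevator_selected"],
                    "t_trial_end": trial.events["trial_end"],
                }
            )
            for s in trial.samples:
                sample_rows.append(
                    (rec.participant_id, trial.trial_id, s.t_ms, s.x_m, s.y_m, s.phase.value)
                )
    trial_cols = [
        "participant_id", "trial_id", "elevator_side", "npc_emotion", "team_name",
        "t_trial_start", "t_conv_start", "t_conv_end", "t_elev_selected", "t_trial_end",
    ]
    pd.DataFrame(trial_rows, columns=trial_cols).to_csv(paths["trials"], index=False)
    pd.DataFrame(
        sample_rows,
        columns=["participant_id", "trial_id", "t_ms", "x_m", "y_m", "phase"],
    ).to_csv(paths["samples"], index=False, float_format=_FLOAT_FMT)
    return paths


def read_cohort(
    in_dir: str | Path, *, strict: bool = True
) -> tuple[list[ParticipantRecord], dict[str, list[str]]]:
    """Read the three-table dialect back into validated records.

    Returns ``(records, problems)`` where ``problems`` maps participant_id to
    the invariant violations collected for it.  With ``strict=True`` (default)
    any violation raises :class:`ValidationError` naming the participant/trial.
    """
    in_dir = Path(in_dir)
    try:
        parts = pd.read_csv(in_dir / "participants.csv", dtype={"participant_id": str})
        trials = pd.read_csv(in_dir / "trials.csv", dtype={"participant_id": str})
        samples = pd.read_csv(in_dir / "samples.csv", dtype={"participant_id": str})
    except (pd.errors.ParserError, FileNotFoundError) as exc:
        raise CohortParseError(f"cannot parse cohort in {in_dir}: {exc}") from exc

    for name, df, required in (
        ("participants.csv", parts, ["participant_id", "age", "gender"]),
        ("trials.csv", trials, ["participant_id", "trial_id", "elevator_side"]),
        ("samples.csv", samples, ["participant_id", "trial_id", "t_ms", "x_m", "y_m", "phase"]),
    ):
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CohortParseError(f"{in_dir / name}: missing columns {missing}")

    sample_groups = {k: g for k, g in samples.groupby(["participant_id", "trial_id"], sort=False)}

    records: list[ParticipantRecord] = []
    problems: dict[str, list[str]] = {}
    for _, prow in parts.iterrows():
        pid = str(prow["participant_id"])
        try:
            gender = Gender(prow["gender"])
        except ValueError as exc:
            raise CohortParseError(
                f"participants.csv: participant {pid}: unknown gender {prow['gender']!r}"
            ) from exc
        lsas = None
        if _LSAS_FEAR[0] in parts.columns and not pd.isna(prow[_LSAS_FEAR[0]]):
            lsas = np.column_stack(
                [
                    [int(prow[c]) for c in _LSAS_FEAR],
                    [int(prow[c]) for c in _LSAS_AVOID],
                ]
            )
        pis: dict[str, list[int]] = {}
        for sub in PIS_SUBSCALES:
            cols = [c for c in _PIS_COLS[sub] if c in parts.columns]
            vals = [int(prow[c]) for c in cols if not pd.isna(prow[c])]
            if vals:
                pis[sub] = vals
        latent = None
        if "latent_sa" in parts.columns and not pd.isna(prow["latent_sa"]):
            latent = float(prow["latent_sa"])

        age = float(prow["age"])
        rec = ParticipantRecord(
            participant_id=pid,
            age=int(age) if age.is_integer() else age,
            gender=gender,
            lsas_responses=lsas,
            pis_responses=pis,
            latent_sa=latent,
        )
        for _, trow in trials[trials["participant_id"] == pid].iterrows():
            tid = int(trow["trial_id"])
            grp = sample_groups.get((pid, tid))
            trial_samples = []
            if grp is not None:
                for _, srow in grp.iterrows():
                    try:
                        trial_samples.append(
                            TrajectorySample(
                                t_ms=int(srow["t_ms"]),
                                x_m=float(srow["x_m"]),
                                y_m=float(srow["y_m"]),
                                phase=Phase(srow["phase"]),
                            )
                        )
                    except (ValueError, TypeError) as exc:
                        raise CohortParseError(
                            f"samples.csv: participant {pid} trial {tid}: bad row "
                            f"({dict(srow)}): {exc}"
                        ) from exc
            rec.trials.append(
                TrialLog(
                    trial_id=tid,
                    elevator_side=Side(trow["elevator_side"]),
                    npc_emotion=Emotion(trow["npc_emotion"]),
                    team_name=str(trow["team_name"]),
                    events={
                        "trial_start": int(trow["t_trial_start"]),
                        "conversation_start": int(trow["t_conv_start"]),
                        "conversation_end": int(trow["t_conv_end"]),
                        "elevator_selected": int(trow["t_elev_selected"]),
                        "trial_end": int(trow["t_trial_end"]),
                    },
                    samples=trial_samples,
                )
            )
        probs = validate_participant(rec)
        if probs:
            problems[pid] = probs
            if strict and any("incomplete" not in p for p in probs):
                raise ValidationError("; ".join(probs))
        records.append(rec)
    return records, problems


def write_room(room: RoomConfig, path: str | Path) -> None:
    data = {
        "npc_position": list(room.npc_position),
        "spawn_position": list(room.spawn_position),
        "elevator_left": list(room.elevator_left),
        "elevator_right": list(room.elevator_right),
        "corridor_half_width": room.corridor_half_width,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_room(path: str | Path) -> RoomConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RoomConfig(
        npc_position=tuple(data["npc_position"]),
        spawn_position=tuple(data["spawn_position"]),
        elevator_left=tuple(data["elevator_left"]),
        elevator_right=tuple(data["elevator_right"]),
        corridor_half_width=float(data.get("corridor_half_width", 6.0)),
    )
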