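"""The seven per-trial digital behavioral markers and participant means.

One explicit marker — the interpersonal distance (IPD), the avatar-to-NPC
Euclidean distance at the moment the conversation is initiated — and six
implicit ones computed from the trajectory sampled every 50 ms after the
conversation: time in room, path length, minimum and mean NPC distance, and
the skewness and kurtosis of the per-trial distribution of NPC distances.

Moment conventions: biased (divide-by-n) central moments; kurtosis is
Pearson's m4/m2^2 (non-excess), so a narrower, more consistent distance
profile reads as *elevated* kurtosis.  The conventions are exposed in
:data:`ESTIMATOR_CONVENTIONS` and carried into the extraction output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .telemetry import ParticipantRecord, Phase, RoomConfig, TrialLog

__all__ = [
    "MarkerSet",
    "MarkerError",
    "MARKER_NAMES",
    "ESTIMATOR_CONVENTIONS",
    "compute_ipd",
    "compute_time_in_room",
    "compute_path_features",
    "compute_markers",
    "aggregate_participant",
    "extract_markers",
]

MARKER_NAMES = (
    "ipd_m",
    "time_in_room_s",
    "path_length_m",
    "min_dist_m",
    "mean_dist_m",
    "dist_skew",
    "dist_kurtosis",
)

ESTIMATOR_CONVENTIONS = "moments=biased_n;kurtosis=pearson_non_excess"


class MarkerError(ValueError):
    """A trial lacks the events or samples a marker needs."""


@dataclass(frozen=True)
class MarkerSet:
    ipd_m: float
    time_in_room_s: float
    path_length_m: float
    min_dist_m: float
    mean_dist_m: float
    dist_skew: float
    dist_kurtosis: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_ipd(trial: TrialLog, room: RoomConfig) -> float:
    """Euclidean avatar-to-NPC distance at the sample where the conversation starts.

    Uses the sample at — or nearest before — the conversation_start event.
    """
    if "conversation_start" not in trial.events:
        raise MarkerError(f"trial {trial.trial_id}: no conversation_start event")
    t0 = trial.events["conversation_start"]
    candidates = [s for s in trial.samples if s.t_ms <= t0]
    if not candidates:
        raise MarkerError(
            f"trial {trial.trial_id}: no sample at or before conversation_start"
        )
    s = max(candidates, key=lambda s: s.t_ms)
    npc = np.asarray(room.npc_position, dtype=float)
    return float(np.hypot(s.x_m - npc[0], s.y_m - npc[1]))


def compute_time_in_room(trial: TrialLog) -> float:
    """Seconds from trial start to trial end, conversation and rating included."""
    for ev in ("trial_start", "trial_end"):
        if ev not in trial.events:
            raise MarkerError(f"trial {trial.trial_id}: missing {ev} event")
    dt = (trial.events["trial_end"] - trial.events["trial_start"]) / 1000.0
    if dt == 0.0:
        warnings.warn(
            f"trial {trial.trial_id}: degenerate zero-duration trial", stacklevel=2
        )
    return dt


def compute_path_features(
    trial: TrialLog, room: RoomConfig
) -> tuple[float, float, float, float, float]:
    """(path_length, min_dist, mean_dist, skew, kurtosis) from post-conversation samples.

    Skew and kurtosis need at least 3 and 4 samples respectively and a
    nonzero distance variance; otherwise they come back as NaN with a
    warning, leaving the remaining features intact.
    """
    pts = np.array([[s.x_m, s.y_m] for s in trial.post_samples])
    if len(pts) < 2:
        warnings.warn(
            f"trial {trial.trial_id}: fewer than 2 post-conversation samples",
            stacklevel=2,
        )
        return (math.nan,) * 5
    npc = np.asarray(room.npc_position, dtype=float)
    path_length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    d = np.linalg.norm(pts - npc, axis=1)
    min_d = float(np.min(d))
    mean_d = float(np.mean(d))

    skew = kurt = math.nan
    m2 = float(np.var(d))  # biased, divide-by-n
    if m2 == 0.0:
        warnings.warn(
            f"trial {trial.trial_id}: zero distance variance; skew/kurtosis undefined",
            stacklevel=2,
        )
    else:
        if len(d) >= 3:
            skew = float(stats.skew(d, bias=True))
        if len(d) >= 4:
            kurt = float(stats.kurtosis(d, fisher=False, bias=True))
    return path_length, min_d, mean_d, skew, kurt


def compute_markers(trial: TrialLog, room: RoomConfig) -> MarkerSet:
    path_length, min_d, mean_d, skew, kurt = compute_path_features(trial, room)
    return MarkerSet(
        ipd_m=compute_ipd(trial, room),
        time_in_room_s=compute_time_in_room(trial),
        path_length_m=path_length,
        min_dist_m=min_d,
        mean_dist_m=mean_d,
        dist_skew=skew,
        dist_kurtosis=kurt,
    )


def aggregate_participant(trial_markers: Sequence[MarkerSet]) -> MarkerSet:
    """Per-marker arithmetic mean over the trials where the marker is defined.

    Missingness is handled per marker, not listwise: a trial with undefined
    kurtosis still contributes its path length.  A marker missing in every
    trial stays NaN (and the participant drops out of that marker's
    regression downstream).
    """
    if not trial_markers:
        raise MarkerError("cannot aggregate an empty trial list")
    out = {}
    for name in MARKER_NAMES:
        vals = np.array([getattr(m, name) for m in trial_markers], dtype=float)
        valid = vals[~np.isnan(vals)]
        out[name] = float(np.mean(valid)) if len(valid) else math.nan
    return MarkerSet(**out)


def extract_markers(
    cohort: Iterable[ParticipantRecord], room: RoomConfig, *, include_trials: bool = True
) -> pd.DataFrame:
    """Marker table: one row per trial plus a ``trial_id='mean'`` row per participant."""
    rows = []
    for rec in cohort:
        per_trial = []
        for trial in rec.trials:
            ms = compute_markers(trial, room)
            per_trial.append(ms)
            if include_trials:
                rows.append(
                    {"participant_id": rec.participant_id, "trial_id": str(trial.trial_id),
                     **ms.as_dict()}
                )
        if per_trial:
            rows.append(
                {"participant_id": rec.participant_id, "trial_id": "mean",
                 **aggregate_participant(per_trial).as_dict()}
            )
    df = pd.DataFrame(rows, columns=["participant_id", "trial_id", *MARKER_NAMES])
    df["conventions"] = ESTIMATOR_CONVENTIONS
    return df
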