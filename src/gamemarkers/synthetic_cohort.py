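"""Synthetic cohorts with the statistical structure the analysis assumes.

A standardized latent social-anxiety trait ``z`` drives everything a real
cohort would correlate: questionnaire answers (via a graded-response item
model) and avoidance behavior in the delivery task (stop distance when
initiating the conversation, and detour clearance when bypassing the NPC).

The movement model is an invention standing in for human steering: a
straight-line approach to the preferred interpersonal distance, a
stationary conversation dwell, then a quadratic Bezier bypass to the target
elevator whose lateral control point is solved so that the *sampled*
closest approach to the NPC equals the participant's preferred clearance.
Solving against the discrete 50 ms sample grid (rather than the continuous
curve) makes noise-free simulations exactly linear in the trait, which the
parameter-recovery tests exploit.

Trait-to-behavior effect sizes are calibrated so that, at the default
cohort size of 102, regressing the questionnaire total on a participant's
mean marker yields R^2 on the order of 0.10 — the magnitude the analysis
stage is designed to detect.  Most of the behavioral variance is therefore
*between-participant heterogeneity unrelated to the trait* (people differ
widely in baseline proxemics), not trial-to-trial jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .telemetry import (
    Emotion,
    Gender,
    ParticipantRecord,
    Phase,
    RoomConfig,
    SAMPLE_PERIOD_MS,
    Side,
    TrajectorySample,
    TrialLog,
)

__all__ = [
    "LsasItemParams",
    "SimulationConfig",
    "TrialSchedule",
    "make_schedule",
    "simulate_lsas",
    "simulate_lsas_totals",
    "simulate_trajectory",
    "simulate_cohort",
]

# Greek-letter team names; 20 distinct per schedule.
_TEAM_NAMES = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron", "pi", "rho",
    "sigma", "tau", "upsilon",
)

# Graded-response defaults, moment-matched so that totals over z ~ N(0,1)
# have mean 58.7 and SD 28.65 (the questionnaire's published 0-144 range
# with a strong common factor).  48 identical items, 3 ordered thresholds.
_GRM_A = 1.066556
_GRM_B = (-0.456875, 0.443125, 1.443125)


@dataclass(frozen=True)
class LsasItemParams:
    """Per-item discrimination and ordered thresholds for the 48 ratings."""

    a: np.ndarray = field(
        default_factory=lambda: np.full(48, _GRM_A)
    )  # (48,)
    b: np.ndarray = field(
        default_factory=lambda: np.tile(np.array(_GRM_B), (48, 1))
    )  # (48, 3)

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != (48,) or b.shape != (48, 3):
            raise ValueError("item parameters must have shapes (48,) and (48, 3)")
        if np.any(np.diff(b, axis=1) <= 0):
            raise ValueError("item thresholds must be strictly increasing (b1 < b2 < b3)")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 102
    seed: int = 0
    room: RoomConfig = field(default_factory=RoomConfig)
    walk_speed_mps: float = 3.0
    # preferred stop distance: d_stop = ipd_base + ipd_slope*z + person + trial noise
    ipd_base_m: float = 2.0
    ipd_slope_m: float = 0.6
    ipd_person_sd_m: float = 1.66
    ipd_noise_sd_m: float = 0.3
    # detour clearance past the NPC, same structure
    clearance_base_m: float = 1.5
    clearance_slope_m: float = 0.5
    clearance_person_sd_m: float = 1.38
    clearance_noise_sd_m: float = 0.25
    # correlation of the person-level (trait-independent) deviations of stop
    # distance and clearance: one shared "proxemic preference" factor —
    # people who stand far from strangers also walk wide around them
    proxemic_cor: float = 0.7
    # per-trial steering cap: the bypass clearance stays below this fraction
    # of the trial's stop distance, keeping the detour curve well-formed
    clearance_cap_frac: float = 0.9
    heading_noise_sd: float = 0.05  # radians per 50 ms step
    # lognormal dwell durations, parameterized by median seconds / sigma(log)
    conversation_median_s: float = 12.0
    conversation_log_sd: float = 0.3
    rating_median_s: float = 4.0
    rating_log_sd: float = 0.3
    lsas_item_params: LsasItemParams = field(default_factory=LsasItemParams)
    # demographics: age ~ round(Normal(37.5, 9.9)) clipped to [20, 65]
    age_mean: float = 37.5
    age_sd: float = 9.9
    age_range: tuple[int, int] = (20, 65)
    # woman / man / non_binary; 1% non-binary exercises the exclusion path
    gender_probs: tuple[float, float, float] = (0.38, 0.61, 0.01)
    # avatar-identification subscale targets (mean, sd) on the 0-4 scale
    pis_targets: dict = field(
        default_factory=lambda: {
            "sim": (3.015, 0.70),
            "emb": (2.65, 0.87),
            "wish": (2.27, 0.95),
        }
    )

    def __post_init__(self) -> None:
        for name in (
            "ipd_base_m", "ipd_person_sd_m", "ipd_noise_sd_m",
            "clearance_base_m", "clearance_person_sd_m", "clearance_noise_sd_m",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.walk_speed_mps <= 0:
            raise ValueError("walk_speed_mps must be > 0")
        if not -1.0 <= self.proxemic_cor <= 1.0:
            raise ValueError("proxemic_cor must lie in [-1, 1]")
        if not 0.0 < self.clearance_cap_frac < 1.0:
            raise ValueError("clearance_cap_frac must lie in (0, 1)")

    def noise_free(self) -> "SimulationConfig":
        """Copy with every stochastic behavioral term switched off."""
        return replace(
            self,
            ipd_person_sd_m=0.0,
            ipd_noise_sd_m=0.0,
            clearance_person_sd_m=0.0,
            clearance_noise_sd_m=0.0,
            heading_noise_sd=0.0,
        )


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered (elevator_side, npc_emotion, team_name) triples, 20 trials."""

    entries: tuple[tuple[Side, Emotion, str], ...]

    def __post_init__(self) -> None:
        if len(self.entries) != 20:
            raise ValueError("a schedule has exactly 20 trials")
        names = [e[2] for e in self.entries]
        if len(set(names)) != 20:
            raise ValueError("team names must be distinct")
        for side in Side:
            for emo in Emotion:
                k = sum(1 for s, e, _ in self.entries if s is side and e is emo)
                if k != 5:
                    raise ValueError(f"cell ({side.value}, {emo.value}) has {k} != 5 trials")


def make_schedule(rng: np.random.Generator) -> TrialSchedule:
    """Balanced 20-trial schedule: 5 per (side x emotion) cell, shuffled order."""
    cells = [(s, e) for s in Side for e in Emotion for _ in range(5)]
    perm = rng.permutation(len(cells))
    entries = tuple(
        (cells[j][0], cells[j][1], _TEAM_NAMES[i]) for i, j in enumerate(perm)
    )
    return TrialSchedule(entries)


# ---------------------------------------------------------------------------
# questionnaires

def simulate_lsas(
    latent_sa: float, params: LsasItemParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw 24x2 ordinal ratings (fear, avoidance) from the graded-response model.

    A single uniform per item compared against the descending exceedance
    probabilities P(rating >= k | z) = logistic(a*(z - b_k)) yields a proper
    draw: the rating is the number of thresholds the uniform clears.
    """
    p = expit(params.a[:, None] * (latent_sa - params.b))  # (48, 3)
    u = rng.random(48)
    ratings = (u[:, None] < p).sum(axis=1)  # in {0..3}
    return ratings.reshape(24, 2)


def simulate_lsas_totals(
    latent_sa: np.ndarray, params: LsasItemParams, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized questionnaire totals for an array of latent traits."""
    z = np.asarray(latent_sa, dtype=float)
    p = expit(params.a[None, :, None] * (z[:, None, None] - params.b[None, :, :]))
    u = rng.random((z.size, 48))
    return (u[:, :, None] < p).sum(axis=(1, 2))


def _simulate_pis(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, list[int]]:
    from .telemetry import PIS_ITEMS

    out: dict[str, list[int]] = {}
    for sub, n_items in PIS_ITEMS.items():
        mean, sd = cfg.pis_targets[sub]
        person = rng.normal(mean, sd)
        items = np.clip(np.rint(person + rng.normal(0, 0.5, n_items)), 0, 4)
        out[sub] = [int(v) for v in items]
    return out


# ---------------------------------------------------------------------------
# trajectory model

_BEZIER_DENSE = 320
_T_GRID = np.linspace(0.0, 1.0, _BEZIER_DENSE)
_BEZIER_BASIS = np.column_stack(
    [(1 - _T_GRID) ** 2, 2 * _T_GRID * (1 - _T_GRID), _T_GRID ** 2]
)


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    return _BEZIER_BASIS @ np.array([p0, p1, p2])


def _resample_equal_steps(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a dense polyline at equal arc-length increments.

    The final point is always included (last step may be shorter), matching a
    walker that covers ``step`` meters per sample period and then stops at
    the door.
    """
    d = np.diff(points, axis=0)
    seg = np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n_full = int(total / step)
    targets = np.arange(1, n_full + 1) * step
    if total - (n_full * step) > 1e-12:
        targets = np.concatenate([targets, [total]])
    x = np.interp(targets, s, points[:, 0])
    y = np.interp(targets, s, points[:, 1])
    return np.column_stack(
        [np.concatenate([[points[0, 0]], x]), np.concatenate([[points[0, 1]], y])]
    )


def _sampled_min_distance(
    stop: np.ndarray, ctrl: np.ndarray, door: np.ndarray, npc: np.ndarray, step: float
) -> float:
    pts = _resample_equal_steps(_bezier(stop, ctrl, door), step)
    dx = pts[:, 0] - npc[0]
    dy = pts[:, 1] - npc[1]
    return float(np.sqrt(np.min(dx * dx + dy * dy)))


def _solve_bypass(
    stop: np.ndarray,
    door: np.ndarray,
    npc: np.ndarray,
    clearance: float,
    side_sign: float,
    step: float,
    w_tol: float = 1e-11,
) -> np.ndarray:
    """Return waypoints whose sampled minimum NPC distance equals ``clearance``.

    The control point sits level with the NPC at lateral offset ``w`` toward
    the target side; the sampled closest approach is monotone in ``w``, so a
    bisection pins it to the requested clearance.  ``w_tol`` is the bracket
    width at which the bisection stops; the tight default matters only for
    noise-free runs, where the sampled minimum must be exactly linear in
    the trait.
    """
    def f(w: float) -> float:
        ctrl = npc + np.array([side_sign * w, 0.0])
        return _sampled_min_distance(stop, ctrl, door, npc, step)

    lo, hi = 0.0, 4.0
    # grow hi until the sampled minimum exceeds the target (saturates at the
    # endpoint distance, which the caller guarantees is above the target)
    while f(hi) < clearance and hi < 64.0:
        hi *= 2.0
    if f(lo) >= clearance:
        w = lo
    else:
        while hi - lo > w_tol:
            mid = 0.5 * (lo + hi)
            if f(mid) < clearance:
                lo = mid
            else:
                hi = mid
        w = hi
    ctrl = npc + np.array([side_sign * w, 0.0])
    return _resample_equal_steps(_bezier(stop, ctrl, door), step)


def _apply_heading_noise(
    waypoints: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Pursuit walk along the reference waypoints with per-step heading noise.

    Each step aims at the next reference waypoint and is rotated by a
    N(0, sd) heading error; with sd = 0 the reference path is reproduced
    exactly.  The final position snaps to the door.
    """
    if sd == 0.0 or len(waypoints) < 2:
        return waypoints.copy()
    out = np.empty_like(waypoints)
    out[0] = waypoints[0]
    px, py = float(waypoints[0, 0]), float(waypoints[0, 1])
    noise = rng.normal(0.0, sd, len(waypoints) - 1)
    for i in range(1, len(waypoints)):
        vx = waypoints[i, 0] - px
        vy = waypoints[i, 1] - py
        r = math.hypot(vx, vy)
        if r > 0.0:
            theta = math.atan2(vy, vx) + noise[i - 1]
            px += r * math.cos(theta)
            py += r * math.sin(theta)
        out[i, 0] = px
        out[i, 1] = py
    out[-1] = waypoints[-1]
    return out


_IPD_CLAMP = (0.5, 8.0)
_CLEARANCE_MIN = 0.3


def simulate_trajectory(
    latent_sa: float,
    trial_id: int,
    entry: tuple[Side, Emotion, str],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    *,
    ipd_person_m: float | None = None,
    clearance_person_m: float | None = None,
) -> TrialLog:
    """Simulate one delivery trial for a participant with trait ``latent_sa``.

    ``ipd_person_m`` / ``clearance_person_m`` carry the participant-level
    preferred distances across trials; when omitted they collapse to the
    population line (base + slope * z).
    """
    side, emotion, team = entry
    room = cfg.room
    npc = np.asarray(room.npc_position, dtype=float)
    spawn = np.asarray(room.spawn_position, dtype=float)
    door = np.asarray(room.elevator(side), dtype=float)
    step = cfg.walk_speed_mps * SAMPLE_PERIOD_MS / 1000.0

    if np.linalg.norm(door - npc) <= _CLEARANCE_MIN:
        raise ValueError("degenerate geometry: elevator door inside the clearance clamp radius")

    if ipd_person_m is None:
        ipd_person_m = cfg.ipd_base_m + cfg.ipd_slope_m * latent_sa
    if clearance_person_m is None:
        clearance_person_m = cfg.clearance_base_m + cfg.clearance_slope_m * latent_sa

    d_stop = ipd_person_m + (
        rng.normal(0.0, cfg.ipd_noise_sd_m) if cfg.ipd_noise_sd_m else 0.0
    )
    d_stop = float(np.clip(d_stop, *_IPD_CLAMP))
    clearance = clearance_person_m + (
        rng.normal(0.0, cfg.clearance_noise_sd_m) if cfg.clearance_noise_sd_m else 0.0
    )
    # the bypass starts at distance d_stop, so the sampled minimum can never
    # exceed it; the steering cap also keeps the detour curve away from the
    # degenerate clearance ~ d_stop regime where the bulge explodes
    cap = min(cfg.clearance_cap_frac * d_stop, d_stop - 1e-6)
    clearance = float(np.clip(clearance, _CLEARANCE_MIN, max(cap, _CLEARANCE_MIN)))

    approach_dir = (npc - spawn) / np.linalg.norm(npc - spawn)
    stop = npc - approach_dir * d_stop
    approach_dist = float(np.linalg.norm(stop - spawn))

    # approach phase: 50 ms grid from spawn, then the stop point itself
    t_conv_start = int(np.ceil(approach_dist / cfg.walk_speed_mps * 1000.0))
    t_conv_start = max(t_conv_start, SAMPLE_PERIOD_MS)
    ts = np.arange(0, t_conv_start, SAMPLE_PERIOD_MS)
    frac = (
        np.minimum(ts * (cfg.walk_speed_mps / 1000.0) / approach_dist, 1.0)
        if approach_dist
        else np.ones_like(ts, dtype=float)
    )
    approach_pts = spawn + frac[:, None] * (stop - spawn)
    samples: list[TrajectorySample] = [
        TrajectorySample(int(t), x, y, Phase.APPROACH)
        for t, (x, y) in zip(ts, approach_pts.tolist())
    ]
    samples.append(
        TrajectorySample(t_conv_start, float(stop[0]), float(stop[1]), Phase.APPROACH)
    )

    conv_dwell = rng.lognormal(np.log(cfg.conversation_median_s), cfg.conversation_log_sd)
    t_conv_end = t_conv_start + max(int(round(conv_dwell * 1000.0)), SAMPLE_PERIOD_MS)

    side_sign = -1.0 if side is Side.LEFT else 1.0
    noise_free = (
        cfg.ipd_person_sd_m == 0.0 and cfg.ipd_noise_sd_m == 0.0
        and cfg.clearance_person_sd_m == 0.0 and cfg.clearance_noise_sd_m == 0.0
        and cfg.heading_noise_sd == 0.0
    )
    waypoints = _solve_bypass(
        stop, door, npc, clearance, side_sign, step,
        w_tol=1e-11 if noise_free else 3e-5,
    )
    walked = _apply_heading_noise(waypoints, cfg.heading_noise_sd, rng)
    samples.extend(
        TrajectorySample(t_conv_end + i * SAMPLE_PERIOD_MS, x, y, Phase.POST_CONVERSATION)
        for i, (x, y) in enumerate(walked.tolist())
    )
    t_elev = t_conv_end + (len(walked) - 1) * SAMPLE_PERIOD_MS

    rating_dwell = rng.lognormal(np.log(cfg.rating_median_s), cfg.rating_log_sd)
    t_end = t_elev + max(int(round(rating_dwell * 1000.0)), SAMPLE_PERIOD_MS)

    return TrialLog(
        trial_id=trial_id,
        elevator_side=side,
        npc_emotion=emotion,
        team_name=team,
        events={
            "trial_start": 0,
            "conversation_start": t_conv_start,
            "conversation_end": t_conv_end,
            "elevator_selected": t_elev,
            "trial_end": t_end,
        },
        samples=samples,
    )


# ---------------------------------------------------------------------------
# cohort assembly

def _participant_rng(seed: int, index: int) -> np.random.Generator:
    # participant i is reproducible independent of cohort size
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def simulate_participant(
    index: int, cfg: SimulationConfig
) -> ParticipantRecord:
    rng = _participant_rng(cfg.seed, index)
    z = float(rng.standard_normal())
    age = int(np.clip(np.rint(rng.normal(cfg.age_mean, cfg.age_sd)), *cfg.age_range))
    gender = [Gender.WOMAN, Gender.MAN, Gender.NON_BINARY][
        rng.choice(3, p=np.asarray(cfg.gender_probs) / np.sum(cfg.gender_probs))
    ]
    lsas = simulate_lsas(z, cfg.lsas_item_params, rng)
    pis = _simulate_pis(cfg, rng)

    # person-level proxemic deviations share a common factor (proxemic_cor)
    rho = cfg.proxemic_cor
    common, e1, e2 = rng.standard_normal(3)
    mix = math.sqrt(max(1.0 - rho * rho, 0.0))
    ipd_person = (
        cfg.ipd_base_m + cfg.ipd_slope_m * z
        + cfg.ipd_person_sd_m * (rho * common + mix * e1)
    )
    clr_person = (
        cfg.clearance_base_m + cfg.clearance_slope_m * z
        + cfg.clearance_person_sd_m * (rho * common + mix * e2)
    )

    schedule = make_schedule(rng)
    trials = [
        simulate_trajectory(
            z, tid, entry, cfg, rng,
            ipd_person_m=ipd_person, clearance_person_m=clr_person,
        )
        for tid, entry in enumerate(schedule.entries, start=1)
    ]
    return ParticipantRecord(
        participant_id=f"P{index:04d}",
        age=age,
        gender=gender,
        lsas_responses=lsas,
        pis_responses=pis,
        latent_sa=z,
        trials=trials,
    )


def simulate_cohort(cfg: SimulationConfig) -> list[ParticipantRecord]:
    """Simulate ``cfg.n_participants`` records, fully reproducible from the seed."""
    return [simulate_participant(i, cfg) for i in range(cfg.n_participants)]
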