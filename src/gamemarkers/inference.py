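"""Two-stage statistics for the marker analysis.

Stage 1 checks the task design: a repeated-measures multivariate test asks
whether the NPC's emotion or the elevator side shifted any marker.  For the
2 x 2 within-participant design each within effect reduces to a single
contrast score per participant and marker; regressing the contrast-score
matrix on an intercept plus covariates (age, gender code) and testing the
intercept gives the classical multivariate statistics — Pillai's trace,
Wilks' Lambda, Hotelling's trace, and Roy's largest root — computed from
the eigenvalues of E^-1 H (hypothesis and error SSCP matrices).  For a
rank-1 hypothesis the four are deterministic functions of one another
(Pillai + Wilks = 1, Hotelling = Roy = Pillai/(1 - Pillai)) and share one
exact F.

Stage 2 asks whether each marker predicts trait social anxiety: one
hierarchical OLS per marker with age and dummy-coded gender (-1 = man,
+1 = woman; non-binary participants excluded from the inferential models
only) in the first block and the participant-mean marker in the second,
questionnaire total as the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .markers import MARKER_NAMES, ESTIMATOR_CONVENTIONS, aggregate_participant, compute_markers
from .questionnaires import score_lsas
from .telemetry import Emotion, Gender, ParticipantRecord, RoomConfig, Side

__all__ = [
    "MultivariateTestResult",
    "HierarchicalRegressionResult",
    "AnalysisReport",
    "multivariate_stats_from_eigs",
    "multivariate_linear_test",
    "within_subject_multivariate_test",
    "hierarchical_regression",
    "cell_marker_means",
    "run_full_analysis",
]

GENDER_CODE = {Gender.MAN: -1.0, Gender.WOMAN: 1.0}

STATISTIC_NAMES = ("pillai", "wilks", "hotelling", "roy")


@dataclass(frozen=True)
class MultivariateTestResult:
    effect: str
    statistic: str  # one of STATISTIC_NAMES
    value: float
    f_stat: float
    df_hypothesis: float
    df_error: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class HierarchicalRegressionResult:
    marker: str
    b_unstandardized: float
    beta_standardized: float
    p_predictor: float
    r_model: float
    r_sq_model: float
    p_model: float
    n_used: int
    r_sq_block1: float
    p_block1: float
    r_sq_change: float


class RankError(np.linalg.LinAlgError):
    """Error SSCP is singular: more response variables than error df."""


def multivariate_stats_from_eigs(
    eigs: np.ndarray, p: int, q_h: int, df_e: int, effect: str = ""
) -> list[MultivariateTestResult]:
    """The four multivariate statistics and their F approximations.

    ``eigs`` are the eigenvalues of E^-1 H, ``p`` the number of response
    variables, ``q_h`` the hypothesis df, ``df_e`` the error df.  The F for
    Roy's largest root is the usual upper bound.  Partial eta squared uses
    the per-statistic definitions, which all coincide with Pillai's trace
    when min(p, q_h) = 1.
    """
    lam = np.sort(np.clip(np.real(eigs), 0.0, None))[::-1]
    s = min(p, q_h)
    m = (abs(p - q_h) - 1) / 2.0
    n0 = (df_e - p - 1) / 2.0

    V = float(np.sum(lam / (1 + lam)))
    W = float(np.prod(1.0 / (1 + lam)))
    T = float(np.sum(lam))
    R = float(lam[0]) if len(lam) else 0.0

    results = []

    # Pillai
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n0 + s + 1)
    F = (df2 * V) / (df1 * (s - V)) if V < s else math.inf
    results.append(
        MultivariateTestResult(effect, "pillai", V, F, df1, df2,
                               float(stats.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0,
                               V / s)
    )

    # Wilks (Rao's F)
    pq = p * q_h
    denom = p * p + q_h * q_h - 5
    t = math.sqrt((pq * pq - 4) / denom) if denom > 0 else 1.0
    w = df_e + q_h - (p + q_h + 1) / 2.0
    df2_w = w * t - (pq - 2) / 2.0
    Wt = W ** (1.0 / t) if W > 0 else 0.0
    F_w = ((1 - Wt) / Wt) * (df2_w / pq) if Wt > 0 else math.inf
    results.append(
        MultivariateTestResult(effect, "wilks", W, F_w, pq, df2_w,
                               float(stats.f.sf(F_w, pq, df2_w)) if math.isfinite(F_w) else 0.0,
                               1.0 - (W ** (1.0 / s) if W > 0 else 0.0))
    )

    # Hotelling-Lawley
    df1_h = s * (2 * m + s + 1)
    df2_h = 2 * (s * n0 + 1)
    F_h = (T * df2_h) / (s * s * (2 * m + s + 1)) if df1_h > 0 else math.nan
    eta_h = (T / s) / (T / s + 1)
    results.append(
        MultivariateTestResult(effect, "hotelling", T, F_h, df1_h, df2_h,
                               float(stats.f.sf(F_h, df1_h, df2_h)), eta_h)
    )

    # Roy (upper-bound F)
    r = max(p, q_h)
    df2_r = df_e - r + q_h
    F_r = R * df2_r / r
    results.append(
        MultivariateTestResult(effect, "roy", R, F_r, r, df2_r,
                               float(stats.f.sf(F_r, r, df2_r)), R / (1 + R))
    )
    return results


def multivariate_linear_test(
    Y: np.ndarray, X: np.ndarray, L: np.ndarray, effect: str = ""
) -> list[MultivariateTestResult]:
    """Test L @ B = 0 in the multivariate linear model Y = X B + U.

    H = (LB)' (L (X'X)^-1 L')^-1 (LB); E is the residual SSCP; the four
    statistics come from the eigenvalues of E^-1 H.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    L = np.atleast_2d(np.asarray(L, dtype=float))
    n, p = Y.shape
    q = X.shape[1]
    df_e = n - np.linalg.matrix_rank(X)
    if df_e < p:
        raise RankError(
            f"error df ({df_e}) < number of response variables ({p}); "
            "reduce the marker set or add participants"
        )
    XtX = X.T @ X
    B = np.linalg.solve(XtX, X.T @ Y)
    resid = Y - X @ B
    E = resid.T @ resid
    LB = L @ B
    M = L @ np.linalg.solve(XtX, L.T)
    H = LB.T @ np.linalg.solve(M, LB)
    eigs = np.linalg.eigvals(np.linalg.solve(E, H))
    return multivariate_stats_from_eigs(eigs, p=p, q_h=L.shape[0], df_e=df_e, effect=effect)


def within_subject_multivariate_test(
    cell_means: np.ndarray,
    age: np.ndarray,
    gender_code: np.ndarray,
    *,
    center_covariates: bool = True,
) -> list[MultivariateTestResult]:
    """Design check for the 2 x 2 within-participant layout.

    ``cell_means`` has shape (n, 2, 2, p) with axes (participant,
    side[left, right], emotion[friendly, angry], marker); only participants
    with all four cells present belong here.  Within effects (emotion,
    side) are per-participant contrast scores tested as the intercept of a
    regression on the covariates; between effects (intercept, age, gender)
    are tested on the cell-averaged scores.  Covariates are mean-centered by
    default so the within-effect intercepts refer to the covariate mean.
    """
    cm = np.asarray(cell_means, dtype=float)
    if cm.ndim != 4 or cm.shape[1:3] != (2, 2):
        raise ValueError("cell_means must have shape (n, 2, 2, n_markers)")
    n = cm.shape[0]
    age = np.asarray(age, dtype=float)
    g = np.asarray(gender_code, dtype=float)
    if center_covariates:
        age = age - age.mean()
        g = g - g.mean()
    X = np.column_stack([np.ones(n), age, g])

    emotion_scores = cm[:, :, 1, :].mean(axis=1) - cm[:, :, 0, :].mean(axis=1)
    side_scores = cm[:, 1, :, :].mean(axis=1) - cm[:, 0, :, :].mean(axis=1)
    avg_scores = cm.mean(axis=(1, 2))

    L_int = np.array([[1.0, 0.0, 0.0]])
    out: list[MultivariateTestResult] = []
    out += multivariate_linear_test(avg_scores, X, L_int, effect="intercept")
    out += multivariate_linear_test(avg_scores, X, [[0.0, 1.0, 0.0]], effect="age")
    out += multivariate_linear_test(avg_scores, X, [[0.0, 0.0, 1.0]], effect="gender")
    out += multivariate_linear_test(emotion_scores, X, L_int, effect="emotion")
    out += multivariate_linear_test(side_scores, X, L_int, effect="side")
    return out


def hierarchical_regression(
    marker_means: np.ndarray,
    lsas_total: np.ndarray,
    age: np.ndarray,
    gender_code: np.ndarray,
    marker_name: str = "marker",
) -> HierarchicalRegressionResult:
    """One covariate-blocked OLS: block 1 age + gender, block 2 adds the marker.

    beta is b * sd(marker) / sd(outcome); the model p-value is the
    full-model (block 2) F test.
    """
    x = np.asarray(marker_means, dtype=float)
    y = np.asarray(lsas_total, dtype=float)
    age = np.asarray(age, dtype=float)
    g = np.asarray(gender_code, dtype=float)
    n = len(y)
    if n <= 4:
        raise ValueError(f"insufficient df: n = {n} <= 4")
    if np.std(x) == 0.0:
        raise ValueError(f"marker {marker_name!r} has zero variance")

    X1 = sm.add_constant(np.column_stack([age, g]))
    X2 = sm.add_constant(np.column_stack([age, g, x]))
    fit1 = sm.OLS(y, X1).fit()
    fit2 = sm.OLS(y, X2).fit()

    b = float(fit2.params[3])
    beta = b * float(np.std(x, ddof=1) / np.std(y, ddof=1))
    r_sq = float(fit2.rsquared)
    return HierarchicalRegressionResult(
        marker=marker_name,
        b_unstandardized=b,
        beta_standardized=beta,
        p_predictor=float(fit2.pvalues[3]),
        r_model=math.sqrt(max(r_sq, 0.0)),
        r_sq_model=r_sq,
        p_model=float(fit2.f_pvalue),
        n_used=n,
        r_sq_block1=float(fit1.rsquared),
        p_block1=float(fit1.f_pvalue),
        r_sq_change=r_sq - float(fit1.rsquared),
    )


# ---------------------------------------------------------------------------
# cohort-level orchestration

def _trial_markers(rec: ParticipantRecord, room: RoomConfig):
    return [(t, compute_markers(t, room)) for t in rec.trials]


def cell_marker_means(
    cohort: Sequence[ParticipantRecord],
    room: RoomConfig,
    *,
    precomputed: dict[str, list] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Per-participant marker means in each (side, emotion) design cell.

    Returns an (n, 2, 2, 7) array with axes (participant, side[left, right],
    emotion[friendly, angry], marker) and the participant ids included;
    participants missing any cell are dropped.  ``precomputed`` can carry
    already-extracted ``[(trial, MarkerSet), ...]`` lists per participant.
    """
    sides = (Side.LEFT, Side.RIGHT)
    emotions = (Emotion.FRIENDLY, Emotion.ANGRY)
    arrs, ids = [], []
    for rec in cohort:
        pairs = (
            precomputed[rec.participant_id]
            if precomputed is not None
            else _trial_markers(rec, room)
        )
        cells = np.full((2, 2, len(MARKER_NAMES)), np.nan)
        ok = True
        for i, side in enumerate(sides):
            for j, emo in enumerate(emotions):
                cell = [
                    ms for t, ms in pairs
                    if t.elevator_side is side and t.npc_emotion is emo
                ]
                if not cell:
                    ok = False
                    continue
                ms = aggregate_participant(cell)
                cells[i, j] = [getattr(ms, name) for name in MARKER_NAMES]
        if ok and not np.any(np.isnan(cells)):
            arrs.append(cells)
            ids.append(rec.participant_id)
    if not arrs:
        return np.empty((0, 2, 2, len(MARKER_NAMES))), []
    return np.stack(arrs), ids


@dataclass
class AnalysisReport:
    mancova: pd.DataFrame
    regressions: pd.DataFrame
    n_participants: int
    n_regression: int
    exclusions: dict[str, list[str]] = field(default_factory=dict)
    conventions: str = ESTIMATOR_CONVENTIONS
    holm_corrected: bool = False


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def run_full_analysis(
    cohort: Sequence[ParticipantRecord],
    room: RoomConfig | None = None,
    *,
    markers: Sequence[str] = MARKER_NAMES,
    holm: bool = False,
) -> AnalysisReport:
    """Run both stages on a scored cohort and return tidy result tables.

    Excludes incomplete participants from everything and non-binary
    participants from the inferential models (they stay in descriptives);
    participants with an undefined mean for a marker drop out of that
    marker's regression only.
    """
    room = room or RoomConfig()
    exclusions: dict[str, list[str]] = {"incomplete": [], "non_binary": [], "missing_marker": []}

    complete = []
    for rec in cohort:
        if rec.complete:
            complete.append(rec)
        else:
            exclusions["incomplete"].append(rec.participant_id)

    per_trial = {rec.participant_id: _trial_markers(rec, room) for rec in complete}

    # stage 1: design check on participants with all four cells
    cm, cm_ids = cell_marker_means(complete, room, precomputed=per_trial)
    id_to_rec = {r.participant_id: r for r in complete}
    keep = [
        pid for pid in cm_ids if id_to_rec[pid].gender in GENDER_CODE
    ]
    keep_mask = np.array([pid in set(keep) for pid in cm_ids])
    mancova_rows: list[dict] = []
    if keep_mask.sum() > len(markers) + 3:
        midx = [MARKER_NAMES.index(m) for m in markers]
        cm_k = cm[keep_mask][:, :, :, midx]
        age = np.array([id_to_rec[pid].age for pid in keep])
        gcode = np.array([GENDER_CODE[id_to_rec[pid].gender] for pid in keep])
        for res in within_subject_multivariate_test(cm_k, age, gcode):
            mancova_rows.append(
                {
                    "effect": res.effect,
                    "statistic": res.statistic,
                    "value": res.value,
                    "F": res.f_stat,
                    "df_hypothesis": res.df_hypothesis,
                    "df_error": res.df_error,
                    "p": res.p,
                    "partial_eta_sq": res.partial_eta_sq,
                }
            )
    mancova = pd.DataFrame(
        mancova_rows,
        columns=["effect", "statistic", "value", "F",
                 "df_hypothesis", "df_error", "p", "partial_eta_sq"],
    )

    # stage 2: per-marker hierarchical regression
    rows = []
    reg_n = 0
    for rec in complete:
        if rec.gender not in GENDER_CODE:
            exclusions["non_binary"].append(rec.participant_id)
    eligible = [r for r in complete if r.gender in GENDER_CODE and r.lsas_responses is not None]
    if eligible:
        means = {
            r.participant_id: aggregate_participant(
                [ms for _, ms in per_trial[r.participant_id]]
            )
            for r in eligible
        }
        totals = {r.participant_id: score_lsas(r.lsas_responses).total for r in eligible}
        for name in markers:
            ids = [
                r.participant_id
                for r in eligible
                if not math.isnan(getattr(means[r.participant_id], name))
            ]
            dropped = [r.participant_id for r in eligible if r.participant_id not in set(ids)]
            exclusions["missing_marker"].extend(f"{name}:{pid}" for pid in dropped)
            if len(ids) <= 4:
                continue
            res = hierarchical_regression(
                np.array([getattr(means[pid], name) for pid in ids]),
                np.array([totals[pid] for pid in ids]),
                np.array([id_to_rec[pid].age for pid in ids]),
                np.array([GENDER_CODE[id_to_rec[pid].gender] for pid in ids]),
                marker_name=name,
            )
            reg_n = max(reg_n, res.n_used)
            rows.append(
                {
                    "marker": name,
                    "B": res.b_unstandardized,
                    "beta": res.beta_standardized,
                    "p_predictor": res.p_predictor,
                    "R": res.r_model,
                    "R_sq": res.r_sq_model,
                    "p_model": res.p_model,
                    "n_used": res.n_used,
                    "R_sq_block1": res.r_sq_block1,
                    "p_block1": res.p_block1,
                    "R_sq_change": res.r_sq_change,
                }
            )
    regressions = pd.DataFrame(
        rows,
        columns=["marker", "B", "beta", "p_predictor", "R", "R_sq", "p_model",
                 "n_used", "R_sq_block1", "p_block1", "R_sq_change"],
    )
    if holm and len(regressions):
        regressions["p_predictor_holm"] = _holm(regressions["p_predictor"].to_numpy())

    return AnalysisReport(
        mancova=mancova,
        regressions=regressions,
        n_participants=len(complete),
        n_regression=reg_n,
        exclusions=exclusions,
        holm_corrected=holm,
    )
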