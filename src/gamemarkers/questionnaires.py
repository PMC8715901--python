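"""Scoring for the social-anxiety and avatar-identification questionnaires.

The Liebowitz Social Anxiety Scale (LSAS) presents 24 social situations,
each rated 0-3 for fear and 0-3 for avoidance; the 48 ratings sum to a
0-144 total.  Published cutoffs: a total of 30 separates non-anxious from
anxious respondents and 60 marks high risk of generalized social anxiety
(both applied inclusively here: total >= cutoff falls in the higher band).
The 24 situations split into 11 social-interaction items and 13
public-performance items.

The Player Identification Scale (PIS) subscales (similarity, embodied,
wishful identification) are item means on their 0-4 agreement scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LsasCategory",
    "LsasResult",
    "ScoringError",
    "SOCIAL_INTERACTION_ITEMS",
    "PERFORMANCE_ITEMS",
    "score_lsas",
    "score_pis",
    "cronbach_alpha",
]

# Canonical instrument assignment (1-based item numbers).
SOCIAL_INTERACTION_ITEMS = (5, 7, 10, 11, 12, 15, 18, 19, 22, 23, 24)
PERFORMANCE_ITEMS = tuple(
    i for i in range(1, 25) if i not in SOCIAL_INTERACTION_ITEMS
)

ANXIOUS_CUTOFF = 30
GENERALIZED_CUTOFF = 60


class ScoringError(ValueError):
    """A response is missing or out of range; message names the item."""


class LsasCategory(str, enum.Enum):
    NON_ANXIOUS = "non_anxious"
    ANXIOUS = "anxious"
    HIGH_RISK_GENERALIZED = "high_risk_generalized"


@dataclass(frozen=True)
class LsasResult:
    total: int
    fear_sum: int
    avoidance_sum: int
    social_interaction_sum: int
    performance_sum: int
    category: LsasCategory


def classify_lsas(total: int) -> LsasCategory:
    if total >= GENERALIZED_CUTOFF:
        return LsasCategory.HIGH_RISK_GENERALIZED
    if total >= ANXIOUS_CUTOFF:
        return LsasCategory.ANXIOUS
    return LsasCategory.NON_ANXIOUS


def score_lsas(responses) -> LsasResult:
    """Score a (24, 2) array of (fear, avoidance) ratings, each in {0,1,2,3}."""
    arr = np.asarray(responses)
    if arr.shape != (24, 2):
        raise ScoringError(f"expected 24x2 ratings, got shape {arr.shape}")
    if np.any(np.isnan(arr.astype(float))):
        i, j = np.argwhere(np.isnan(arr.astype(float)))[0]
        raise ScoringError(
            f"item {i + 1} ({'fear' if j == 0 else 'avoidance'}): missing rating"
        )
    arr = arr.astype(int)
    bad = np.argwhere((arr < 0) | (arr > 3))
    if len(bad):
        i, j = bad[0]
        raise ScoringError(
            f"item {i + 1} ({'fear' if j == 0 else 'avoidance'}): "
            f"rating {arr[i, j]} outside 0-3"
        )
    fear = int(arr[:, 0].sum())
    avoid = int(arr[:, 1].sum())
    total = fear + avoid
    si = int(sum(arr[i - 1].sum() for i in SOCIAL_INTERACTION_ITEMS))
    perf = int(sum(arr[i - 1].sum() for i in PERFORMANCE_ITEMS))
    return LsasResult(
        total=total,
        fear_sum=fear,
        avoidance_sum=avoid,
        social_interaction_sum=si,
        performance_sum=perf,
        category=classify_lsas(total),
    )


def score_pis(responses: dict[str, list[int]]) -> dict[str, float]:
    """Per-subscale arithmetic means of 0-4 agreement ratings."""
    out: dict[str, float] = {}
    for sub, vals in responses.items():
        if not vals:
            raise ScoringError(f"subscale {sub!r}: no item responses")
        arr = np.asarray(vals, dtype=float)
        if np.any((arr < 0) | (arr > 4)):
            raise ScoringError(f"subscale {sub!r}: rating outside 0-4")
        out[sub] = float(arr.mean())
    return out


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / variance of sums).

    Rows are respondents, columns items; unbiased (n-1) variances.  Returns
    NaN when the total score has zero variance (alpha undefined).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 respondents and 2 items")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        return math.nan
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
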