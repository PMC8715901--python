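"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: explicit
Python loops and textbook formulas only.
"""

import math

from gamemarkers.telemetry import Phase


def brute_force_markers(trial, room):
    """Recompute all seven markers from raw samples with explicit loops."""
    nx, ny = room.npc_position
    post = [s for s in trial.samples if s.phase is Phase.POST_CONVERSATION]
    path = 0.0
    for a, b in zip(post, post[1:]):
        path += math.sqrt((b.x_m - a.x_m) ** 2 + (b.y_m - a.y_m) ** 2)
    d = [math.sqrt((s.x_m - nx) ** 2 + (s.y_m - ny) ** 2) for s in post]
    n = len(d)
    mean_d = sum(d) / n
    m2 = sum((x - mean_d) ** 2 for x in d) / n
    m3 = sum((x - mean_d) ** 3 for x in d) / n
    m4 = sum((x - mean_d) ** 4 for x in d) / n
    skew = m3 / m2**1.5 if m2 > 0 and n >= 3 else math.nan
    kurt = m4 / m2**2 if m2 > 0 and n >= 4 else math.nan
    t0 = trial.events["conversation_start"]
    before = [s for s in trial.samples if s.t_ms <= t0]
    sb = max(before, key=lambda s: s.t_ms)
    ipd = math.sqrt((sb.x_m - nx) ** 2 + (sb.y_m - ny) ** 2)
    return {
        "ipd_m": ipd,
        "time_in_room_s": (trial.events["trial_end"] - trial.events["trial_start"]) / 1000,
        "path_length_m": path,
        "min_dist_m": min(d),
        "mean_dist_m": mean_d,
        "dist_skew": skew,
        "dist_kurtosis": kurt,
    }
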