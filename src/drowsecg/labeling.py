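"""Ground-truth labels: behavioral drowsiness score/level and crash proximity.

Two independent schemes, mirroring the study design:

* a descriptive behavioral score S = 0.40·PERCLOS + 0.25·Yawn + 0.20·Blink +
  0.15·Posture over [0,1]-scaled camera-derived indicators, bucketed into
  Alert / Light / Moderate / Severe; and
* the evaluation label, a binary crash-proximity flag: a window is positive
  iff it ends within 60 s before a crash.  This label is a pure function of
  window times and crash times — no physiological or behavioral feature can
  leak into it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DrowsecgError

SCORE_WEIGHTS = {"perclos": 0.40, "yawn": 0.25, "blink": 0.20, "posture": 0.15}
LEVEL_THRESHOLDS = {"light": 0.25, "moderate": 0.40, "severe": 0.60}
CRASH_HORIZON_S = 60.0

LEVELS = ["Alert", "Light", "Moderate", "Severe"]


@dataclass
class IndicatorScaling:
    """Maps from raw indicator units to the [0,1] inputs of the score.

    PERCLOS is already a fraction.  Yawn and blink frequencies pass through
    saturating maps f/(f+f0) with half-saturation at 3 yawns/min and 30
    blinks/min; posture is head-pose variance relative to a reference,
    clipped at 1.  These maps are this package's reconstruction (the score's
    published form does not fix them) and are config-exposed.
    """

    yawn_half_per_min: float = 3.0
    blink_half_per_min: float = 30.0
    head_var_ref: float = 25.0

    def scale_yawn(self, freq_per_min):
        f = np.asarray(freq_per_min, dtype=float)
        return f / (f + self.yawn_half_per_min)

    def scale_blink(self, freq_per_min):
        f = np.asarray(freq_per_min, dtype=float)
        return f / (f + self.blink_half_per_min)

    def scale_posture(self, head_var):
        return np.minimum(np.asarray(head_var, dtype=float) / self.head_var_ref, 1.0)


def behavioral_score(perclos, yawn, blink, posture):
    """Weighted behavioral drowsiness score on [0,1]-scaled indicators."""
    arrs = [np.asarray(a, dtype=float) for a in (perclos, yawn, blink, posture)]
    for a in arrs:
        if np.any((a < 0) | (a > 1)):
            raise DrowsecgError("behavioral score inputs must lie in [0, 1]")
    p, y, b, po = arrs
    s = (SCORE_WEIGHTS["perclos"] * p + SCORE_WEIGHTS["yawn"] * y
         + SCORE_WEIGHTS["blink"] * b + SCORE_WEIGHTS["posture"] * po)
    return s if s.shape else float(s)


def drowsiness_level(s):
    """Bucket a behavioral score: Alert <0.25 ≤ Light <0.40 ≤ Moderate <0.60 ≤ Severe."""
    arr = np.asarray(s, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise DrowsecgError("behavioral score must lie in [0, 1]")
    out = np.select(
        [arr < LEVEL_THRESHOLDS["light"], arr < LEVEL_THRESHOLDS["moderate"], arr < LEVEL_THRESHOLDS["severe"]],
        ["Alert", "Light", "Moderate"],
        default="Severe",
    )
    return out if arr.shape else str(out)


def crash_proximity_labels(window_end_times_s: np.ndarray, crash_times_s,
                           horizon_s: float = CRASH_HORIZON_S) -> np.ndarray:
    """Binary pre-crash label per window.

    A window with end time t is positive iff t_crash − horizon ≤ t < t_crash
    for some crash.  The window's sample time is its end (the most recent
    data it contains), so every positive window strictly precedes its crash.
    """
    ends = np.asarray(window_end_times_s, dtype=float)
    labels = np.zeros(len(ends), dtype=int)
    for tc in np.asarray(list(crash_times_s), dtype=float):
        labels[(ends >= tc - horizon_s) & (ends < tc)] = 1
    return labels


def label_windows(feature_df: pd.DataFrame, crash_times_by_session: dict,
                  scaling: IndicatorScaling | None = None,
                  horizon_s: float = CRASH_HORIZON_S) -> pd.DataFrame:
    """Full label table for a feature frame (raw, un-normalized features).

    ``crash_times_by_session`` maps (participant_id, session_id) to a list of
    crash times.  Returns id columns + s_behavioral, level, crash_proximal.
    """
    sc = scaling or IndicatorScaling()
    s = behavioral_score(
        np.clip(feature_df["perclos"].to_numpy(), 0.0, 1.0),
        sc.scale_yawn(np.clip(feature_df["yawn_freq"].to_numpy(), 0.0, None)),
        sc.scale_blink(np.clip(feature_df["blink_freq"].to_numpy(), 0.0, None)),
        sc.scale_posture(np.clip(feature_df["head_var"].to_numpy(), 0.0, None)),
    )
    out = feature_df[["participant_id", "session_id", "window_start_s", "window_end_s"]].copy()
    out["s_behavioral"] = s
    out["level"] = drowsiness_level(np.asarray(s))
    out["crash_proximal"] = 0
    for (pid, sid), grp in out.groupby(["participant_id", "session_id"]):
        crashes = crash_times_by_session.get((pid, sid), [])
        out.loc[grp.index, "crash_proximal"] = crash_proximity_labels(
            grp["window_end_s"].to_numpy(), crashes, horizon_s
        )
    return out
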