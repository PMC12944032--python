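"""The 35-dimensional window feature set.

Every 30 s analysis window (50% overlap, so one window every 15 s) yields:

* 12 derivative features — mean, SD, RMS, max |.|, zero-crossing rate, and
  OLS slope of the first and second RR derivatives;
* 11 base HRV features — time domain (mRR, SDNN, RMSSD, pNN50, triangular
  index) and Lomb-Scargle frequency domain (LF, HF, LF/HF, total power,
  normalized LF/HF units);
* 8 behavioral features — PERCLOS (trailing 1 min horizon), blink frequency
  and duration, yawn frequency, head pitch/yaw, head-pose variance;
* 4 driving features — SDLP, steering reversal rate, mean |steering angle|,
  minimum time-to-line-crossing.

The 30 s window is short for LF estimation by Task-Force standards; LF values
here are short-window estimates feeding a classifier, not clinical HRV
readings, and the manifest marks them as such.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .derivatives import UniformSignal
from .ecg import RRISeries
from .errors import DataQualityError

WINDOW_LEN_S = 30.0
WINDOW_STEP_S = 15.0

_DERIV_STATS = ["mean", "sd", "rms", "maxabs", "zcr", "slope"]
D1_FEATURES = [f"d1_{s}" for s in _DERIV_STATS]
D2_FEATURES = [f"d2_{s}" for s in _DERIV_STATS]
BASE_HRV_FEATURES = [
    "mrr_ms", "sdnn_ms", "rmssd_ms", "pnn50_pct", "tri_index",
    "lf_power", "hf_power", "lf_hf_ratio", "total_power", "lf_nu", "hf_nu",
]
BEHAVIORAL_FEATURES = [
    "perclos", "blink_freq", "blink_dur_s", "yawn_freq", "yawn_intensity",
    "head_pitch_deg", "head_yaw_deg", "head_var",
]
DRIVING_FEATURES = ["sdlp_m", "steer_reversal_rate", "mean_abs_steer_deg", "tlc_s"]

#: canonical order of the 35 features
FEATURE_NAMES = D1_FEATURES + D2_FEATURES + BASE_HRV_FEATURES + BEHAVIORAL_FEATURES + DRIVING_FEATURES
assert len(FEATURE_NAMES) == 35

ID_COLUMNS = ["participant_id", "session_id", "window_start_s", "window_end_s"]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TRI_BIN_S = 1.0 / 128.0


def feature_manifest() -> dict:
    """Feature-group membership consumed by the ablation runner.

    Besides the four primary groups, exposes reduced derivative sets (three
    magnitude statistics per derivative order) matching the coarser feature
    counts used in ablation-style reporting.
    """
    reduced = ["mean", "sd", "rms"]
    return {
        "feature_order": list(FEATURE_NAMES),
        "groups": {
            "derivatives": D1_FEATURES + D2_FEATURES,
            "base_hrv": list(BASE_HRV_FEATURES),
            "behavioral": list(BEHAVIORAL_FEATURES),
            "driving": list(DRIVING_FEATURES),
            "d1": list(D1_FEATURES),
            "d2": list(D2_FEATURES),
            "d1_reduced": [f"d1_{s}" for s in reduced],
            "d2_reduced": [f"d2_{s}" for s in reduced],
            "derivatives_reduced": [f"d1_{s}" for s in reduced] + [f"d2_{s}" for s in reduced],
        },
        "notes": {"lf_power": "short-window estimate (30 s)", "lf_hf_ratio": "short-window estimate (30 s)"},
    }


def make_windows(session_span_s: float, length_s: float = WINDOW_LEN_S,
                 overlap: float = 0.5) -> np.ndarray:
    """Window start times: 0, step, 2·step, … while start + length ≤ span."""
    step = length_s * (1.0 - overlap)
    if session_span_s < length_s:
        return np.zeros(0)
    n = int(np.floor((session_span_s - length_s) / step + 1e-9)) + 1
    return np.arange(n) * step


def _ffill_signs(x: np.ndarray) -> np.ndarray:
    """Signs of x with exact zeros carrying the previous nonzero sign."""
    s = np.sign(x)
    out = s.copy()
    last = 0.0
    for i in range(len(s)):
        if out[i] == 0:
            out[i] = last
        else:
            last = out[i]
    return out


def derivative_features(blocks: list[UniformSignal], start_s: float, end_s: float,
                        prefix: str) -> dict[str, float]:
    """Six summary statistics of a derivative signal inside one window.

    Zero-crossing rate is sign changes per second (exact zeros keep the
    previous sign, so they never double-count); slope is the OLS linear-trend
    coefficient of value against time.
    """
    ts, vs = [], []
    for b in blocks:
        t = b.times
        m = (t >= start_s) & (t < end_s)
        if m.any():
            ts.append(t[m])
            vs.append(b.values[m])
    out = {f"{prefix}_{s}": np.nan for s in _DERIV_STATS}
    if not ts:
        return out
    t = np.concatenate(ts)
    v = np.concatenate(vs)
    if len(v) < 2:
        return out
    out[f"{prefix}_mean"] = float(np.mean(v))
    out[f"{prefix}_sd"] = float(np.std(v, ddof=1))
    out[f"{prefix}_rms"] = float(np.sqrt(np.mean(v**2)))
    out[f"{prefix}_maxabs"] = float(np.max(np.abs(v)))
    signs = _ffill_signs(v)
    nz = signs != 0
    crossings = int(np.sum(np.diff(signs[nz]) != 0)) if nz.sum() > 1 else 0
    span = t[-1] - t[0]
    out[f"{prefix}_zcr"] = crossings / span if span > 0 else 0.0
    out[f"{prefix}_slope"] = float(np.polyfit(t, v, 1)[0])
    return out


def time_domain_features(rr_times_s: np.ndarray, rr_ms: np.ndarray,
                         start_s: float, end_s: float) -> dict[str, float]:
    """mRR, SDNN, RMSSD, pNN50, triangular index for RR intervals in a window.

    Intervals belong to the window of their end beat.  RMSSD/pNN50 need at
    least three intervals (two successive differences).
    """
    m = (rr_times_s > start_s) & (rr_times_s <= end_s)
    rr = rr_ms[m]
    out = dict.fromkeys(["mrr_ms", "sdnn_ms", "rmssd_ms", "pnn50_pct", "tri_index"], np.nan)
    if len(rr) < 2:
        return out
    out["mrr_ms"] = float(np.mean(rr))
    out["sdnn_ms"] = float(np.std(rr, ddof=1))
    bins = np.floor(rr / 1000.0 / TRI_BIN_S).astype(int)
    _, counts = np.unique(bins, return_counts=True)
    out["tri_index"] = float(len(rr) / counts.max())
    if len(rr) >= 3:
        d = np.diff(rr)
        out["rmssd_ms"] = float(np.sqrt(np.mean(d**2)))
        out["pnn50_pct"] = float(100.0 * np.mean(np.abs(d) > 50.0))
    return out


def frequency_domain_features(rr_times_s: np.ndarray, rr_ms: np.ndarray,
                              start_s: float, end_s: float,
                              n_freqs: int = 256) -> dict[str, float]:
    """Lomb-Scargle band powers of the irregular tachogram in a window.

    The periodogram is evaluated on a dense 0.003–0.5 Hz grid directly from
    the (beat time, RR) pairs — no resampling — and band powers are trapezoid
    integrals over LF 0.04–0.15 Hz and HF 0.15–0.40 Hz; total power spans
    0.003–0.40 Hz.  Normalized units split LF+HF into percentages.
    """
    m = (rr_times_s > start_s) & (rr_times_s <= end_s)
    t, y = rr_times_s[m], rr_ms[m]
    out = dict.fromkeys(["lf_power", "hf_power", "lf_hf_ratio", "total_power", "lf_nu", "hf_nu"], np.nan)
    if len(y) < 8:
        return out
    f = np.linspace(0.003, 0.5, n_freqs)
    p = sps.lombscargle(t, y - y.mean(), 2 * np.pi * f)
    def band(lo, hi):
        sel = (f >= lo) & (f <= hi)
        return float(np.trapezoid(p[sel], f[sel]))
    lf, hf = band(*LF_BAND), band(*HF_BAND)
    out["lf_power"], out["hf_power"] = lf, hf
    out["total_power"] = band(0.003, HF_BAND[1])
    if hf > 0:
        out["lf_hf_ratio"] = lf / hf
    if lf + hf > 0:
        out["lf_nu"] = 100.0 * lf / (lf + hf)
        out["hf_nu"] = 100.0 * hf / (lf + hf)
    return out


def behavioral_window_features(behavioral: pd.DataFrame, start_s: float, end_s: float,
                               perclos_horizon_s: float = 60.0) -> dict[str, float]:
    """Window summaries of the behavioral streams.

    PERCLOS is averaged over the trailing 1 min ending at the window end (its
    conventional horizon); all other indicators are 30 s window means.
    head_var is the variance of pitch plus variance of yaw inside the window.
    """
    t = behavioral["time_s"].to_numpy()
    win = (t >= start_s) & (t < end_s)
    out = dict.fromkeys(BEHAVIORAL_FEATURES, np.nan)
    if not win.any():
        return out
    trail = (t >= end_s - perclos_horizon_s) & (t < end_s)
    out["perclos"] = float(behavioral.loc[trail, "perclos"].mean()) if trail.any() else np.nan
    for col, feat in [("blink_freq", "blink_freq"), ("blink_dur_s", "blink_dur_s"),
                      ("yawn_freq", "yawn_freq"), ("yawn_intensity", "yawn_intensity"),
                      ("head_pitch_deg", "head_pitch_deg"), ("head_yaw_deg", "head_yaw_deg")]:
        out[feat] = float(behavioral.loc[win, col].mean())
    pitch = behavioral.loc[win, "head_pitch_deg"].to_numpy()
    yaw = behavioral.loc[win, "head_yaw_deg"].to_numpy()
    if len(pitch) >= 2:
        out["head_var"] = float(np.var(pitch, ddof=1) + np.var(yaw, ddof=1))
    else:
        out["head_var"] = 0.0
    return out


def steering_reversal_rate(steer_deg: np.ndarray, duration_s: float, gap_deg: float = 2.0) -> float:
    """Direction changes of the steering angle exceeding a 2° gap, per minute.

    Counted on the sequence of local extrema: every swing between successive
    extrema of at least ``gap_deg`` is one reversal.
    """
    if len(steer_deg) < 3:
        return 0.0
    d = np.diff(steer_deg)
    nz = d != 0
    if not nz.any():
        return 0.0
    turning = np.flatnonzero(np.diff(_ffill_signs(d)) != 0) + 1
    ext = np.concatenate(([steer_deg[0]], steer_deg[turning], [steer_deg[-1]]))
    swings = np.abs(np.diff(ext))
    return float(np.sum(swings >= gap_deg) / (duration_s / 60.0))


def driving_window_features(driving: pd.DataFrame, start_s: float, end_s: float,
                            lane_half_width_m: float = 1.8, tlc_cap_s: float = 30.0) -> dict[str, float]:
    """SDLP, steering reversal rate, mean |steering|, minimum TLC in a window.

    TLC projects the current lateral velocity: time until the lane boundary
    on the side the vehicle is drifting toward, capped at 30 s.
    """
    t = driving["time_s"].to_numpy()
    m = (t >= start_s) & (t < end_s)
    out = dict.fromkeys(DRIVING_FEATURES, np.nan)
    if m.sum() < 3:
        return out
    x = driving.loc[m, "lane_pos_m"].to_numpy()
    steer = driving.loc[m, "steering_deg"].to_numpy()
    dt = float(np.median(np.diff(t[m])))
    out["sdlp_m"] = float(np.std(x, ddof=1))
    out["steer_reversal_rate"] = steering_reversal_rate(steer, end_s - start_s)
    out["mean_abs_steer_deg"] = float(np.mean(np.abs(steer)))
    v = np.gradient(x, dt)
    tlc = np.full(len(x), tlc_cap_s)
    pos = v > 1e-9
    neg = v < -1e-9
    tlc[pos] = np.minimum((lane_half_width_m - x[pos]) / v[pos], tlc_cap_s)
    tlc[neg] = np.minimum((-lane_half_width_m - x[neg]) / v[neg], tlc_cap_s)
    tlc = np.clip(tlc, 0.0, tlc_cap_s)
    out["tlc_s"] = float(np.min(tlc))
    return out


def extract_features(rr: RRISeries, d1_blocks: list[UniformSignal], d2_blocks: list[UniformSignal],
                     behavioral: pd.DataFrame, driving: pd.DataFrame,
                     duration_s: float, participant_id: str, session_id: str,
                     lane_half_width_m: float = 1.8) -> pd.DataFrame:
    """All 35 features for every window of one session.

    Returns a DataFrame with the four id columns followed by the 35 feature
    columns in canonical order; features that cannot be computed in a window
    are NaN (to be imputed downstream).
    """
    starts = make_windows(duration_s)
    rr_t, rr_v = rr.retained()
    rows = []
    for s0 in starts:
        s1 = s0 + WINDOW_LEN_S
        row: dict[str, float] = {
            "participant_id": participant_id, "session_id": session_id,
            "window_start_s": s0, "window_end_s": s1,
        }
        row.update(derivative_features(d1_blocks, s0, s1, "d1"))
        row.update(derivative_features(d2_blocks, s0, s1, "d2"))
        row.update(time_domain_features(rr_t, rr_v, s0, s1))
        row.update(frequency_domain_features(rr_t, rr_v, s0, s1))
        row.update(behavioral_window_features(behavioral, s0, s1))
        row.update(driving_window_features(driving, s0, s1, lane_half_width_m))
        rows.append(row)
    return pd.DataFrame(rows, columns=ID_COLUMNS + FEATURE_NAMES)


def normalize_per_participant(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant z-score of every feature column.

    Returns the normalized frame and a (participant × feature) boolean frame
    flagging degenerate columns (zero or undefined SD), which are set to 0.
    Normalization never mixes participants, so participant-level CV splits
    stay leak-free.
    """
    out = df.copy()
    flags = []
    for pid, grp in df.groupby("participant_id"):
        mu = grp[FEATURE_NAMES].mean()
        sd = grp[FEATURE_NAMES].std(ddof=1)
        degenerate = (sd == 0) | sd.isna()
        z = (grp[FEATURE_NAMES] - mu) / sd
        z.loc[:, degenerate[degenerate].index] = 0.0
        out.loc[grp.index, FEATURE_NAMES] = z
        flags.append(pd.Series(degenerate, name=pid))
    return out, pd.DataFrame(flags)


def impute_missing(df: pd.DataFrame, max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Linear interpolation of missing feature values over window index.

    Performed per session and per feature; leading/trailing gaps take the
    nearest observed value.  A session-feature with more than 20% missing is
    a data-quality failure and raises rather than fabricating a trend.
    """
    out = df.copy()
    for (pid, sid), grp in df.groupby(["participant_id", "session_id"]):
        block = grp.sort_values("window_start_s")
        vals = block[FEATURE_NAMES]
        frac = vals.isna().mean()
        bad = frac[frac > max_missing_frac]
        if not bad.empty:
            raise DataQualityError(
                f"session {pid}/{sid}: features exceed {max_missing_frac:.0%} missing: "
                + ", ".join(f"{k} ({v:.0%})" for k, v in bad.items())
            )
        filled = vals.interpolate(method="linear", limit_direction="both", axis=0)
        out.loc[block.index, FEATURE_NAMES] = filled
    return out
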