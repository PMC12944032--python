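"""Synthetic driving-session generator.

Produces multi-stream driving sessions with the statistical structure the
downstream analysis assumes: a latent drowsiness state that ramps up once per
session, RR-interval dynamics that lengthen and shift toward high-frequency
(parasympathetic) variability as drowsiness deepens, behavioral indicators
(PERCLOS, yawning, blinks, head pose) that lag physiology by several minutes,
driving degradation (lane weaving, steering corrections) that precedes
crashes, and rare crash events driven by an impairment-proportional hazard
plus lane departures.

All randomness flows from one seed per session; sub-streams use fixed spawn
keys so that adding draws to one stream never perturbs another.  A fixed
``SimConfig`` therefore yields byte-identical sessions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .errors import ConfigurationError

BEHAVIORAL_RATE_HZ = 1.0
DRIVING_RATE_HZ = 60.0
#: behavioral channel order used in SessionRecord.behavioral and behavioral.csv
BEHAVIORAL_COLUMNS = [
    "perclos",
    "yawn_freq",
    "yawn_intensity",
    "blink_freq",
    "blink_dur_s",
    "head_pitch_deg",
    "head_yaw_deg",
    "head_var",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic driving session.

    Units are embedded in the field names; amplitudes are in milliseconds of
    RR-interval modulation.  ``drowsiness_onset_s`` is the center of the
    logistic alert-to-drowsy transition and ``onset_steepness`` its slope
    (1/s); ``behavioral_lag_s`` / ``driving_lag_s`` delay the behavioral and
    driving responses relative to the latent physiological state.
    """

    duration_s: float = 5400.0
    ecg_rate: float = 500.0
    drowsiness_onset_s: float = 1800.0
    onset_steepness: float = 0.01
    rr_baseline_ms: float = 800.0
    rr_drowsy_gain_ms: float = 150.0
    lf_amp_ms: float = 30.0
    hf_amp_ms: float = 20.0
    behavioral_lag_s: float = 360.0
    driving_lag_s: float = 240.0
    crash_hazard_scale: float = 1.5e-4
    noise_sd_ms: float = 8.0
    artifact_rate: float = 0.5  # bursts per minute
    artifact_min_s: float = 0.5
    artifact_max_s: float = 1.5
    ecg_noise_sd: float = 0.02  # white noise, units of QRS amplitude
    wander_amp: float = 0.15  # baseline wander amplitude (<1 Hz)
    lane_half_width_m: float = 1.8
    # lane-noise inflation at full drowsiness: alert SDLP ~0.25 m rises to
    # ~0.45 m when fully drowsy, keeping lane departures (1.8 m) rare
    driving_noise_gain: float = 0.8
    latent_noise_amp: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.ecg_rate < 100:
            raise ConfigurationError("ecg_rate must be at least 100 Hz")
        if not (0 <= self.drowsiness_onset_s <= self.duration_s):
            raise ConfigurationError("drowsiness_onset_s must lie in [0, duration_s]")
        for name in ("rr_baseline_ms", "rr_drowsy_gain_ms", "lf_amp_ms", "hf_amp_ms",
                     "noise_sd_ms", "artifact_rate", "crash_hazard_scale",
                     "behavioral_lag_s", "driving_lag_s", "latent_noise_amp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.onset_steepness <= 0:
            raise ConfigurationError("onset_steepness must be positive")


@dataclass
class CrashEvent:
    time_s: float
    severity: str  # "minor" | "major"


@dataclass
class SessionRecord:
    """One synchronized multi-stream driving session.

    ``true_*`` fields are generator ground truth and have no counterpart in
    real recordings; downstream modules never read them (tests do).
    """

    participant_id: str
    session_id: str
    ecg: np.ndarray
    ecg_rate: float
    behavioral: pd.DataFrame  # time_s + BEHAVIORAL_COLUMNS, 1 Hz
    driving: pd.DataFrame  # time_s, lane_pos_m, steering_deg, 60 Hz
    crashes: list[CrashEvent]
    duration_s: float
    true_onset_s: float
    true_beat_times_s: np.ndarray
    true_rr_ms: np.ndarray
    artifact_spans: list[tuple[float, float]] = field(default_factory=list)
    config: SimConfig | None = None


def _substream(cfg_seed: int, key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg_seed, spawn_key=(key,))))


def _smooth_noise(rng: np.random.Generator, n: int, rate_hz: float, smooth_s: float = 20.0) -> np.ndarray:
    """Bounded smooth noise: Gaussian white noise low-passed and rescaled to max|.| = 1."""
    if n == 0:
        return np.zeros(0)
    raw = rng.standard_normal(n)
    sm = gaussian_filter1d(raw, sigma=max(smooth_s * rate_hz, 1.0), mode="reflect")
    peak = np.max(np.abs(sm))
    return sm / peak if peak > 0 else sm


class DrowsinessTrajectory:
    """Latent drowsiness D(t) in [0, 1]: logistic ramp plus bounded smooth noise."""

    def __init__(self, cfg: SimConfig):
        cfg.validate()
        self.onset_s = cfg.drowsiness_onset_s
        self.steepness = cfg.onset_steepness
        self.duration_s = cfg.duration_s
        rng = _substream(cfg.seed, 0)
        self._noise_rate = 1.0
        n = int(np.ceil(cfg.duration_s * self._noise_rate)) + 1
        self._noise = cfg.latent_noise_amp * _smooth_noise(rng, n, self._noise_rate, smooth_s=30.0)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.isinf(self.steepness):
            base = np.where(t >= self.onset_s, 1.0, 0.0)
        else:
            base = expit(self.steepness * (t - self.onset_s))
        idx = np.clip(t * self._noise_rate, 0, len(self._noise) - 1)
        noise = np.interp(idx, np.arange(len(self._noise)), self._noise)
        # no noise outside the session span (lagged lookups at t<0 stay clean)
        noise = np.where((t >= 0) & (t <= self.duration_s), noise, 0.0)
        return np.clip(base + noise, 0.0, 1.0)


def simulate_trajectory(cfg: SimConfig) -> DrowsinessTrajectory:
    """Latent drowsiness series D(t) ∈ [0,1] for the session."""
    return DrowsinessTrajectory(cfg)


def generate_rr_series(D: DrowsinessTrajectory, cfg: SimConfig):
    """Beat times and RR intervals driven by the latent state.

    RR(t) = baseline + gain·D(t) + LF oscillation (0.1 Hz, amplitude shrinking
    with D) + HF oscillation (0.25 Hz, amplitude growing with D) + white noise,
    clipped to the physiological band [300, 2000] ms.  Beat times are the
    cumulative sum of the generated intervals.

    Returns ``(beat_times_s, rr_ms)``; ``rr_ms[i]`` is the interval between
    beats i and i+1.
    """
    cfg.validate()
    rng = _substream(cfg.seed, 1)
    beat_times: list[float] = []
    rrs: list[float] = []
    t = 0.5  # first beat clear of the session boundary (full template)
    while t < cfg.duration_s:
        d = float(D(t))
        rr = (
            cfg.rr_baseline_ms
            + cfg.rr_drowsy_gain_ms * d
            + cfg.lf_amp_ms * (1.0 - 0.6 * d) * np.sin(2 * np.pi * 0.1 * t)
            + cfg.hf_amp_ms * (0.3 + 0.7 * d) * np.sin(2 * np.pi * 0.25 * t)
            + (cfg.noise_sd_ms * rng.standard_normal() if cfg.noise_sd_ms > 0 else 0.0)
        )
        if rr <= 0:
            raise ConfigurationError("configuration produced a non-positive RR interval")
        rr = float(np.clip(rr, 300.0, 2000.0))
        beat_times.append(t)
        rrs.append(rr)
        t += rr / 1000.0
    beat_arr = np.array(beat_times)
    rr_arr = np.array(rrs)
    if len(beat_arr) >= 2:
        rr_arr = rr_arr[:-1]  # last interval extends past duration; keep pairs only
        return beat_arr, rr_arr
    return beat_arr, np.zeros(0)


def _add_hump(wave: np.ndarray, rate: float, center_s: float, amp: float, sigma_s: float) -> None:
    half = 4.0 * sigma_s
    i0 = max(int(np.floor((center_s - half) * rate)), 0)
    i1 = min(int(np.ceil((center_s + half) * rate)) + 1, len(wave))
    if i1 <= i0:
        return
    tt = np.arange(i0, i1) / rate
    wave[i0:i1] += amp * np.exp(-0.5 * ((tt - center_s) / sigma_s) ** 2)


def synthesize_ecg(beat_times_s: np.ndarray, cfg: SimConfig):
    """Template-beat ECG waveform at ``cfg.ecg_rate``.

    Each beat is an analytic spike-plus-hump template (dominant R spike with
    smaller P and T humps) — enough to exercise R-peak detection and the
    signal-quality indices; it is not a physiological (diagnostic) ECG model.
    Adds baseline wander (<1 Hz), white noise, and, at ``artifact_rate``
    bursts/min, high-amplitude saturating motion-artifact segments.

    Returns ``(waveform, artifact_spans)`` where spans are (start_s, end_s).
    """
    cfg.validate()
    rng = _substream(cfg.seed, 2)
    n = int(round(cfg.duration_s * cfg.ecg_rate))
    wave = np.zeros(n)
    for bt in np.asarray(beat_times_s, dtype=float):
        _add_hump(wave, cfg.ecg_rate, bt, 1.0, 0.012)            # R
        _add_hump(wave, cfg.ecg_rate, bt - 0.18, 0.12, 0.025)    # P
        _add_hump(wave, cfg.ecg_rate, bt + 0.28, 0.25, 0.060)    # T
    tgrid = np.arange(n) / cfg.ecg_rate
    if cfg.wander_amp > 0:
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        wave += cfg.wander_amp * np.sin(2 * np.pi * 0.18 * tgrid + ph1)
        wave += 0.6 * cfg.wander_amp * np.sin(2 * np.pi * 0.33 * tgrid + ph2)
    if cfg.ecg_noise_sd > 0:
        wave += cfg.ecg_noise_sd * rng.standard_normal(n)
    spans: list[tuple[float, float]] = []
    if cfg.artifact_rate > 0:
        n_bursts = rng.poisson(cfg.artifact_rate * cfg.duration_s / 60.0)
        starts = np.sort(rng.uniform(0, cfg.duration_s, size=n_bursts))
        for s in starts:
            dur = rng.uniform(cfg.artifact_min_s, cfg.artifact_max_s)
            i0 = int(s * cfg.ecg_rate)
            i1 = min(int((s + dur) * cfg.ecg_rate), n)
            if i1 <= i0:
                continue
            burst = rng.uniform(-8.0, 8.0, size=i1 - i0)
            wave[i0:i1] = np.clip(wave[i0:i1] + burst, -8.0, 8.0)
            spans.append((s, min(s + dur, cfg.duration_s)))
    return wave, spans


def generate_behavioral_streams(D: DrowsinessTrajectory, cfg: SimConfig) -> pd.DataFrame:
    """Behavioral indicator series at 1 Hz, driven by the lagged latent state.

    PERCLOS rises from ~0.02 toward ~0.40, yawn/blink frequencies and head
    variability rise, all with bounded smooth noise.  A continuous
    ``yawn_intensity`` channel (mouth-opening proxy in [0,1]) supports the
    sustained-exceedance yawn detector used in the lead-time analysis.
    """
    cfg.validate()
    rng = _substream(cfg.seed, 3)
    t = np.arange(0.0, cfg.duration_s + 1e-9, 1.0 / BEHAVIORAL_RATE_HZ)
    dl = D(t - cfg.behavioral_lag_s)
    noise = [_smooth_noise(rng, len(t), BEHAVIORAL_RATE_HZ) for _ in range(8)]
    df = pd.DataFrame({
        "time_s": t,
        "perclos": np.clip(0.02 + 0.38 * dl + 0.015 * noise[0], 0.0, 1.0),
        "yawn_freq": np.clip(0.1 + 3.9 * dl + 0.2 * noise[1], 0.0, None),
        # slope calibrated so sustained-yawn detection trails the PERCLOS
        # threshold crossing by ~1.6 min, the spacing between the two
        # behavioral detectors' published lead times
        "yawn_intensity": np.clip(0.08 + 0.90 * dl + 0.02 * noise[2], 0.0, 1.0),
        "blink_freq": np.clip(12.0 + 14.0 * dl + 1.0 * noise[3], 0.0, None),
        "blink_dur_s": np.clip(0.18 + 0.30 * dl + 0.02 * noise[4], 0.05, None),
        "head_pitch_deg": 2.0 + 9.0 * dl + 1.5 * noise[5],
        "head_yaw_deg": 2.0 * (0.5 + 1.5 * dl) * noise[6],
        "head_var": np.clip(1.5 + 28.0 * dl + 1.0 * noise[7], 0.0, None),
    })
    return df


def generate_driving_streams(D: DrowsinessTrajectory, cfg: SimConfig) -> pd.DataFrame:
    """Lane position and steering angle at 60 Hz.

    Lane position follows a mean-reverting random walk whose innovation SD
    scales with the lagged latent state (alert SDLP ≈ 0.25 m); steering is a
    stabilizing response to lateral error plus drowsiness-scaled noise.
    """
    cfg.validate()
    rng = _substream(cfg.seed, 4)
    dt = 1.0 / DRIVING_RATE_HZ
    t = np.arange(0.0, cfg.duration_s, dt)
    dl = D(t - cfg.driving_lag_s)
    theta = 0.15  # mean reversion 1/s
    sigma0 = 0.25 * np.sqrt(2 * theta)  # stationary SD 0.25 m when alert
    sigma = sigma0 * (1.0 + cfg.driving_noise_gain * dl)
    eps = rng.standard_normal(len(t))
    x = np.empty(len(t))
    x[0] = 0.0
    sq = np.sqrt(dt)
    for k in range(1, len(t)):
        x[k] = x[k - 1] - theta * x[k - 1] * dt + sigma[k - 1] * sq * eps[k - 1]
    v = np.gradient(x, dt)
    steer_noise = gaussian_filter1d(rng.standard_normal(len(t)), sigma=0.3 * DRIVING_RATE_HZ)
    steer = -4.0 * x - 1.5 * v + 6.0 * (0.5 + 2.0 * dl) * steer_noise
    return pd.DataFrame({"time_s": t, "lane_pos_m": x, "steering_deg": steer})


def sample_crashes(driving: pd.DataFrame, D: DrowsinessTrajectory, cfg: SimConfig) -> list[CrashEvent]:
    """Crash events: lane-departure crossings plus an impairment-driven hazard.

    A crash fires when |lane position| first crosses the lane half-width
    (up-crossings only, 30 s refractory) or when a Bernoulli draw under the
    inhomogeneous hazard ``crash_hazard_scale · D(t − driving_lag_s)`` fires
    (evaluated per second).  Events are sorted by time; severity is drawn
    minor/major with the empirical ~7:1 imbalance of simulator crashes.
    """
    cfg.validate()
    rng = _substream(cfg.seed, 5)
    events: list[CrashEvent] = []
    lane = driving["lane_pos_m"].to_numpy()
    tdrv = driving["time_s"].to_numpy()
    over = np.abs(lane) >= cfg.lane_half_width_m
    crossings = np.flatnonzero(over[1:] & ~over[:-1])
    last = -np.inf
    for k in crossings:
        tc = float(tdrv[k + 1])
        if tc - last >= 30.0:
            events.append(CrashEvent(tc, "minor"))
            last = tc
    if cfg.crash_hazard_scale > 0:
        tsec = np.arange(0.0, cfg.duration_s, 1.0)
        p = np.clip(cfg.crash_hazard_scale * D(tsec - cfg.driving_lag_s), 0.0, 1.0)
        fires = rng.random(len(tsec)) < p
        events.extend(CrashEvent(float(tt), "minor") for tt in tsec[fires])
    events.sort(key=lambda e: e.time_s)
    for e in events:
        e.severity = "major" if rng.random() < 0.12 else "minor"
    return events


def generate_session(cfg: SimConfig, participant_id: str = "P01", session_id: str = "S01") -> SessionRecord:
    """Assemble one full synchronized SessionRecord from a SimConfig."""
    cfg.validate()
    D = simulate_trajectory(cfg)
    beat_times, rr = generate_rr_series(D, cfg)
    ecg, spans = synthesize_ecg(beat_times, cfg)
    behavioral = generate_behavioral_streams(D, cfg)
    driving = generate_driving_streams(D, cfg)
    crashes = sample_crashes(driving, D, cfg)
    return SessionRecord(
        participant_id=participant_id,
        session_id=session_id,
        ecg=ecg,
        ecg_rate=cfg.ecg_rate,
        behavioral=behavioral,
        driving=driving,
        crashes=crashes,
        duration_s=cfg.duration_s,
        true_onset_s=cfg.drowsiness_onset_s,
        true_beat_times_s=beat_times,
        true_rr_ms=rr,
        artifact_spans=spans,
        config=cfg,
    )


def generate_cohort(
    n_participants: int,
    sessions_per_participant: int,
    cfg_template: SimConfig,
    seed: int,
) -> list[SessionRecord]:
    """Cohort of sessions with reproducible per-participant parameter jitter.

    Each participant gets a jittered resting RR baseline (SD 40 ms) and each
    session a jittered drowsiness onset time (SD 120 s, clipped to the middle
    of the session), emulating inter-individual baseline differences.
    """
    if n_participants < 2:
        raise ConfigurationError("need at least 2 participants for participant-level CV")
    if sessions_per_participant < 1:
        raise ConfigurationError("sessions_per_participant must be >= 1")
    cfg_template.validate()
    master = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(97,))))
    sessions: list[SessionRecord] = []
    for p in range(n_participants):
        baseline = cfg_template.rr_baseline_ms + 40.0 * master.standard_normal()
        for s in range(sessions_per_participant):
            onset = cfg_template.drowsiness_onset_s + 120.0 * master.standard_normal()
            onset = float(np.clip(onset, 0.1 * cfg_template.duration_s, 0.8 * cfg_template.duration_s))
            sess_seed = int(master.integers(0, 2**31 - 1))
            cfg = dataclasses.replace(
                cfg_template, rr_baseline_ms=float(baseline),
                drowsiness_onset_s=onset, seed=sess_seed,
            )
            sessions.append(generate_session(cfg, participant_id=f"P{p+1:02d}", session_id=f"S{s+1:02d}"))
    return sessions


# ---------------------------------------------------------------------------
# session directory IO (CSV + JSON, the pipeline's on-disk exchange format)

_FLOAT_FMT = "%.6f"


def write_session(record: SessionRecord, out_dir: str | Path) -> Path:
    """Write a SessionRecord as a directory of CSV files plus meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = len(record.ecg)
    ecg_df = pd.DataFrame({"time_s": np.arange(n) / record.ecg_rate, "ecg": record.ecg})
    ecg_df.to_csv(out / "ecg.csv", index=False, float_format=_FLOAT_FMT)
    record.behavioral.to_csv(out / "behavioral.csv", index=False, float_format=_FLOAT_FMT)
    record.driving.to_csv(out / "driving.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        {"time_s": [c.time_s for c in record.crashes], "severity": [c.severity for c in record.crashes]}
    ).to_csv(out / "crashes.csv", index=False, float_format=_FLOAT_FMT)
    meta = {
        "participant_id": record.participant_id,
        "session_id": record.session_id,
        "ecg_rate": record.ecg_rate,
        "duration_s": record.duration_s,
        "true_onset_s": record.true_onset_s,
        "config": dataclasses.asdict(record.config) if record.config else None,
        "artifact_spans": [list(s) for s in record.artifact_spans],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out


def read_session(session_dir: str | Path) -> SessionRecord:
    """Read a session directory written by :func:`write_session`.

    Generator ground truth (beat times, RR) is not part of the on-disk format;
    the returned record carries empty truth arrays, as for real recordings.
    """
    d = Path(session_dir)
    meta = json.loads((d / "meta.json").read_text())
    ecg = pd.read_csv(d / "ecg.csv")["ecg"].to_numpy()
    behavioral = pd.read_csv(d / "behavioral.csv")
    driving = pd.read_csv(d / "driving.csv")
    crashes_df = pd.read_csv(d / "crashes.csv")
    crashes = [CrashEvent(float(r.time_s), str(r.severity)) for r in crashes_df.itertuples()]
    cfg = SimConfig(**meta["config"]) if meta.get("config") else None
    return SessionRecord(
        participant_id=meta["participant_id"],
        session_id=meta["session_id"],
        ecg=ecg,
        ecg_rate=float(meta["ecg_rate"]),
        behavioral=behavioral,
        driving=driving,
        crashes=crashes,
        duration_s=float(meta["duration_s"]),
        true_onset_s=float(meta["true_onset_s"]),
        true_beat_times_s=np.zeros(0),
        true_rr_ms=np.zeros(0),
        artifact_spans=[tuple(s) for s in meta.get("artifact_spans", [])],
        config=cfg,
    )
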