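"""End-to-end pipeline: simulate → preprocess → derive → featurize → label →
train → evaluate → leadtime, as cached, re-runnable stages over a run
directory of plain-text files (CSV + JSON/YAML).

Each stage reads only the files earlier stages wrote, writes its own outputs
with fixed float formatting (so reruns are byte-identical), and is skipped
when its outputs already exist.  Every random operation derives its seed from
the run configuration, so a rerun from the same config reproduces every file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ecg as ecgmod
from . import evaluation as ev
from . import features as feat
from . import labeling
from .classifier import ModelConfig
from .derivatives import UniformSignal, derivative_blocks, resample_rr_uniform
from .errors import DrowsecgError
from .simulate import SimConfig, generate_cohort, read_session, write_session

log = logging.getLogger("drowsecg")

_FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig.reduced)
    n_participants: int = 3
    sessions_per_participant: int = 2
    k_folds: int = 3
    seed: int = 0
    sqi_segment_len_s: float = 10.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["sim"] = SimConfig(**raw["sim"])
        raw["model"] = ModelConfig(**raw["model"])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _session_dirs(run_dir: Path) -> list[Path]:
    return sorted((run_dir / "sessions").iterdir()) if (run_dir / "sessions").exists() else []


def _timed(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %-10s %6.1f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_timed("simulate")
def stage_simulate(cfg: RunConfig, run_dir: Path, force: bool = False) -> None:
    sess_root = run_dir / "sessions"
    if sess_root.exists() and not force:
        return
    cohort = generate_cohort(cfg.n_participants, cfg.sessions_per_participant, cfg.sim, cfg.seed)
    for rec in cohort:
        write_session(rec, sess_root / f"{rec.participant_id}_{rec.session_id}")


@_timed("preprocess")
def stage_preprocess(cfg: RunConfig, run_dir: Path, force: bool = False) -> None:
    for d in _session_dirs(run_dir):
        if (d / "rr.csv").exists() and not force:
            continue
        rec = read_session(d)
        filt = ecgmod.bandpass_filter(rec.ecg, rec.ecg_rate)
        beats = ecgmod.detect_r_peaks(filt, rec.ecg_rate)
        rr = ecgmod.reject_rr_artifacts(ecgmod.compute_rr(beats))
        reports = ecgmod.compute_sqi(filt, rec.ecg_rate, cfg.sqi_segment_len_s)
        rr, excl_frac = ecgmod.exclude_segments(rr, reports)
        pd.DataFrame({
            "beat_time_s": rr.beat_times_s[1:], "rr_ms": rr.rr_ms,
            "quality": rr.quality_mask.astype(int),
        }).to_csv(d / "rr.csv", index=False, float_format=_FLOAT_FMT)
        pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
            d / "sqi.csv", index=False, float_format=_FLOAT_FMT)
        (d / "quality.json").write_text(json.dumps({"excluded_fraction": excl_frac}))


def _read_rr(d: Path) -> ecgmod.RRISeries:
    df = pd.read_csv(d / "rr.csv")
    ends = df["beat_time_s"].to_numpy()
    rr = df["rr_ms"].to_numpy()
    beats = np.concatenate(([ends[0] - rr[0] / 1000.0], ends))
    return ecgmod.RRISeries(beats, rr, df["quality"].to_numpy().astype(bool))


def _write_blocks(path: Path, blocks: list[UniformSignal]) -> None:
    frames = [pd.DataFrame({"time_s": b.times, "value": b.values, "block": i})
              for i, b in enumerate(blocks)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_blocks(path: Path, rate: float = 4.0) -> list[UniformSignal]:
    df = pd.read_csv(path)
    return [UniformSignal(g["time_s"].iloc[0], rate, g["value"].to_numpy())
            for _, g in df.groupby("block")]


@_timed("derive")
def stage_derive(cfg: RunConfig, run_dir: Path, force: bool = False) -> None:
    for d in _session_dirs(run_dir):
        if (d / "d2.csv").exists() and not force:
            continue
        rr = _read_rr(d)
        blocks = resample_rr_uniform(rr)
        d1, d2 = derivative_blocks(blocks)
        _write_blocks(d / "uniform_rr.csv", blocks)
        _write_blocks(d / "d1.csv", d1)
        _write_blocks(d / "d2.csv", d2)


@_timed("featurize")
def stage_featurize(cfg: RunConfig, run_dir: Path, force: bool = False) -> None:
    out = run_dir / "features.csv"
    if out.exists() and not force:
        return
    frames = []
    for d in _session_dirs(run_dir):
        meta = json.loads((d / "meta.json").read_text())
        rr = _read_rr(d)
        d1 = _read_blocks(d / "d1.csv")
        d2 = _read_blocks(d / "d2.csv")
        behavioral = pd.read_csv(d / "behavioral.csv")
        driving = pd.read_csv(d / "driving.csv")
        frames.append(feat.extract_features(
            rr, d1, d2, behavioral, driving, meta["duration_s"],
            meta["participant_id"], meta["session_id"],
            lane_half_width_m=cfg.sim.lane_half_width_m,
        ))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(out, index=False, float_format=_FLOAT_FMT)
    (run_dir / "feature_manifest.json").write_text(json.dumps(feat.feature_manifest(), indent=1))


@_timed("label")
def stage_label(cfg: RunConfig, run_dir: Path, force: bool = False) -> None:
    out = run_dir / "labels.csv"
    if out.exists() and not force:
        return
    df = pd.read_csv(run_dir / "features.csv")
    crashes = {}
    for d in _session_dirs(run_dir):
        meta = json.loads((d / "meta.json").read_text())
        cdf = pd.read_csv(d / "crashes.csv")
        crashes[(meta["participant_id"], meta["session_id"])] = cdf["time_s"].tolist() if len(cdf) else []
    labels = labeling.label_windows(df, crashes)
    labels.to_csv(out, index=False, float_format=_FLOAT_FMT)


def _prepared_features(run_dir: Path) -> pd.DataFrame:
    df = pd.read_csv(run_dir / "features.csv")
    df = feat.impute_missing(df)
    normed, _ = feat.normalize_per_participant(df)
    return normed


@_timed("train")
def stage_train(cfg: RunConfig, run_dir: Path, force: bool = False) -> None:
    """Participant-level CV training; writes pooled held-out predictions."""
    out = run_dir / "predictions.csv"
    if out.exists() and not force:
        return
    features = _prepared_features(run_dir)
    labels = pd.read_csv(run_dir / "labels.csv")
    participants = sorted(features["participant_id"].unique())
    k = min(cfg.k_folds, len(participants))
    splits = ev.participant_kfold(participants, k=k, seed=cfg.seed)
    model_cfg = dataclasses.replace(cfg.model, seed=cfg.seed)
    pooled, histories = ev.run_cv(features, labels, splits, model_cfg)
    pooled.to_csv(out, index=False, float_format=_FLOAT_FMT)
    hist_rows = [dict(fold=h["fold"], **e) for h in histories for e in h["history"]]
    pd.DataFrame(hist_rows).to_csv(run_dir / "training_log.csv", index=False, float_format=_FLOAT_FMT)


@_timed("evaluate")
def stage_evaluate(cfg: RunConfig, run_dir: Path, force: bool = False) -> None:
    out = run_dir / "metrics.json"
    if out.exists() and not force:
        return
    pooled = pd.read_csv(run_dir / "predictions.csv")
    m = ev.classification_metrics(pooled["probability"].to_numpy(), pooled["label"].to_numpy())
    Path(out).write_text(json.dumps(m, indent=1, sort_keys=True))


@_timed("leadtime")
def stage_leadtime(cfg: RunConfig, run_dir: Path, force: bool = False) -> None:
    out = run_dir / "leadtime.csv"
    if out.exists() and not force:
        return
    pooled = pd.read_csv(run_dir / "predictions.csv")
    rows = []
    for d in _session_dirs(run_dir):
        meta = json.loads((d / "meta.json").read_text())
        key = (meta["participant_id"], meta["session_id"])
        sess = pooled[(pooled["participant_id"] == key[0]) & (pooled["session_id"] == key[1])]
        if sess.empty:
            continue
        behavioral = pd.read_csv(d / "behavioral.csv")
        cdf = pd.read_csv(d / "crashes.csv")
        for tc in (cdf["time_s"].tolist() if len(cdf) else []):
            rec = ev.detect_onsets(sess["end_time_s"].to_numpy(), sess["probability"].to_numpy(),
                                   behavioral, float(tc))
            rows.append({
                "participant_id": key[0], "session_id": key[1],
                "crash_time_s": rec.crash_time_s,
                "t_detect_hrv": rec.t_detect_hrv, "t_detect_perclos": rec.t_detect_perclos,
                "t_detect_yawn": rec.t_detect_yawn, "valid": rec.valid,
            })
    pd.DataFrame(rows, columns=["participant_id", "session_id", "crash_time_s",
                                "t_detect_hrv", "t_detect_perclos", "t_detect_yawn",
                                "valid"]).to_csv(out, index=False, float_format=_FLOAT_FMT)


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "derive": stage_derive,
    "featurize": stage_featurize,
    "label": stage_label,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "leadtime": stage_leadtime,
}


def run_pipeline(cfg: RunConfig, run_dir: str | Path, force: bool = False) -> Path:
    """Execute all stages in order; returns the run directory.

    Writes a manifest recording the config, its hash, and stage order, so a
    report can be traced to the exact configuration that produced it.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "run_config.yaml")
    for name, fn in STAGES.items():
        try:
            fn(cfg, run_dir, force=force)
        except FileNotFoundError as e:
            raise DrowsecgError(f"stage '{name}' missing upstream file: {e}") from e
    manifest = {"config_hash": cfg.config_hash(), "stages": list(STAGES)}
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return run_dir


def fixture_config(seed: int = 0) -> RunConfig:
    """Small-cohort configuration for tests: 3 participants × 2 sessions ×
    10 min with an early onset and elevated crash hazard, reduced model."""
    sim = SimConfig(duration_s=600.0, drowsiness_onset_s=200.0, onset_steepness=0.02,
                    crash_hazard_scale=6e-3, behavioral_lag_s=120.0, driving_lag_s=60.0,
                    artifact_rate=0.2, seed=seed)
    model = ModelConfig.reduced(epochs=8, patience=8, seed=seed)
    return RunConfig(sim=sim, model=model, n_participants=3,
                     sessions_per_participant=2, k_folds=3, seed=seed)


def make_fixture(seed: int, out_dir: str | Path) -> Path:
    """Generate the small cohort on disk (sessions only, no training)."""
    cfg = fixture_config(seed)
    run_dir = Path(out_dir)
    stage_simulate(cfg, run_dir)
    return run_dir
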