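"""Canned study-scale experiments: lead-time parameter recovery and the
feature-group ablation, each runnable from a single seed.

These are the desk-scale analogues of the study's temporal-precedence and
ablation analyses, sized so the full set runs in minutes on one CPU.  The
lead-time experiment trains the (reduced) gated transformer on crash-labeled
sessions and measures, per crash on held-out sessions, how much earlier the
classifier probability crosses 0.5 than the PERCLOS and yawn detectors — the
quantity that should recover the generator's built-in behavioral lag.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import classifier as clf
from . import ecg as ecgmod
from . import evaluation as ev
from . import features as feat
from . import labeling
from .derivatives import derivative_blocks, resample_rr_uniform
from .simulate import SessionRecord, SimConfig, generate_session


def leadtime_sim_config(seed: int = 0) -> SimConfig:
    """Session template for the lead-time experiment.

    25 min sessions with the default gradual alert-to-drowsy transition
    centered near 12 min.  The crash hazard is elevated (desk-scale sessions
    must contribute several crashes each) and tracks impairment directly
    (zero driving lag): crashes are caused by the impairment itself, so
    pre-crash windows sample the entire drowsiness ramp rather than only its
    plateau.  Crashes too early for the (lagged) behavioral detectors yield
    invalid records and drop out of the comparison, exactly as crashes
    without all three detections do in the study design.
    """
    return SimConfig(
        duration_s=2000.0,
        drowsiness_onset_s=1400.0,
        onset_steepness=0.015,
        behavioral_lag_s=360.0,
        driving_lag_s=0.0,
        crash_hazard_scale=8e-3,
        artifact_rate=0.3,
        seed=seed,
    )


def session_features(rec: SessionRecord) -> pd.DataFrame:
    """Full single-session pipeline: ECG → RR → derivatives → 35 features."""
    rr, _, _ = ecgmod.preprocess_ecg(rec.ecg, rec.ecg_rate)
    blocks = resample_rr_uniform(rr)
    d1, d2 = derivative_blocks(blocks)
    return feat.extract_features(
        rr, d1, d2, rec.behavioral, rec.driving, rec.duration_s,
        rec.participant_id, rec.session_id,
        lane_half_width_m=rec.config.lane_half_width_m if rec.config else 1.8,
    )


def _cohort_frames(sessions: list[SessionRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Features (imputed, per-participant z-scored) and labels for sessions."""
    frames = [session_features(r) for r in sessions]
    df = pd.concat(frames, ignore_index=True)
    df = feat.impute_missing(df)
    crashes = {(r.participant_id, r.session_id): [c.time_s for c in r.crashes] for r in sessions}
    labels = labeling.label_windows(df, crashes)
    normed, _ = feat.normalize_per_participant(df)
    return normed, labels


def _jittered(template: SimConfig, rng: np.random.Generator) -> SimConfig:
    onset = float(np.clip(template.drowsiness_onset_s + 60.0 * rng.standard_normal(),
                          0.2 * template.duration_s, 0.75 * template.duration_s))
    return dataclasses.replace(
        template,
        rr_baseline_ms=template.rr_baseline_ms + 40.0 * rng.standard_normal(),
        drowsiness_onset_s=onset,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def leadtime_experiment(seed: int = 0, n_train_participants: int = 9,
                        n_models: int = 3, n_eval_sessions: int = 115,
                        model_cfg: clf.ModelConfig | None = None) -> dict:
    """Train a small ensemble on a cohort, then measure per-crash detection
    lead times on freshly generated held-out sessions (new participants).

    HRV-based detection uses models trained on HRV features only (derivatives
    + base metrics): the probability series must reflect cardiac physiology,
    not the behavioral or driving streams it is compared against.  An
    ensemble of ``n_models`` detectors (rotated validation subsets and
    initialization seeds, evaluation sessions assigned round-robin) averages
    out where any single trained model's probability happens to cross 0.5
    along the drowsiness ramp.

    Returns the lead-time summary (means, Wilcoxon tests, rank-biserial,
    HRV-first fraction) plus bookkeeping counts.
    """
    template = leadtime_sim_config()
    rng = np.random.default_rng(seed)

    train_sessions = [
        generate_session(_jittered(template, rng), f"T{p:02d}", "S01")
        for p in range(n_train_participants)
    ]
    features, labels = _cohort_frames(train_sessions)
    base_cfg = model_cfg or clf.ModelConfig.reduced(epochs=30, patience=12, seed=seed)
    manifest = feat.feature_manifest()
    hrv_features = manifest["groups"]["derivatives"] + manifest["groups"]["base_hrv"]
    base_cfg = dataclasses.replace(base_cfg, input_dim=len(hrv_features))
    pids = sorted({r.participant_id for r in train_sessions})
    sequences = clf.build_sequences(features, labels, T=base_cfg.seq_len,
                                    feature_names=hrv_features)
    models = []
    best_aucs = []
    per_model = max(len(pids) // n_models, 1)
    for m in range(n_models):
        val_ids = set(pids[m * per_model: (m + 1) * per_model])
        tr = [s for s in sequences if s.participant_id not in val_ids]
        va = [s for s in sequences if s.participant_id in val_ids]
        cfg_m = dataclasses.replace(base_cfg, seed=base_cfg.seed + 1000 * m)
        model, history = clf.train(tr, va, cfg_m)
        models.append(model)
        best_aucs.append(max(h["val_auc"] for h in history))

    records: list[ev.LeadTimeRecord] = []
    n_crashes = 0
    for k in range(n_eval_sessions):
        rec = generate_session(_jittered(template, rng), f"E{k:03d}", "S01")
        if not rec.crashes:
            continue
        df = session_features(rec)
        df = feat.impute_missing(df)
        normed, _ = feat.normalize_per_participant(df)
        crashes = {(rec.participant_id, rec.session_id): [c.time_s for c in rec.crashes]}
        lab = labeling.label_windows(df, crashes)
        seqs = clf.build_sequences(normed, lab, T=base_cfg.seq_len, feature_names=hrv_features)
        if not seqs:
            continue
        preds = clf.predict_proba(models[k % n_models], seqs)
        for c in rec.crashes:
            n_crashes += 1
            records.append(ev.detect_onsets(
                preds["end_time_s"].to_numpy(), preds["probability"].to_numpy(),
                rec.behavioral, c.time_s,
            ))
    summary = ev.lead_time_analysis(records)
    summary["n_crashes"] = n_crashes
    summary["behavioral_lag_s"] = template.behavioral_lag_s
    summary["lead_gap_hrv_perclos_s"] = summary["lead_hrv_mean_s"] - summary["lead_perclos_mean_s"]
    summary["train_sequences"] = len(sequences)
    summary["best_val_auc"] = float(np.max(best_aucs))
    return summary


def ablation_sim_config(seed: int = 0) -> SimConfig:
    """Cohort template for the ablation: driving-led crashes.

    Lane noise inflates strongly with drowsiness so most crashes are lane
    departures preceded by visible weaving — driving features should carry
    the strongest pre-crash signal, with HRV features informative but weaker.
    """
    return SimConfig(
        duration_s=1200.0,
        drowsiness_onset_s=420.0,
        onset_steepness=0.02,
        behavioral_lag_s=240.0,
        driving_lag_s=120.0,
        crash_hazard_scale=1.0e-3,
        driving_noise_gain=2.6,
        artifact_rate=0.3,
        seed=seed,
    )


def ablation_experiment(seed: int = 0, n_participants: int = 6,
                        sessions_per_participant: int = 1, k_folds: int = 2,
                        model_cfg: clf.ModelConfig | None = None) -> pd.DataFrame:
    """Feature-group ablation with participant-level CV on a small cohort."""
    template = ablation_sim_config()
    rng = np.random.default_rng(seed + 101)
    sessions = [
        generate_session(_jittered(template, rng), f"A{p:02d}", f"S{s:02d}")
        for p in range(n_participants) for s in range(sessions_per_participant)
    ]
    features, labels = _cohort_frames(sessions)
    cfg = model_cfg or clf.ModelConfig.reduced(epochs=12, patience=12, seed=seed)
    pids = sorted(features["participant_id"].unique())
    splits = ev.participant_kfold(pids, k=k_folds, seed=seed)
    manifest = feat.feature_manifest()
    return ev.ablation_study(features, labels, manifest, splits, cfg)
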