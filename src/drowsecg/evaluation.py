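"""Evaluation: participant-level CV, ablation, metrics, and lead-time analysis.

Cross-validation is split at the participant level — every sample's fold
membership is a function of its participant id alone, so no individual's data
can appear on both sides of a split.  The temporal analysis compares three
detectors per crash (classifier probability, PERCLOS threshold, sustained
yawn-signal exceedance) inside a 15 min pre-crash window, and tests the
paired lead-time differences with an exact Wilcoxon signed-rank test
(matched-pairs rank-biserial correlation as effect size).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import classifier as clf
from .errors import ConfigurationError, DrowsecgError, InsufficientDataError
from .features import FEATURE_NAMES
from .metrics import accuracy_f1, auc_score

PRECRASH_WINDOW_S = 900.0
PERCLOS_THRESHOLD = 0.15
YAWN_THRESHOLD = 0.6
YAWN_SUSTAIN_S = 2.0
PROB_THRESHOLD = 0.5


@dataclass
class FoldSplit:
    fold_id: int
    train: set[str]
    val: set[str]
    test: set[str]

    def assert_disjoint(self) -> None:
        if (self.train & self.val) or (self.train & self.test) or (self.val & self.test):
            raise DrowsecgError(f"fold {self.fold_id}: participant sets overlap")


def participant_kfold(participants: list[str], k: int = 5, seed: int = 0,
                      val_frac: float = 0.15) -> list[FoldSplit]:
    """Participant-level k-fold splits with a held-out validation share.

    Participants are shuffled once by seed and partitioned into k near-equal
    test groups; within each fold, ~15% of the non-test participants (at
    least one) become the validation set, the rest train.
    """
    uniq = sorted(set(participants))
    if len(uniq) < k:
        raise ConfigurationError(f"need at least k={k} participants, got {len(uniq)}")
    rng = np.random.default_rng(seed)
    order = [uniq[i] for i in rng.permutation(len(uniq))]
    groups = [order[i::k] for i in range(k)]
    folds = []
    for f in range(k):
        test = set(groups[f])
        rest = [p for p in order if p not in test]
        n_val = max(int(round(val_frac * len(rest))), 1)
        val = set(rest[:n_val])
        train = set(rest[n_val:])
        split = FoldSplit(f, train, val, test)
        split.assert_disjoint()
        folds.append(split)
    return folds


def loso_split(participants: list[str]) -> list[FoldSplit]:
    """Leave-one-subject-out: each participant is the test set once."""
    uniq = sorted(set(participants))
    if len(uniq) < 2:
        raise ConfigurationError("LOSO needs at least 2 participants")
    folds = []
    for f, p in enumerate(uniq):
        rest = [q for q in uniq if q != p]
        val = {rest[f % len(rest)]}
        split = FoldSplit(f, set(rest) - val, val, {p})
        split.assert_disjoint()
        folds.append(split)
    return folds


def classification_metrics(probabilities: np.ndarray, labels: np.ndarray,
                           threshold: float = PROB_THRESHOLD) -> dict:
    """Accuracy and positive-class F1 at the threshold, plus rank AUC.

    AUC is NaN (flagged) when only one class is present; accuracy and F1 are
    still reported — the imbalance pathology where a trivial all-negative
    predictor scores near-perfect accuracy is exactly why AUC is primary.
    """
    acc, f1 = accuracy_f1(labels, probabilities, threshold)
    auc = auc_score(labels, probabilities)
    return {"accuracy": acc, "f1": f1, "auc": auc, "auc_defined": not np.isnan(auc)}


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact for small n, normal approximation beyond)


def wilcoxon_signed_rank(diffs: np.ndarray, exact_max_n: int = 25) -> dict:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon convention); |diffs| get midranks.
    For n ≤ ``exact_max_n`` the null distribution of W⁺ is enumerated exactly
    by dynamic programming over the (doubled, hence integer) midranks; above
    that, the normal approximation with tie correction is used.  Effect size
    is the matched-pairs rank-biserial correlation (W⁺−W⁻)/(W⁺+W⁻).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        return {"n": 0, "w_plus": 0.0, "w_minus": 0.0, "p": np.nan,
                "r_rb": 0.0, "method": "degenerate", "all_zero": True}
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    r_rb = (w_plus - w_minus) / (w_plus + w_minus)
    if n <= exact_max_n:
        doubled = np.round(2 * ranks).astype(int)
        counts = np.zeros(doubled.sum() + 1)
        counts[0] = 1.0
        for r in doubled:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: len(counts) - r]
            counts = counts + shifted
        counts /= counts.sum()
        w2 = int(round(2 * w_plus))
        cdf_le = counts[: w2 + 1].sum()
        cdf_ge = counts[w2:].sum()
        p = min(2.0 * min(cdf_le, cdf_ge), 1.0)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        method = "normal"
    return {"n": n, "w_plus": w_plus, "w_minus": w_minus, "p": float(p),
            "r_rb": float(r_rb), "method": method, "all_zero": False}


# ---------------------------------------------------------------------------
# lead-time analysis


@dataclass
class LeadTimeRecord:
    crash_time_s: float
    t_detect_hrv: float | None
    t_detect_perclos: float | None
    t_detect_yawn: float | None

    def lead(self, which: str) -> float | None:
        t = getattr(self, f"t_detect_{which}")
        return None if t is None else self.crash_time_s - t

    @property
    def valid(self) -> bool:
        return all(getattr(self, f"t_detect_{w}") is not None for w in ("hrv", "perclos", "yawn"))


def _earliest_exceedance(times: np.ndarray, values: np.ndarray, threshold: float,
                         t0: float, t1: float) -> float | None:
    m = (times >= t0) & (times < t1) & (values > threshold)
    return float(times[m][0]) if m.any() else None


def _earliest_sustained(times: np.ndarray, values: np.ndarray, threshold: float,
                        sustain_s: float, t0: float, t1: float) -> float | None:
    m = (times >= t0) & (times < t1)
    t, v = times[m], values[m]
    above = v > threshold
    if not above.any():
        return None
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        if t[b - 1] - t[a] > sustain_s:
            return float(t[a])
    return None


def detect_onsets(prob_times_s: np.ndarray, probabilities: np.ndarray,
                  behavioral: pd.DataFrame, crash_time_s: float,
                  window_s: float = PRECRASH_WINDOW_S) -> LeadTimeRecord:
    """Earliest detection by each indicator inside the pre-crash window.

    HRV: classifier probability > 0.5; PERCLOS: instantaneous series > 0.15;
    yawning: yawn-intensity signal > 0.6 sustained for more than 2 s.  The
    window is [crash − 15 min, crash); its left edge is included, so a
    detection exactly there yields the maximal 900 s lead.
    """
    t0 = crash_time_s - window_s
    bt = behavioral["time_s"].to_numpy()
    return LeadTimeRecord(
        crash_time_s=crash_time_s,
        t_detect_hrv=_earliest_exceedance(np.asarray(prob_times_s, dtype=float),
                                          np.asarray(probabilities, dtype=float),
                                          PROB_THRESHOLD, t0, crash_time_s),
        t_detect_perclos=_earliest_exceedance(bt, behavioral["perclos"].to_numpy(),
                                              PERCLOS_THRESHOLD, t0, crash_time_s),
        t_detect_yawn=_earliest_sustained(bt, behavioral["yawn_intensity"].to_numpy(),
                                          YAWN_THRESHOLD, YAWN_SUSTAIN_S, t0, crash_time_s),
    )


def lead_time_analysis(records: list[LeadTimeRecord]) -> dict:
    """Summary statistics and paired tests over per-crash lead-time records.

    Uses only records with all three detections present.  Reports mean ± SD
    lead per indicator, Wilcoxon tests of the paired HRV−PERCLOS and
    HRV−yawn differences with rank-biserial effect sizes, and the fraction of
    crashes where the HRV detector fired first.
    """
    valid = [r for r in records if r.valid]
    if len(valid) < 5:
        raise InsufficientDataError(f"need >= 5 valid records, got {len(valid)}")
    leads = {w: np.array([r.lead(w) for r in valid]) for w in ("hrv", "perclos", "yawn")}
    out = {
        "n_records": len(records),
        "n_valid": len(valid),
        "valid_rate": len(valid) / len(records) if records else np.nan,
    }
    for w, v in leads.items():
        out[f"lead_{w}_mean_s"] = float(np.mean(v))
        out[f"lead_{w}_sd_s"] = float(np.std(v, ddof=1))
    out["wilcoxon_hrv_vs_perclos"] = wilcoxon_signed_rank(leads["hrv"] - leads["perclos"])
    out["wilcoxon_hrv_vs_yawn"] = wilcoxon_signed_rank(leads["hrv"] - leads["yawn"])
    first = [
        r.t_detect_hrv < min(r.t_detect_perclos, r.t_detect_yawn) for r in valid
    ]
    out["hrv_earliest_fraction"] = float(np.mean(first))
    return out


# ---------------------------------------------------------------------------
# cross-validated training and ablation


def run_cv(features_df: pd.DataFrame, labels_df: pd.DataFrame, splits: list[FoldSplit],
           cfg: clf.ModelConfig, feature_names: list[str] | None = None,
           label_col: str = "crash_proximal") -> tuple[pd.DataFrame, list[dict]]:
    """Train per fold and pool held-out test predictions.

    Returns (pooled prediction frame with fold ids, per-fold histories).
    """
    names = feature_names or FEATURE_NAMES
    cfg = dataclasses.replace(cfg, input_dim=len(names))
    sequences = clf.build_sequences(features_df, labels_df, T=cfg.seq_len,
                                    label_col=label_col, feature_names=names)
    preds, histories = [], []
    for split in splits:
        split.assert_disjoint()
        tr = [s for s in sequences if s.participant_id in split.train]
        va = [s for s in sequences if s.participant_id in split.val]
        te = [s for s in sequences if s.participant_id in split.test]
        if not tr or not va or not te:
            continue
        model, hist = clf.train(tr, va, cfg)
        histories.append({"fold": split.fold_id, "history": hist})
        frame = clf.predict_proba(model, te)
        frame["fold"] = split.fold_id
        preds.append(frame)
    if not preds:
        raise InsufficientDataError("no fold produced predictions")
    return pd.concat(preds, ignore_index=True), histories


def default_ablation_configurations(manifest: dict) -> dict[str, list[str]]:
    """Feature subsets for the standard ablation table."""
    g = manifest["groups"]
    complete = list(manifest["feature_order"])
    return {
        "complete": complete,
        "without_derivatives": [f for f in complete if f not in set(g["derivatives"])],
        "driving_only": list(g["driving"]),
        "hrv_complete": list(g["derivatives"]) + list(g["base_hrv"]),
        "derivatives_only": list(g["derivatives_reduced"]),
        "d1_only": list(g["d1_reduced"]),
        "d2_only": list(g["d2_reduced"]),
    }


def ablation_study(features_df: pd.DataFrame, labels_df: pd.DataFrame,
                   manifest: dict, splits: list[FoldSplit], cfg: clf.ModelConfig,
                   configurations: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Retrain the same model spec on each feature subset and tabulate metrics.

    Each configuration retrains from scratch with the shared seed; metrics are
    computed on the pooled held-out predictions across folds.
    """
    configs = configurations or default_ablation_configurations(manifest)
    known = set(manifest["feature_order"])
    rows = []
    for name, feats in configs.items():
        unknown = [f for f in feats if f not in known]
        if unknown:
            raise ConfigurationError(f"ablation configuration {name}: unknown features {unknown}")
        pooled, _ = run_cv(features_df, labels_df, splits, cfg, feature_names=feats)
        m = classification_metrics(pooled["probability"].to_numpy(), pooled["label"].to_numpy())
        rows.append({"configuration": name, "n_features": len(feats),
                     "accuracy": m["accuracy"], "f1": m["f1"], "auc": m["auc"]})
    return pd.DataFrame(rows)


def characteristic_correlation(accuracies: np.ndarray, characteristics: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (two-sided p, t distribution with n−2 df) per characteristic.

    Constant characteristics yield an undefined r and are flagged rather than
    reported as a number.
    """
    acc = np.asarray(accuracies, dtype=float)
    if len(acc) < 3:
        raise InsufficientDataError("correlation needs at least 3 participants")
    rows = []
    for col in characteristics.columns:
        x = characteristics[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(acc) == 0:
            rows.append({"characteristic": col, "r": np.nan, "p": np.nan, "defined": False})
            continue
        r, p = stats.pearsonr(x, acc)
        rows.append({"characteristic": col, "r": float(r), "p": float(p), "defined": True})
    return pd.DataFrame(rows)
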