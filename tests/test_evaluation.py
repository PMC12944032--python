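"""CV splits, metrics vs brute force, Wilcoxon exactness, lead-time logic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drowsecg import evaluation as ev
from drowsecg.errors import ConfigurationError, DrowsecgError, InsufficientDataError
from drowsecg.metrics import auc_score


def brute_force_auc(y, s):
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_wilcoxon_p(diffs):
    """Exact two-sided p by enumerating every sign assignment of |diffs|."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [sum(r for r, pick in zip(ranks, signs) if pick)
          for signs in itertools.product([0, 1], repeat=n)]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(2 * min(p_le, p_ge), 1.0)


class TestSplits:
    def test_kfold_group_sizes(self):
        parts = [f"P{i:02d}" for i in range(25)]
        folds = ev.participant_kfold(parts, k=5, seed=0)
        assert len(folds) == 5
        for f in folds:
            assert len(f.test) == 5
            f.assert_disjoint()
        tests = [p for f in folds for p in f.test]
        assert sorted(tests) == sorted(parts)  # partition

    def test_kfold_deterministic(self):
        parts = [f"P{i}" for i in range(10)]
        a = ev.participant_kfold(parts, k=5, seed=3)
        b = ev.participant_kfold(parts, k=5, seed=3)
        assert [(f.train, f.val, f.test) for f in a] == [(f.train, f.val, f.test) for f in b]

    def test_kfold_too_few(self):
        with pytest.raises(ConfigurationError):
            ev.participant_kfold(["A", "B"], k=5)

    def test_loso(self):
        parts = [f"P{i}" for i in range(7)]
        folds = ev.loso_split(parts)
        assert len(folds) == 7
        tests = [next(iter(f.test)) for f in folds]
        assert sorted(tests) == sorted(parts)
        for f in folds:
            assert len(f.test) == 1
            f.assert_disjoint()
        with pytest.raises(ConfigurationError):
            ev.loso_split(["only"])

    def test_leakage_guard_raises(self):
        bad = ev.FoldSplit(0, {"A", "B"}, {"B"}, {"C"})
        with pytest.raises(DrowsecgError):
            bad.assert_disjoint()


class TestMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        m = ev.classification_metrics(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert m["auc"] == 1.0 and m["accuracy"] == 1.0 and m["f1"] == 1.0

    def test_random_scores_near_half(self):
        r = np.random.default_rng(0)
        y = r.integers(0, 2, 2000)
        m = ev.classification_metrics(r.random(2000), y)
        assert 0.45 <= m["auc"] <= 0.55

    def test_imbalance_pathology(self):
        n = 20000
        y = np.zeros(n, dtype=int)
        y[: int(0.0009 * n) + 1] = 1
        m = ev.classification_metrics(np.zeros(n), y)
        assert m["accuracy"] > 0.999
        assert m["f1"] == 0.0

    def test_single_class_flagged(self):
        m = ev.classification_metrics(np.array([0.2, 0.7]), np.array([0, 0]))
        assert not m["auc_defined"] and np.isnan(m["auc"])
        assert m["accuracy"] == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_brute_force(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 200))
        y = r.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = np.round(r.random(n), 2)  # coarse grid forces ties
        assert auc_score(y, s) == pytest.approx(brute_force_auc(y, s), abs=1e-12)

    def test_auc_monotone_transform_invariance(self):
        r = np.random.default_rng(7)
        y = r.integers(0, 2, 300)
        s = r.random(300)
        assert auc_score(y, s) == pytest.approx(auc_score(y, np.exp(3 * s)), abs=1e-12)


class TestWilcoxon:
    def test_five_positive_pairs_exact(self):
        out = ev.wilcoxon_signed_rank(np.array([3.0, 1.0, 2.0, 5.0, 4.0]))
        assert out["p"] == pytest.approx(0.0625)
        assert out["r_rb"] == 1.0
        assert out["method"] == "exact"

    def test_all_zero_degenerate(self):
        out = ev.wilcoxon_signed_rank(np.zeros(8))
        assert out["all_zero"] and out["r_rb"] == 0.0 and np.isnan(out["p"])

    @pytest.mark.parametrize("n", [2, 3, 5, 8, 10])
    def test_exact_matches_enumeration_all_patterns(self, n):
        mags = np.arange(1.0, n + 1.0)
        for signs in itertools.product([-1, 1], repeat=n):
            d = mags * np.array(signs)
            ours = ev.wilcoxon_signed_rank(d)["p"]
            assert ours == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_exact_with_ties(self):
        d = np.array([2.0, -2.0, 3.0, 3.0, -1.0, 4.0])
        ours = ev.wilcoxon_signed_rank(d)["p"]
        assert ours == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_large_n_close_to_scipy(self):
        r = np.random.default_rng(0)
        d = r.standard_normal(60) + 0.4
        ours = ev.wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, alternative="two-sided", correction=False)
        assert ours["method"] == "normal"
        assert ours["p"] == pytest.approx(ref.pvalue, rel=0.15)


class TestDetectOnsets:
    def _behavioral(self, perclos_cross_s=500.0, yawn_start_s=650.0):
        t = np.arange(0.0, 1200.0)
        b = pd.DataFrame({
            "time_s": t,
            "perclos": np.where(t >= perclos_cross_s, 0.3, 0.05),
            "yawn_intensity": np.where((t >= yawn_start_s), 0.8, 0.1),
        })
        return b

    def test_lead_arithmetic(self):
        t = np.arange(0.0, 1200.0, 15.0)
        p = np.where(t >= 600.0, 0.9, 0.1)
        rec = ev.detect_onsets(t, p, self._behavioral(), 1000.0)
        assert rec.lead("hrv") == pytest.approx(400.0)
        assert rec.lead("perclos") == pytest.approx(500.0)
        assert rec.valid

    def test_never_crossing_invalid(self):
        t = np.arange(0.0, 1200.0, 15.0)
        rec = ev.detect_onsets(t, np.full(len(t), 0.2), self._behavioral(), 1000.0)
        assert rec.t_detect_hrv is None and not rec.valid

    def test_window_left_edge_included(self):
        t = np.arange(0.0, 1200.0, 15.0)
        p = np.full(len(t), 0.9)  # exceeds threshold everywhere
        # crash at 1005: window start 105 falls exactly on the 15 s grid
        rec = ev.detect_onsets(t, p, self._behavioral(200.0, 300.0), 1005.0)
        assert rec.lead("hrv") == pytest.approx(900.0)

    def test_yawn_requires_sustained_exceedance(self):
        t = np.arange(0.0, 1200.0)

        def frame(yawn):
            return pd.DataFrame({"time_s": t, "perclos": np.full(len(t), 0.3),
                                 "yawn_intensity": yawn})

        yawn = np.full(len(t), 0.1)
        yawn[700:702] = 0.8  # spans 1 s only -> not sustained > 2 s
        rec = ev.detect_onsets(t, np.full(len(t), 0.9), frame(yawn), 1000.0)
        assert rec.t_detect_yawn is None
        yawn[800:805] = 0.8  # spans 4 s -> sustained
        rec = ev.detect_onsets(t, np.full(len(t), 0.9), frame(yawn), 1000.0)
        assert rec.t_detect_yawn == pytest.approx(800.0)


class TestLeadTimeAnalysis:
    def _records(self, n, gap=300.0):
        out = []
        for i in range(n):
            tc = 2000.0 + 10 * i
            out.append(ev.LeadTimeRecord(tc, tc - 700.0 - i, tc - 700.0 + gap - i, tc - 250.0))
        return out

    def test_summary_arithmetic(self):
        s = ev.lead_time_analysis(self._records(10))
        assert s["n_valid"] == 10 and s["valid_rate"] == 1.0
        assert s["lead_hrv_mean_s"] - s["lead_perclos_mean_s"] == pytest.approx(300.0)
        assert s["wilcoxon_hrv_vs_perclos"]["r_rb"] == 1.0
        assert s["hrv_earliest_fraction"] == 1.0

    def test_insufficient_records(self):
        with pytest.raises(InsufficientDataError):
            ev.lead_time_analysis(self._records(4))


class TestCharacteristicCorrelation:
    def test_perfect_linear(self):
        acc = np.array([0.8, 0.82, 0.84, 0.86, 0.88])
        chars = pd.DataFrame({"chest_cm": [80, 85, 90, 95, 100]})
        out = ev.characteristic_correlation(acc, chars)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_constant_flagged(self):
        out = ev.characteristic_correlation(
            np.array([0.8, 0.9, 0.7]), pd.DataFrame({"h": [170, 170, 170]}))
        assert not out["defined"].iloc[0]

    def test_hand_computed_five_points(self):
        acc = np.array([0.85, 0.81, 0.90, 0.86, 0.83])
        x = np.array([100.0, 78.0, 108.0, 95.0, 88.0])
        out = ev.characteristic_correlation(acc, pd.DataFrame({"chest": x}))
        xc, ac = x - x.mean(), acc - acc.mean()
        r_hand = (xc * ac).sum() / np.sqrt((xc**2).sum() * (ac**2).sum())
        assert out["r"].iloc[0] == pytest.approx(r_hand, abs=1e-12)
        t_stat = r_hand * np.sqrt(3 / (1 - r_hand**2))
        p_hand = 2 * stats.t.sf(abs(t_stat), df=3)
        assert out["p"].iloc[0] == pytest.approx(p_hand, abs=1e-12)

    def test_too_few(self):
        with pytest.raises(InsufficientDataError):
            ev.characteristic_correlation(np.array([0.8, 0.9]), pd.DataFrame({"x": [1, 2]}))


class TestAblation:
    def test_duplicate_configuration_identical_and_unknown_rejected(self):
        from drowsecg import features as F
        r = np.random.default_rng(0)
        rows = []
        for p in range(4):
            for k in range(30):
                d = 1.0 if k > 15 else 0.0
                row = {"participant_id": f"P{p}", "session_id": "S1",
                       "window_start_s": 15.0 * k, "window_end_s": 15.0 * k + 30}
                row.update({f: d + 0.3 * r.standard_normal() for f in F.FEATURE_NAMES})
                rows.append(row)
        feats = pd.DataFrame(rows, columns=F.ID_COLUMNS + F.FEATURE_NAMES)
        labels = feats[["participant_id", "session_id", "window_start_s", "window_end_s"]].copy()
        labels["crash_proximal"] = (labels["window_start_s"] > 15 * 15).astype(int)
        from drowsecg.classifier import ModelConfig
        cfg = ModelConfig.reduced(epochs=2, patience=2, seed=0)
        splits = ev.participant_kfold([f"P{p}" for p in range(4)], k=2, seed=0)
        manifest = F.feature_manifest()
        configs = {"a": manifest["groups"]["base_hrv"], "b": manifest["groups"]["base_hrv"]}
        table = ev.ablation_study(feats, labels, manifest, splits, cfg, configs)
        assert table.loc[0, "auc"] == pytest.approx(table.loc[1, "auc"])
        with pytest.raises(ConfigurationError):
            ev.ablation_study(feats, labels, manifest, splits, cfg, {"bad": ["nope"]})
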