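"""35-feature window extraction: grids, statistics, spectra, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drowsecg import features as F
from drowsecg.derivatives import UniformSignal, derivative_blocks, resample_rr_uniform
from drowsecg.ecg import preprocess_ecg
from drowsecg.errors import DataQualityError
from drowsecg.simulate import SimConfig, generate_session


class TestWindows:
    @pytest.mark.parametrize("span, expected", [
        (60.0, [0.0, 15.0, 30.0]),
        (30.0, [0.0]),
        (29.0, []),
    ])
    def test_examples(self, span, expected):
        assert list(F.make_windows(span)) == expected

    @given(st.floats(30.0, 600.0))
    def test_count_formula(self, span):
        n = len(F.make_windows(span))
        assert n == int(np.floor((span - 30.0) / 15.0 + 1e-9)) + 1


class TestDerivativeFeatures:
    def test_constant_series(self):
        b = [UniformSignal(0, 4.0, np.full(120, -2.5))]
        out = F.derivative_features(b, 0, 30, "d1")
        assert out["d1_mean"] == -2.5
        assert out["d1_sd"] == 0.0
        assert out["d1_rms"] == 2.5
        assert out["d1_maxabs"] == 2.5
        assert out["d1_zcr"] == 0.0
        assert out["d1_slope"] == pytest.approx(0.0, abs=1e-9)

    def test_alternating_sign_zcr(self):
        b = [UniformSignal(0, 4.0, np.array([1.0, -1.0, 1.0, -1.0]))]
        out = F.derivative_features(b, 0, 30, "d1")
        assert out["d1_zcr"] == pytest.approx(3 / 0.75)

    def test_ramp_slope_exact(self):
        t = np.arange(120) / 4.0
        b = [UniformSignal(0, 4.0, 0.7 * t + 2)]
        out = F.derivative_features(b, 0, 30, "d1")
        assert out["d1_slope"] == pytest.approx(0.7, abs=1e-9)

    def test_missing_when_empty(self):
        out = F.derivative_features([], 0, 30, "d1")
        assert all(np.isnan(v) for v in out.values())


class TestTimeDomain:
    RR = np.array([800.0, 810.0, 790.0, 805.0])
    T = np.array([1.0, 2.0, 3.0, 4.0])

    def test_rmssd_hand_value(self):
        out = F.time_domain_features(self.T, self.RR, 0, 5)
        assert out["rmssd_ms"] == pytest.approx(np.sqrt(725.0 / 3.0), abs=1e-9)

    def test_sdnn_hand_value(self):
        out = F.time_domain_features(self.T, self.RR, 0, 5)
        assert out["sdnn_ms"] == pytest.approx(np.sqrt(218.75 / 3.0), abs=1e-9)

    def test_pnn50_zero_when_diffs_small(self):
        out = F.time_domain_features(self.T, self.RR, 0, 5)
        assert out["pnn50_pct"] == 0.0

    def test_pnn50_counts_large_diffs(self):
        rr = np.array([800.0, 860.0, 800.0, 810.0])
        out = F.time_domain_features(self.T, rr, 0, 5)
        assert out["pnn50_pct"] == pytest.approx(100.0 * 2 / 3)

    def test_insufficient_beats_missing(self):
        out = F.time_domain_features(np.array([1.0]), np.array([800.0]), 0, 5)
        assert np.isnan(out["mrr_ms"])


class TestFrequencyDomain:
    def _tachogram(self, freq, amp=25.0, seed=0):
        r = np.random.default_rng(seed)
        bt = np.cumsum(r.uniform(0.7, 0.9, 45))
        bt = bt[bt < 30]
        return bt, 800.0 + amp * np.sin(2 * np.pi * freq * bt)

    def test_hf_sinusoid_dominates(self):
        bt, rr = self._tachogram(0.25)
        out = F.frequency_domain_features(bt, rr, 0, 30)
        assert out["hf_power"] > out["lf_power"]
        assert out["hf_nu"] > 50.0

    def test_lf_sinusoid_dominates(self):
        bt, rr = self._tachogram(0.10)
        out = F.frequency_domain_features(bt, rr, 0, 30)
        assert out["lf_power"] > out["hf_power"]
        assert out["lf_nu"] > 50.0

    def test_constant_tachogram_negligible_power(self):
        bt, rr_sin = self._tachogram(0.25)
        sin_hf = F.frequency_domain_features(bt, rr_sin, 0, 30)["hf_power"]
        out = F.frequency_domain_features(bt, np.full(len(bt), 800.0), 0, 30)
        assert out["hf_power"] < 1e-6 * sin_hf
        assert out["lf_power"] < 1e-6 * sin_hf

    def test_normalized_units_sum_to_100(self):
        bt, rr = self._tachogram(0.2, seed=4)
        out = F.frequency_domain_features(bt, rr, 0, 30)
        assert out["lf_nu"] + out["hf_nu"] == pytest.approx(100.0)


class TestBehavioralFeatures:
    def _frame(self, **cols):
        t = np.arange(0.0, 120.0)
        base = {c: np.zeros(len(t)) for c in
                ["perclos", "yawn_freq", "yawn_intensity", "blink_freq",
                 "blink_dur_s", "head_pitch_deg", "head_yaw_deg", "head_var"]}
        base.update({k: np.full(len(t), v) for k, v in cols.items()})
        return pd.DataFrame({"time_s": t, **base})

    def test_constant_eye_closure(self):
        out = F.behavioral_window_features(self._frame(perclos=0.3), 60, 90)
        assert out["perclos"] == pytest.approx(0.3)

    def test_yawn_rate_constant(self):
        out = F.behavioral_window_features(self._frame(yawn_freq=3.0), 60, 90)
        assert out["yawn_freq"] == pytest.approx(3.0)

    def test_constant_head_pose_zero_variance(self):
        out = F.behavioral_window_features(
            self._frame(head_pitch_deg=5.0, head_yaw_deg=-2.0), 60, 90)
        assert out["head_var"] == pytest.approx(0.0)


class TestDrivingFeatures:
    def _frame(self, lane, steer):
        t = np.arange(len(lane)) / 60.0
        return pd.DataFrame({"time_s": t, "lane_pos_m": lane, "steering_deg": steer})

    def test_straight_driving(self):
        d = self._frame(np.zeros(1800), np.zeros(1800))
        out = F.driving_window_features(d, 0, 30)
        assert out["sdlp_m"] == 0.0
        assert out["steer_reversal_rate"] == 0.0

    def test_sine_lane_sdlp(self):
        t = np.arange(1800) / 60.0
        lane = 0.8 * np.sin(2 * np.pi * t / 10.0)  # 3 whole periods
        out = F.driving_window_features(self._frame(lane, np.zeros(1800)), 0, 30)
        assert out["sdlp_m"] == pytest.approx(0.8 / np.sqrt(2), rel=0.02)

    def test_tlc_constant_velocity(self):
        v = 0.1  # m/s drifting toward the line at 1.8 m
        t = np.arange(1800) / 60.0
        lane = v * t
        out = F.driving_window_features(self._frame(lane, np.zeros(1800)), 0, 10)
        x_last = v * (10.0 - 1 / 60.0)  # min TLC occurs at the window's end
        assert out["tlc_s"] == pytest.approx((1.8 - x_last) / v, rel=0.05)


class TestNormalizeImpute:
    def _df(self):
        r = np.random.default_rng(0)
        draws = r.standard_normal((20, len(F.FEATURE_NAMES)))
        rows = []
        for pid, shift in [("P1", 0.0), ("P2", 5.0)]:
            for k in range(20):
                row = {"participant_id": pid, "session_id": "S1",
                       "window_start_s": 15.0 * k, "window_end_s": 15.0 * k + 30}
                row.update({f: shift + draws[k, j] for j, f in enumerate(F.FEATURE_NAMES)})
                rows.append(row)
        return pd.DataFrame(rows, columns=F.ID_COLUMNS + F.FEATURE_NAMES)

    def test_zscore_identity(self):
        out, flags = F.normalize_per_participant(self._df())
        for _, grp in out.groupby("participant_id"):
            assert np.allclose(grp[F.FEATURE_NAMES].mean(), 0.0, atol=1e-12)
            assert np.allclose(grp[F.FEATURE_NAMES].std(ddof=1), 1.0, atol=1e-12)
        assert not flags.any().any()

    def test_shift_invariance(self):
        out, _ = F.normalize_per_participant(self._df())
        g1 = out[out.participant_id == "P1"][F.FEATURE_NAMES].to_numpy()
        g2 = out[out.participant_id == "P2"][F.FEATURE_NAMES].to_numpy()
        # same raw draws shifted by +5 → identical normalized values
        assert np.allclose(np.sort(g1[:, 0]), np.sort(g2[:, 0]), atol=1e-9)

    def test_single_window_participant_degenerate(self):
        df = self._df().iloc[:1].copy()
        out, flags = F.normalize_per_participant(df)
        assert np.allclose(out[F.FEATURE_NAMES].to_numpy(), 0.0)
        assert flags.loc["P1"].all()

    def test_impute_midpoint(self):
        df = self._df().iloc[:6].copy()
        df.loc[df.index[1], "mrr_ms"] = np.nan
        before = df["mrr_ms"].to_numpy()
        out = F.impute_missing(df)
        assert out["mrr_ms"].iloc[1] == pytest.approx((before[0] + before[2]) / 2)

    def test_impute_edge_fill(self):
        df = self._df().iloc[:6].copy()
        df.loc[df.index[0], "sdnn_ms"] = np.nan
        out = F.impute_missing(df)
        assert out["sdnn_ms"].iloc[0] == pytest.approx(df["sdnn_ms"].iloc[1])

    def test_impute_identity_when_complete(self):
        df = self._df()
        pd.testing.assert_frame_equal(F.impute_missing(df), df)

    def test_impute_refuses_heavy_missingness(self):
        df = self._df()
        df.loc[df.participant_id == "P1", "mrr_ms"] = np.nan
        with pytest.raises(DataQualityError):
            F.impute_missing(df)


@pytest.fixture(scope="module")
def session_features():
    cfg = SimConfig(duration_s=600, drowsiness_onset_s=200, onset_steepness=0.02,
                    seed=2, artifact_rate=0.0, noise_sd_ms=0.0, latent_noise_amp=0.0)
    rec = generate_session(cfg)
    rr, _, _ = preprocess_ecg(rec.ecg, rec.ecg_rate)
    blocks = resample_rr_uniform(rr)
    d1, d2 = derivative_blocks(blocks)
    return F.extract_features(rr, d1, d2, rec.behavioral, rec.driving,
                              rec.duration_s, "P1", "S1")


class TestFullExtraction:

    def test_feature_count_contract(self, session_features):
        assert list(session_features.columns) == F.ID_COLUMNS + F.FEATURE_NAMES
        man = F.feature_manifest()
        assert len(man["groups"]["derivatives"]) == 12
        assert len(man["groups"]["base_hrv"]) == 11
        assert len(man["groups"]["behavioral"]) == 8
        assert len(man["groups"]["driving"]) == 4
        assert man["feature_order"] == F.FEATURE_NAMES

    def test_window_count(self, session_features):
        assert len(session_features) == int((600 - 30) / 15) + 1

    def test_drowsiness_response_directional(self, session_features):
        first, last = session_features.iloc[0], session_features.iloc[-1]
        assert last["mrr_ms"] > first["mrr_ms"]
        assert last["hf_power"] > first["hf_power"]
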