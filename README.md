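# drowsecg

Early drowsiness detection from the **first and second derivatives of heart
rate variability**, built as a fully synthetic, reproducible analysis
pipeline for driving-simulator studies.

Behavioral drowsiness cues (eye closure, yawning) appear only after
impairment has set in. Cardiac autonomic rebalancing — the shift from
sympathetic toward parasympathetic dominance — starts earlier, and the
*velocity* and *acceleration* of RR-interval change capture that transition
while conventional HRV statistics still look normal. `drowsecg` implements
the complete analysis chain needed to study this claim:

1. **Synthetic driving sessions** — a latent drowsiness state D(t) ∈ [0,1]
   (logistic ramp) drives RR dynamics (RR lengthening, LF→HF power shift), a
   template-beat capacitive-style ECG at 500 Hz with motion-artifact bursts,
   behavioral indicators (PERCLOS, blinks, yawns, head pose) lagging
   physiology by a configurable delay, lane/steering telemetry at 60 Hz, and
   rare crash events from an impairment-proportional hazard plus lane
   departures.
2. **ECG preprocessing** — 4–35 Hz zero-phase Butterworth filtering, a
   derivative-energy R-peak detector with block-adaptive thresholding,
   rejection of implausible RR intervals (outside 300–2000 ms), and
   segment-level signal-quality exclusion (absolute deviation, kurtosis,
   5–15 Hz band-power ratio).
3. **HRV derivatives** — cubic-spline resampling of the tachogram to a
   uniform 4 Hz grid, then central differences

   dRRI/dt ≈ (RRI(t+Δt) − RRI(t−Δt)) / 2Δt,
   d²RRI/dt² ≈ (RRI(t+Δt) − 2·RRI(t) + RRI(t−Δt)) / Δt²,   Δt = 0.25 s.

4. **35 features per 30 s window** (50% overlap): 12 derivative statistics,
   11 time/frequency HRV metrics (Lomb-Scargle spectra), 8 behavioral, 4
   driving-performance features; per-participant z-scoring and linear
   imputation.
5. **Labels** — a behavioral score
   S = 0.40·PERCLOS + 0.25·Yawn + 0.20·Blink + 0.15·Posture with
   Alert/Light/Moderate/Severe buckets, and an independent binary
   *crash-proximity* label (window ends within 60 s before a crash) that no
   physiological feature can leak into.
6. **Classifier** — a gated transformer encoder (feature embedding,
   learnable positional encoding, pre-norm multi-head self-attention, GELU
   FFN, sigmoid gate on the pooled sequence, 2-layer head) over sequences of
   T = 10 consecutive windows, trained with AdamW, cosine annealing,
   label-smoothed inverse-frequency-weighted cross-entropy, stratified
   batches, early stopping, and validation-set threshold optimization; plus
   a logistic-regression baseline. Implemented in NumPy on a small
   gradient-checked reverse-mode autodiff core.
7. **Evaluation** — participant-level k-fold and leave-one-subject-out CV
   with leakage guards, feature-group ablation, accuracy/F1/AUC, and the
   temporal lead-time analysis: per crash, the earliest classifier
   probability > 0.5, PERCLOS > 15%, and sustained yawn-signal exceedance
   within a 15 min pre-crash window, compared by exact paired Wilcoxon
   signed-rank tests with rank-biserial effect sizes.

## Worked example

```python
from drowsecg import SimConfig, generate_session, preprocess_ecg
from drowsecg.derivatives import resample_rr_uniform, derivative_blocks
from drowsecg.features import extract_features

cfg = SimConfig(duration_s=600, drowsiness_onset_s=240, seed=7)
rec = generate_session(cfg)
rr, reports, excluded = preprocess_ecg(rec.ecg, rec.ecg_rate)
blocks = resample_rr_uniform(rr)
d1, d2 = derivative_blocks(blocks)
feats = extract_features(rr, d1, d2, rec.behavioral, rec.driving,
                         rec.duration_s, "P01", "S01")
```

prints (via the obvious `print` statements):

```
session: 300000 ECG samples at 500 Hz, 0 crash(es)
beats detected: 671, RR retained: 668/670, segments excluded: 0.0%
windows: 39
mean RR     first->last window:   813.2 ->   942.6 ms
HF power    first->last window:    27.8 ->    72.8 ms^2
|d1| max    first->last window:    45.4 ->    58.4 ms/s
PERCLOS     first->last window:   0.026 ->   0.169
```

The 10 min session ramps into drowsiness at 4 min: mean RR lengthens by
~130 ms, high-frequency (parasympathetic) power roughly triples, the
first-derivative magnitude rises during the transition, and PERCLOS — which
lags physiology by the configured 6 min — has barely started to move by the
session's end. That ordering is exactly the early-warning window the
derivative features are designed to exploit.

The full pipeline (simulate → preprocess → derive → featurize → label →
train → evaluate → leadtime) is one command:

```
drowsecg all --seed 3 --out runs/demo          # or: drowsecg simulate/--stage-- ...
```

Every stage writes plain CSV/JSON into the run directory, reruns are
byte-identical, and each stage can be re-run alone from cached upstream
outputs.

## Layout

```
src/drowsecg/
  simulate.py      synthetic sessions, cohorts, session CSV/JSON IO
  ecg.py           filtering, R-peak detection, RR screening, SQI
  derivatives.py   uniform resampling + finite-difference derivatives
  features.py      the 35-feature window set, normalization, imputation
  labeling.py      behavioral score/levels + crash-proximity labels
  classifier.py    gated transformer (NumPy autodiff) + linear baseline
  evaluation.py    CV splits, metrics, Wilcoxon, ablation, lead times
  experiments.py   canned lead-time and ablation studies
  pipeline.py      staged, cached, deterministic end-to-end runs
  cli.py           `drowsecg` command-line interface
docs/methods.md    model, parameter, and calibration documentation
```
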