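# Methods

This note documents the models, parameter choices, and calibrations behind
`drowsecg`, in the order the pipeline runs. Everything quantitative stated
here is either a design definition or a quantity the test suite /
`scripts/acceptance.py` computes at run time.

## 1. Synthetic driving sessions

**Latent state.** Each session carries one latent drowsiness series
D(t) ∈ [0,1]: a logistic ramp `expit(k·(t − t₀))` centered at
`drowsiness_onset_s` (t₀) with steepness `onset_steepness` (k, 1/s), plus
bounded smooth noise (Gaussian noise low-passed with a 30 s kernel,
rescaled to max amplitude `latent_noise_amp` = 0.04) and clipped to [0,1].
A logistic ramp is the simplest monotone alert→drowsy transition; smoothed
rather than white noise keeps derivatives of downstream signals meaningful.
With k = 0.01 (default), the 10–90% transition spans ≈ 7 min, a gradual
onset typical of monotonous-highway protocols.

**RR dynamics.** Beat-to-beat intervals are

RR(t) = RR₀ + g·D(t) + A_LF·(1 − 0.6·D)·sin(2π·0.1·t)
      + A_HF·(0.3 + 0.7·D)·sin(2π·0.25·t) + ε,  ε ~ N(0, σ²)

with defaults RR₀ = 800 ms, drowsy gain g = 150 ms, A_LF = 30 ms,
A_HF = 20 ms, σ = 8 ms; values are clipped to the physiological 300–2000 ms
band and beat times are the cumulative sum of intervals (first beat at
0.5 s so its template is complete). The LF amplitude shrinks and the HF
amplitude grows with D, encoding the sympathetic→parasympathetic shift; the
0.1 / 0.25 Hz carriers sit in the centers of the conventional LF/HF bands.

**ECG.** Each beat is an analytic template (Gaussian R spike σ = 12 ms,
amplitude 1; P hump −180 ms, 0.12; T hump +280 ms, 0.25) summed onto a
500 Hz grid, plus <1 Hz baseline wander (amplitude 0.15), white noise
(SD 0.02), and Poisson motion-artifact bursts: broadband noise railing at
±8 (>5× QRS), duration 0.5–1.5 s at `artifact_rate` bursts/min (default
0.5). The template is sufficient to exercise R-peak detection and the SQI;
it is *not* a diagnostic ECG model. Burst duration reflects brief posture
shifts; the long-burst regime used to study segment exclusion (15–25 s
leaning/shifting episodes) is configured explicitly where needed.

**Behavioral streams (1 Hz).** All indicators are driven by the lagged
latent state D_b(t) = D(t − `behavioral_lag_s`), default lag 360 s:
PERCLOS = 0.02 + 0.38·D_b (alert ≈ 2%, saturating toward ~0.40), yawn
frequency 0.1 + 3.9·D_b /min, a continuous yawn-intensity (mouth-opening
proxy) channel 0.08 + 0.90·D_b, blink frequency 12 + 14·D_b /min, blink
duration 0.18 + 0.30·D_b s, head pitch drift, yaw wander, and a head-pose
variance channel — each with bounded smooth noise. Two calibrations are
anchored to published detector behavior: PERCLOS crosses the 15% detection
threshold at latent quantile (0.15−0.02)/0.38 ≈ 0.34, and the
yawn-intensity slope is set so the sustained-yawn detector (>0.6 for >2 s)
trails the PERCLOS detector by ≈ 1.6 min — the spacing between the two
behavioral detectors' reported lead times.

**Driving (60 Hz).** Lane position follows a mean-reverting (OU) walk,
θ = 0.15 /s, with innovation SD scaled so alert SDLP ≈ 0.25 m rising to
≈ 0.45 m at full drowsiness (`driving_noise_gain` = 0.8) — the standard
alert/impaired SDLP range. Steering is a stabilizing response
(−4·lane − 1.5·lateral velocity) plus drowsiness-scaled smooth noise.

**Crashes.** Two mechanisms: (i) lane departures — first up-crossings of
|lane| ≥ 1.8 m with a 30 s refractory; (ii) a Bernoulli-per-second hazard
`crash_hazard_scale · D(t − driving_lag_s)`. Severity is drawn minor/major
at ≈ 7:1. Default hazard 1.5×10⁻⁴ /s keeps, over 90 min sessions, the
fraction of raw samples within 60 s of a crash below 1% (the extreme class
imbalance the classification design must cope with); test fixtures and the
lead-time study elevate the hazard explicitly, since desk-scale studies
need hundreds of crashes.

**Reproducibility.** All draws derive from one `SeedSequence` per session
with fixed spawn keys per sub-stream (latent, RR, ECG, behavioral, driving,
crashes); identical config ⇒ byte-identical session files. Cohorts add
per-participant baseline-RR jitter (SD 40 ms) and per-session onset jitter
(SD 120 s).

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: ECG morphology variation and arrhythmia,
triboelectric/coupling physics of capacitive electrodes, road vibration,
circadian/time-on-task structure beyond a single monotone ramp, blinks or
yawns as discrete events (rates and intensities are continuous channels),
and non-stationary individual differences beyond baseline shifts.

## 2. ECG preprocessing

Band-pass 4–35 Hz, 4th-order Butterworth, applied forward-backward
(`sosfiltfilt`), so peaks do not shift. R peaks come from a
derivative-energy detector: squared first difference, 150 ms moving-average
envelope, threshold = 0.35 × a robust local scale (median over ±5 of the
2 s block maxima, each block maximum clipped at 1.5× the session-median
block maximum so clustered artifact bursts cannot inflate the threshold),
0.3 s refractory, peak refinement to the filtered-signal maximum within
±50 ms, and suppression of saturated regions (envelope >10× the median
block maximum, dilated 0.2 s) where no genuine beat is recoverable.

RR intervals outside 300–2000 ms are masked (values kept for audit).
Per 10 s segment, three SQI indices decide exclusion:

* absolute deviation about the segment median — **mean** absolute
  deviation by default (threshold 0.25 in QRS-amplitude units): a median
  variant is provided but is by construction insensitive to bursts covering
  <50% of a segment, which defeats the index's purpose of catching large
  motion artifacts;
* Pearson kurtosis (Gaussian = 3) with a lower bound of 3.5 — QRS-bearing
  segments are heavy-tailed, flat or noise-only segments are not; a
  zero-variance segment has undefined kurtosis and is excluded;
* 5–15 Hz periodogram power fraction with a lower bound of 0.15 — QRS
  energy concentrates in this band.

Thresholds are calibrated to the generator's unit QRS amplitude and are
config, not literature, values; real recordings need rescaling. An RR
interval is masked when either bounding beat falls in an excluded segment.

## 3. Uniform resampling and derivatives

The retained tachogram (each RR anchored at its end-beat time) is
interpolated with a natural cubic spline and evaluated on the 4 Hz grid
inside the data span — no extrapolation. Gaps longer than 5 s (artifact
exclusions) split the series into independently resampled blocks so the
spline never invents dynamics across a gap. Derivatives use the central
difference and the three-point stencil at interior points only (each
differentiation trims one sample per side); both are exact on polynomials
of the matching degree and carry the standard sin(ωΔt)/(ωΔt) attenuation on
sinusoids, which the tests verify in closed form.

## 4. Features

30 s windows, 50% overlap (starts every 15 s; a span S yields
⌊(S−30)/15⌋+1 windows). Per window:

* 12 derivative features — mean, SD (n−1), RMS, max |·|, zero-crossing
  rate (sign changes per second of sampled span; exact zeros carry the
  previous sign), OLS slope — for d1 and d2;
* 11 base HRV — mRR, SDNN, RMSSD, pNN50, triangular index (bin width
  1/128 s), and Lomb-Scargle band powers on a 0.003–0.5 Hz grid of 256
  frequencies (trapezoid integration; LF 0.04–0.15, HF 0.15–0.40 Hz,
  total 0.003–0.40 Hz, normalized units on LF+HF). The 30 s window is
  below the conventional ~250 s recommendation for LF reliability; LF
  values are short-window classifier inputs, flagged as such in the
  feature manifest, not clinical readings;
* 8 behavioral — PERCLOS over the trailing **1 min** (its conventional
  horizon; all other features use the 30 s window), blink frequency and
  duration, yawn frequency, mouth-opening (yawn-intensity) mean, head
  pitch, head yaw, and head-pose variance (var(pitch)+var(yaw) within the
  window);
* 4 driving — SDLP, steering reversal rate (extremum-to-extremum swings
  ≥2°, per minute), mean |steering|, and minimum time-to-line-crossing
  (lateral position + velocity projected to the 1.8 m boundary, capped at
  30 s).

Features are z-scored **per participant** over all of that participant's
windows (self-normalization; never across participants, so participant-
level CV splits stay leak-free — at the documented cost of using a
participant's full recording for their own normalization constants, as no
online variant is specified). Missing values are linearly interpolated per
session and feature, edges filled with the nearest value; a session-feature
over 20% missing raises an error rather than fabricating a trend.

## 5. Labels

Behavioral score S = 0.40·PERCLOS + 0.25·Yawn + 0.20·Blink + 0.15·Posture
on [0,1]-scaled indicators; buckets Alert (S<0.25), Light (0.25≤S<0.40),
Moderate (0.40≤S<0.60), Severe (S≥0.60). The score's published form leaves
the indicator scalings open; this package uses saturating maps
f/(f+f₀) with f₀ = 3 yawns/min and 30 blinks/min, and posture =
min(head_var/25 deg², 1) — config-exposed reconstructions.

The evaluation label is crash proximity alone: a window is positive iff its
**end** time t satisfies t_crash − 60 ≤ t < t_crash for any crash. The
function receives only window times and crash times, so no physiological or
behavioral quantity can leak into the label. Overlapping pre-crash windows
of nearby crashes are not de-duplicated.

## 6. Classifier

Architecture (full preset): linear embed 35→128, learnable positional
embeddings over T = 10 windows, 6 pre-norm encoder layers (8 heads ×
16-dim, FFN 512, GELU, dropout 0.1), global average pooling, a sigmoid
gate g = σ(W_g·pool + b_g) applied elementwise to the pooled vector
(letting the model reweight features per input, e.g. across participants),
then a 64-unit ReLU head and 2-class softmax. The reduced preset
(2 layers, embed 32, 4×8 heads, FFN 64) is the default for test-scale work.

Training: AdamW (lr 3×10⁻⁴, weight decay 0.01), cosine annealing,
label-smoothed (ε = 0.1) cross-entropy with inverse-frequency class weights
normalized to mean 1, stratified half-positive/half-negative mini-batches
(minority resampled), early stopping on validation AUC (patience 15; ties
broken toward the later epoch, since AUC is threshold-free and often
plateaus while the decision boundary is still settling), and **validation
threshold optimization**: the balanced-accuracy-optimal threshold τ* is
folded into the reported probability by the monotone logit shift
p ↦ σ(logit(p) − logit(τ*)), so the operating convention "positive iff
p > 0.5" coincides with the optimized operating point while AUC and
probability ordering are untouched. Without this step the raw probabilities
of a heavily reweighted model are miscalibrated and threshold-crossing
detection times become erratic.

Everything runs on a small reverse-mode autodiff engine over NumPy arrays
(broadcast arithmetic, batched matmul, reductions, shape ops), gradient-
checked against central finite differences in the test suite. Sequences are
built from runs of strictly consecutive windows (stride 1; runs shorter
than T dropped; label = last window). A sequence's probability is
time-indexed by its last window's end. An L2-regularized logistic
regression on single-window features serves as the sanity baseline.

## 7. Evaluation

Participant-level k-fold CV shuffles participants once per seed, partitions
them into k near-equal test groups, and reserves ~15% of the remaining
participants (≥1) for validation — all three sets are disjoint *participant*
sets, asserted on every use. LOSO-CV makes each participant the test set
once. Metrics: accuracy and positive-class F1 at p > 0.5, and AUC by the
Mann-Whitney rank statistic with midranks (the primary metric: under
extreme imbalance a trivial all-negative predictor scores near-perfect
accuracy with F1 = 0).

The Wilcoxon signed-rank test drops zero differences, midranks ties, and
enumerates the exact null of W⁺ by dynamic programming over doubled
midranks for n ≤ 25 (normal approximation with tie correction above);
effect size is the matched-pairs rank-biserial correlation
(W⁺−W⁻)/(W⁺+W⁻). The implementation is tested against brute-force
enumeration of all sign assignments.

Lead times: for each crash, the earliest time in [t_crash − 900 s, t_crash)
(left edge included) at which (i) the classifier probability exceeds 0.5,
(ii) PERCLOS exceeds 0.15, (iii) the yawn-intensity signal exceeds 0.6 for
more than 2 s. A crash is a valid record only if all three detections
exist. Two planned paired tests (HRV vs PERCLOS, HRV vs yawn) are reported
unadjusted; a Holm option exists in config.

The ablation retrains the same model spec from scratch per feature subset
(complete, without-derivatives, driving-only, HRV-complete,
derivatives-only and the per-order reduced sets) with the shared seed and
pools held-out predictions across folds.

## 8. The lead-time recovery experiment

The headline property is parameter recovery: the generator encodes a known
physiology-to-behavior lag (360 s), and the evaluation pipeline should
measure it as the mean difference between the HRV-classifier lead and the
PERCLOS lead over hundreds of crashes.

The detector model is trained on **HRV features only** (12 derivatives + 11
base metrics): the probability series must reflect cardiac physiology, not
the behavioral or driving streams it is being compared against — a
full-feature model keys on driving telemetry and its crossing time then
measures the driving lag instead.

Two systematic offsets shape where the classifier crossing lands on the
drowsiness ramp, and the scenario is designed so they cancel:

* *Operating-quantile offset.* A threshold detector fires when its signal
  crosses a fixed quantile of the latent ramp: PERCLOS > 0.15 corresponds
  to quantile ≈ 0.34 under the generator mapping. The classifier's
  crossing quantile is emergent — with inverse-frequency weighting it
  settles near the session's drowsy-time fraction — so sessions are built
  with ≈ 30% drowsy time (2000 s, onset 1400 s) to align the two
  quantiles. Crashes are driven by the impairment hazard with *zero*
  additional driving lag (crashes are caused by the impairment directly),
  so pre-crash positives sample the whole ramp rather than only its
  plateau.
* *Content trailing.* A sequence's probability is indexed at its last
  window's end, but its content averages the preceding 165 s, trailing the
  index by ≈ (T−1)/2·15 + 15 ≈ 82 s. The residual quantile offset scales
  as 1/k while the trailing term does not; onset steepness k = 0.015 (a
  still-gradual ≈ 5 min transition) balances the two.

Each run trains an ensemble of three reduced-preset detectors (rotated
validation participants and initialization seeds) and assigns evaluation
sessions round-robin, averaging out residual run-to-run variation in any
single model's crossing point. 115 evaluation sessions yield well over 200
valid crash records in a few minutes on one CPU; crashes occurring before
the behavioral detectors can fire produce invalid records and drop out,
mirroring the study design's valid-detection filter. The recovered gap, its
Wilcoxon test, the rank-biserial effect size, and the HRV-first fraction
are computed by `tests/test_acceptance.py` and `scripts/acceptance.py`.

## 9. Numerical and degenerate-input conventions

Natural spline boundaries (zero second derivative); derivatives undefined
at block edges rather than one-sided; zero-variance features set to 0 with
a degeneracy flag under z-scoring; LF/HF ratio undefined (missing) when
HF = 0; AUC undefined (flagged) for single-class labels; Wilcoxon
degenerate (all zero differences) flagged with r_rb = 0; kurtosis undefined
on constant segments (segment excluded); window "sample time" is always
the window end. CSV outputs use fixed 6-decimal formatting so repeated runs
are byte-identical.

## 10. Known limitations

The generator's monotone single-onset ramp cannot probe recovery from
drowsiness, fluctuating vigilance, or alerting events. Feature noise levels
are more benign than capacitive recordings in moving vehicles. The
lead-time recovery depends on the documented quantile-matching design; on
real data, where the latent state and its mapping to indicators are
unknown, the measured gap estimates the detector-crossing difference, not a
pure physiological lag. The classifier's published-scale preset (6 layers,
128-dim) is implemented but routinely exercised only in reduced form; the
NumPy engine is single-threaded and not suited to large-scale training.
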