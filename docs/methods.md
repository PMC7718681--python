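# Methods

## Signal model and preprocessing

IMU channels (tri-axial accelerometer and gyroscope, 50 Hz) are band-pass
filtered at 0.3–20 Hz with a 2nd-order Butterworth: the low edge suppresses
drift and gravity leakage, the high edge bounds the band of voluntary human
movement. Spectral features additionally apply a 6th-order 2–5 Hz
Butterworth, the band where cerebellar intention tremor and the repetitive
test movements live. Both filters run zero-phase (forward–backward,
`sosfiltfilt`), which doubles the effective order but preserves event timing
across channels — a deliberate choice, since several features compare the
timing of events between signals. The 2–5 Hz filter is applied *on top of*
the 0.3–20 Hz-filtered signal; this ordering is an assumption (the two bands
barely interact, so the composition is benign).

Angular acceleration is the central finite difference of angular rate
(one-sided at the ends); angle is the cumulative trapezoid of angular rate
with the mean removed to suppress residual drift. These are the lowest-order
unbiased schemes; their discretisation error (a `sinc(ω·dt)` gain) is
asserted exactly in the tests.

## Features (62)

Per hand: FCT contributes DTW error, reaction time and acceleration
alterations per screen axis plus one Fitts'-law kinematic delay (7×2 = 14);
FTT contributes the inter-tap-interval coefficient of variation and fuzzy
entropy of accel X, accel Z and gyro X (4×2 = 8); FNT contributes RF/MR of
angular acceleration on X/Y/Z and linear acceleration X, and RF only of
linear acceleration Y/Z (10×2 = 20); DDKT contributes RF/MR of the angle and
the linear acceleration on X/Z and of angular acceleration Y (10×2 = 20).
Each feature carries exactly one STAR tag; for the FNT linear-acceleration
channels the tag follows the axis-role rule of the angular channels (X/Z →
Stability; on the primary axis Y, RF → Timing and MR → Rhythmicity).

Implementation notes:

* **DTW error** returns the accumulated cost `DS(n,m)` of the optimal
  monotone warping path under absolute-difference local cost. (A literal
  "sum the cumulative matrix along the backtracked path" reading would
  double-count accumulated costs; the standard accumulated cost is used.)
  Computed per axis on trial-mean-subtracted position; numba-compiled.
* **Reaction time** restricts the cross-correlation to non-negative lags
  (the marker can only trail the target) and converts the argmax lag to ms.
* **Kinematic delay** computes, per reach, `ID = log2(di/ra)` from the 2-D
  distance between consecutive target centres, and `MT` as the time from
  target onset to the first sample with marker–centre distance ≤ `ra`. The
  search window ends at the next target onset (the target disappears then),
  so the inter-event interval caps MT; a reach whose marker never enters the
  disc in its window is excluded and logged, and a trial with no valid reach
  is an error. One value per hand (2-D geometry), counted once in the
  catalog. A reach with `di ≤ ra` has no difficulty and contributes 0.
* **Acceleration alterations** counts sign changes of the second difference
  of position, after a 5-sample moving average (raw 30 Hz pixel second
  differences are noise-dominated; the window is in the config).
  Accelerations below 1e-8 of the position scale are treated as zero. The
  operation returns the per-reach mean; the catalog stores the per-trial
  total (mean × 20 reaches), the scaling on which group means are
  conventionally quoted — either is derivable from the other.
* **Tap detection** (the protocol does not prescribe one): peaks of
  |accel Z| above 3× the median absolute deviation, separated by ≥ 150 ms.
  This rule presumes tap transients of finite width that lift the MAD above
  the inter-tap baseline — true of real contact transients and of the
  generator's biphasic impact pulses; it is not robust to a signal that is
  pure white noise plus ideal spikes.
* **Fuzzy entropy** follows the defining equations literally: templates of
  length m (and m+1) drawn with `N−m` (resp. `N−m−1`) starting points,
  mean-centred per template (standard practice for the statistic, which its
  defining papers leave implicit), Chebyshev distances, Gaussian-of-order-2
  similarity, self-matches excluded. Computed on the 0.3–20 Hz band, not the
  2–5 Hz band. Defaults m = 3, r = 0.2·std(y).
* **RF/MR** uses a Hann window and zero-padding to ≥ 1024 points for stable
  peak location; the single-sided spectrum is amplitude-normalised (a tone
  of amplitude A reports MR = A) and the DC bin is excluded, constraining
  RF to (0, Nyquist). Magnitudes are reported in input units; no conversion
  to sensor millivolts is attempted.

## Statistics

Group differences use a Shapiro–Wilk gate at α = 0.05 per group: both normal
→ two-sample t-test, otherwise Wilcoxon rank-sum. The effect size is always
Cohen's *d* with pooled SD, the convention under which the study's power
design value (minimum detectable d for 14 vs 41 subjects at 80 % power,
two-sided α = 0.05) evaluates to 0.88. That quantity is solved by bisection
of the noncentral-t power function to 1e-6. No multiple-testing correction
is applied, mirroring the per-feature α = 0.05 presentation convention.

## Feature selection

FBE draws 90 % of subjects (stratified by group so both classes appear),
fits an OLS model of the SARA upper-limb sum on the candidate features, and
repeatedly removes the feature with the largest partial p-value above α
until all survivors are significant. The "p-value of a feature given the
currently selected set" is implemented as the nested-model partial F-test,
which for a single column equals the squared coefficient t-test. The
procedure repeats 100 times; a feature's selection frequency is its survival
fraction, with ties broken by mean partial F. A vanishing Tikhonov jitter
(1e-10 of the Gram trace) keeps near-collinear designs numerically honest —
duplicated features then show the huge standard errors they deserve and
split survivals rather than both passing. When candidate features exceed
rows − 2, a marginal-correlation prefilter reduces the set first (logged).
The continuous SARA-UL sum is the response; a binary-label variant exists
behind a flag but is not the default. Baselines: random-forest permutation
importance, a plain ReliefF (k = 5 hits/misses; no established Python
implementation is available in the stack, so it is written here), and the
activation order along the LASSO regularisation path.

## Diagnosis and severity

LD, QDA, SVM (RBF) and KNN are evaluated by leave-one-out over subjects,
with standardisation computed on each training fold only. Hyperparameters
the protocol leaves open, all surfaced in the config: QDA uses the eigen
solver with Ledoit–Wolf per-class covariance shrinkage — at the clinical
operating point (14 controls, 22 features) a fixed small shrinkage leaves
the class covariance degenerate, while Ledoit–Wolf adapts to the
sample-to-dimension ratio; SVM uses the median-heuristic RBF bandwidth per
fold; KNN uses k = 5. Class imbalance (41:14) is left as-is and MCC is
reported to expose it. AUC comes from the pooled held-out scores.

Severity: ridge regression of the SARA-UL *sum* (0–15 — chosen over other
composites because the bucket thresholds reach 10), with the penalty chosen
by inner leave-one-out over a log grid 1e-3…1e3 within each outer fold
(`RidgeCV`'s closed-form LOO). Held-out predicted scores are bucketed at
4/7/10 (half-open intervals exactly as defined) and cross-tabulated against
the clinical level `round(SARA-UL/3)`. Note the two scales' boundaries are
offset by construction (bucket edges 4/7/10 vs rounding edges 4.5/7.5/10.5),
so exact-level agreement is conservative while within-one-level agreement is
the meaningful recovery measure.

Test-combination analysis re-runs selection + LOO + severity on the feature
subsets of each test pairing (FCT+FTT, FCT+FNT, FCT+DDKT, the three triples,
and all four), reporting metrics, severity correlation and STAR composition
per combination.

## Synthetic cohort generator

The generator emulates the study conditions: 55 subjects by default with the
41:14 ataxic:control split; ataxic severities uniform on [0.5, 3.0],
controls at s = 0. Every knob is affine in s with its direction fixed by the
clinically expected group differences: reaction delay 750 + 140·s ms
(calibrated so extracted cross-correlation reaction times land near ~750 ms
for controls and ~1100 ms for severe subjects — the internal motor latency
is the knob minus half the reach duration, because the cross-correlation
lag of a smoothed step response sits mid-rise), overshoot gain 0.02 + 0.06·s
of the jump distance, tremor 1 + 6·s px, inter-tap CV 0.05 + 0.08·s,
broadband movement texture 1 − 0.25·s (complexity loss: amplitude of the
irregular component *falls* with disease), primary oscillation 3.5 − 0.3·s
Hz at amplitude 1.5 − 0.35·s, secondary-axis leakage 0.1 + 0.3·s. The
severity-to-SARA link is linear with rounding noise:
`SARA-UL = clip(round(3·s + ε), 0, 15)`, ε ~ N(0, 0.5).

Design choices worth knowing:

* Reaches are minimum-jerk (smooth, physiological, closed-form for oracle
  tests); tremor is 2–5 Hz band-passed noise rather than a pure tone, so
  spectral peaks are realistic but detectable.
* Intention tremor is gated by movement speed (with a small postural floor).
  This matters because acceleration-alteration counts are amplitude-blind —
  they respond to the *spectral composition* of the signal, so the severity
  effect must come from tremor outweighing the smooth reach during
  movement; additive white marker noise would pin the count at the
  noise-flip rate for everyone, which is why the marker noise default is 0.
* FCT targets jump a fixed distance in jittered near-diagonal directions
  inside a central disc. Free random-walk targets would wander across the
  screen and dominate the trial-mean-removed trajectories, masking severity
  in the DTW error.
* Tap contacts are zero-mean biphasic transients (a deceleration–rebound
  pulse) over a gentle sub-threshold oscillation; a unipolar spike train
  would shift baseline under the band-pass and confuse the MAD threshold.
* DDKT receives severity-independent log-normal subject variability
  (amplitude, leakage, frequency; sd 0.5) — rapid alternating movement is
  idiosyncratic even among healthy subjects — so the four tests are not
  equally informative by construction.

What the generator does **not** emulate: biomechanically coupled limb
dynamics, sensor bias/orientation error, disease-subtype signatures,
learning/fatigue across the trial, and realistic between-feature noise
correlation. Passing tests therefore demonstrate that the pipeline recovers
known monotone structure under the stated noise model — not clinical
performance on real recordings.

## Problem sizes and numerical choices

The reference study condition for the end-to-end tests is a 100-subject
cohort at seed 0: selection over 100 subsample iterations, QDA on the top-22
features, ridge severity with inner LOO. The DTW oracle in the tests
enumerates all monotone paths exhaustively for sequences up to length 6; the
fuzzy-entropy oracle is a literal double loop at N = 10. Degenerate inputs
fail loudly: zero-variance series for reaction time or Spearman, all-zero
signals for spectral peaks, < 4 detected taps, empty DTW inputs, a zero MCC
denominator is defined as 0 and logged. Missing recordings yield missing
features; subjects missing any feature used by a model are excluded from
that fit (logged) — no imputation is attempted.

## Known limitations

* The catalog is the canonical 62-item enumeration; a variant count of 64
  appears in some descriptions of this protocol and is not modelled.
* Reported RF is constrained to (0, Nyquist); published values above the
  Nyquist of a 50 Hz recording (e.g. a 40 Hz resonant frequency) cannot be
  produced and are treated as unit/indexing artefacts upstream.
* The FBE null ("feature independent of the predicted score") is
  operationalised as a linear partial F-test; nonlinear conditional
  dependence is invisible to it.
* Severity buckets and clinical rounding use offset boundaries (see above),
  so the exact-agreement diagonal understates recovery by design.
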