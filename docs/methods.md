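# Methods

## Problem and pipeline

`semgpipe` implements a complete surface-electromyography (sEMG)
hand-gesture classification analysis for four forearm muscles — Extensor
Digitorum (ED), Palmaris Longus (PL), Flexor Carpi Ulnaris (FCU) and
Extensor Carpi Radialis (ECR) — sampled at 1024 Hz.  Fifteen gesture
classes are distinguished: rest, and grasp / radial deviation / ulnar
deviation / four finger pinches, each with the forearm pronated or
supinated.  The pipeline is

1. **simulate** annotated recordings (no subject data are distributed, so a
   synthetic generator stands in for the cohort; see below),
2. **segment** the signal into overlapping windows of 250 ms (256 samples),
   stepped by 125 ms (128 samples),
3. **extract** six features per channel and window — waveform length
   `y = Σ_r |t_r − t_{r−1}|`, windowed RMS `m_rms = sqrt(Σ m_i² / n)`, and
   the four coefficients of an autoregressive model
   `t_n = Σ_{i=1..4} q_i t_{n−i} + w_n` — giving 24-dimensional feature
   vectors,
4. **classify** with a one-vs-one multi-class soft-margin SVM
   (`min ½‖w‖² + c Σ ξ_n`) with RBF kernel
   `k(x_i, x_j) = exp(−γ‖x_i − x_j‖²)`, tuning `(c, γ)` by stratified
   8-fold cross-validated grid search over `c ∈ (0, 100]`, `γ ∈ (0, 3]` on
   a 90 % training partition (stratified; the remaining 10 % is the test
   set),
5. **evaluate** per-subject accuracy and 15×15 confusion matrices, the
   adjacent-finger pinch-confusion fraction, and cohort summaries
   (group means, senior-vs-young force/torque decrease in percent,
   accuracy decrease in percentage points, accuracy-vs-strength linear
   fits).

## Synthetic sEMG generator

The generator is first-class, tested code; its defaults define the study
conditions the acceptance suite runs under.

**Signal model.**  Per channel,

    x(t) = (noise_floor + envelope(t) · activation[m, class(t)]) · carrier(t)

- `envelope(t)` is a trapezoidal effort profile per protocol event
  (0.25 s ramps) at the event's target level — 50 % MVC for sustained
  grasps and wrist deviations, a comfortable 35 % for pinches — modulated
  by a slow (1–2.5 Hz) sinusoidal tremor of depth 0.03.
- `activation` is a 4×15 matrix of per-muscle engagement in [0, 1],
  grounded in muscle function (FCU drives ulnar deviation, ECR radial
  deviation, ED finger/wrist extension, PL wrist flexion).  Pinch columns
  vary along a finger axis with the middle- and ring-finger positions
  deliberately close, because those pinches share most of their forearm
  synergy; this reproduces, by construction, the classic middle↔ring
  confusion observed in real recordings.  Supinated gestures load the
  flexors more and the extensors less; supinated pinches nearly silence
  ECR so the two pinch families do not overlap.
- `carrier(t)` is unit-variance resonant Gaussian noise: white noise
  filtered by an AR(2) pole pair of radius 0.82 whose angle rises from
  0.15π toward 0.80π with muscle activation — emulating the upward shift
  of the sEMG power spectrum as faster motor units are recruited — then
  band-limited to 20–450 Hz with a 4th-order Butterworth (sEMG carries its
  usable energy below ~500 Hz; the 20 Hz high-pass suppresses the
  motion-artifact band).  The spectral shift is what makes the AR
  coefficients class-informative rather than pure estimation noise.
- Per event, each muscle's activation receives a multiplicative
  log-normal jitter (σ = 0.04) and the spectral angle a matching jitter
  (σ = 0.04): repeated gestures are similar, never identical.
- Force (N) and torque (N·m) tracks follow the envelope scaled by the
  subject's maxima; torque is signed, radial positive / ulnar negative.

**Subjects.**  A `SubjectProfile` carries maximum force and torque,
a `separability` in (0, 1] and a `noise_floor`.  Separability shrinks the
activation columns toward their mean pattern with a convex mapping
(contrast = separability^1.3): loss of gesture distinctiveness accelerates
at the low end, where reduced motor control blurs muscle patterns
disproportionately.  Group defaults place seniors at separability
0.60 ± 0.05 with maximum force 3.11 ± 1.2 N and torque 5.92 ± 2.0 N·m,
young subjects at 0.90 ± 0.03, 4.20 ± 1.0 N and 3.37 ± 1.2 N·m; seniors
also get a higher noise floor (0.065 vs 0.040 envelope units), reflecting
the lower signal-to-noise ratio of aged tissue.  These defaults were
calibrated once so that default cohort studies land near ~91 % mean senior
and ~96 % mean young accuracy, bracketing the reference values the
shipped cohort tables summarise.

**Protocols.**  Six timed schedules mirror a data-collection session:
C/FC — three 5 s grasps at 50 % MVC; D/FD — three repetitions of
alternating radial/ulnar deviation (four 1.25 s sub-events each, so the
torque sign alternates three times per repetition); E/FE — two 2.5 s
pinches per finger at a comfortable level.  The F-prefixed variants are
performed supinated.  Rest (class 1) comes from the inter-event gaps.
Event duration is a parameter (default 5 s) because sustained-event
lengths are the kind of protocol detail that varies between sessions.

**What the generator does not model:** motor-unit action potentials,
electrode placement and inter-channel crosstalk, fatigue drift within a
session, recording artifacts.  Passing end-to-end tests therefore shows
that the pipeline recovers the class structure this generative model
encodes — not that the same accuracy would be reached on any particular
real cohort.

## Segmentation and labelling

Windows are half-open sample intervals `[k·step, k·step + window)`;
trailing samples that do not fill a window are discarded (the feature
formulas assume full windows).  Labels come from the per-sample track
under two policies: `pure` (training default) drops windows straddling a
class transition; `majority` keeps every window with its modal label, ties
breaking toward the earlier-starting label.  An `event_margin_s` parameter
(default 0.3 s) additionally invalidates samples around every transition,
so training windows come from steady-state effort rather than the on/off
ramps.  Within each subject, windows are subsampled to at most
`max_windows_per_class` (default 40, seeded and deterministic) because
sustained grasps would otherwise outnumber brief pinches several-fold.

## Feature extraction

AR coefficients use the prediction-form sign convention (positive `q_1`
for positively lag-1-correlated signals).  Burg estimation is the default
— stable on 256-sample windows — with Yule-Walker (MLE autocovariances)
available for sensitivity checks; both estimators, as provided by
statsmodels, already return prediction-form coefficients.  The AR noise
variance is not included as a feature (six features per channel).
Waveform length and RMS scale linearly with the signal amplitude and AR
coefficients are amplitude-invariant; this scale equivariance is asserted
numerically in the tests.  Degenerate inputs (constant windows, windows
shorter than the AR order + 1) raise instead of returning silent NaNs,
naming the offending channel.

## Classification

Features are standardized to zero mean and unit spread with statistics
fitted on the training data only (re-fitted inside every CV fold); RBF
distances on raw features would be dominated by the large-scale amplitude
dimensions.  A zero-spread feature is centered and left unscaled, with a
warning.  The grid search evaluates every `(c, γ)` pair on identical
stratified fold assignments; ties in mean held-out accuracy break toward
smaller `c`, then smaller `γ` (preferring the smoother model).  The
default grid — `c ∈ {1, 5, 10, 15, 25, 45, 70, 100}`,
`γ ∈ {0.1, …, 3.0}` (13 values) — spans the search region where the
cross-validation surface peaks for this feature set.  The underlying
binary solver is scikit-learn's `SVC` (libsvm): its contract here is the
soft-margin objective and the one-vs-one majority vote (105 pairwise
classifiers for 15 classes; vote ties resolve to the lowest class id),
not any particular solver algorithm.  Cross-validation runs on the
training partition only, so the held-out test windows never influence
hyperparameter choice.

## Evaluation

Confusion matrices are oriented rows = true, columns = predicted.  The
adjacent-pinch fraction is the share of misclassified pinch windows whose
prediction is the adjacent-finger pinch in the same arm position
(pairs 5–6, 6–7, 7–8, 12–13, 13–14, 14–15); under uniform error spreading
this fraction would be ≈ 1.5/14 ≈ 0.107 (each pinch class has one or two
adjacent neighbours among 14 wrong labels), and the acceptance suite
requires the observed fraction to exceed that baseline.  Between-group
comparisons follow the conventions of the reference tables: force and
torque decreases are relative percent changes of the senior mean from the
young mean; the accuracy decrease is the percentage-point difference.

The package ships reference per-subject summary tables (12 seniors,
7 young) under `semgpipe/data/`; `cohort_summary` recomputes their group
statistics (senior 90.62 % / 3.11 N / 5.92 N·m; young 97.6 % / 4.20 N /
3.37 N·m; ≈26 % force decrease; ≈7-point accuracy decrease), which the
acceptance tests assert.

## Problem sizes, reproducibility, numerical choices

A default cohort study runs 19 subjects × 6 protocols (≈25 s of signal
each), ≈540 windows per subject before the per-class cap, a 104-point
grid × 8 folds per subject; it completes in a few minutes on one CPU.
One master seed deterministically derives every per-subject, per-recording
and per-split seed (via `numpy.random.SeedSequence` spawn keys), so a full
study is bit-reproducible from a single integer; the test suite asserts
byte-identical recordings, feature tables, grid surfaces and reports under
repeated runs.  Recording CSVs store floats with 17 significant digits and
are parsed with correctly-rounded float conversion, making write/read
round trips exact.  Stationarity of user-supplied AR coefficient sets is
checked via the characteristic-polynomial roots (strict unit-circle
interior).

## Known limitations

- The generator's class structure is low-dimensional (one activation
  pattern per gesture plus jitter); real sEMG exhibits richer trial-to-
  trial variability, electrode-shift nonstationarity and crosstalk.
- Per-subject test sets are small (≈50 windows), so individual test
  accuracies are quantized in steps of ~2 points; cohort means are the
  stable quantities.
- Force/torque-vs-accuracy fits are reported but the default generator
  couples accuracy to separability, not strength, so those correlations
  are weak by construction.
- No significance testing between groups is performed.
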