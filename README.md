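# semgpipe

Surface-electromyography (sEMG) hand-gesture classification, end to end:
simulate annotated 4-channel forearm sEMG, segment it into overlapping
windows, extract waveform-length / RMS / autoregressive features, train a
multi-class RBF-kernel SVM tuned by cross-validated grid search, and
evaluate per-subject and per-cohort performance.

## The problem

sEMG-controlled assistive devices for the hand need to recognize what the
wearer intends from forearm muscle activity alone.  The question this
pipeline addresses is whether fifteen everyday hand gestures — rest,
grasp, radial/ulnar wrist deviation and four finger pinches, in both
pronated and supinated arm positions — can be classified from only four
forearm muscles (Extensor Digitorum, Palmaris Longus, Flexor Carpi
Ulnaris, Extensor Carpi Radialis), and how much accuracy degrades in
seniors, whose gesture-specific muscle patterns are less distinct and
whose maximum strength is lower than in young adults.

## Method

Recordings sampled at 1024 Hz are cut into 250 ms windows (256 samples)
stepped by 125 ms.  Each window and channel yields six features:

- waveform length `y = Σ_r |t_r − t_{r−1}|` (signal complexity),
- windowed RMS `m_rms = sqrt((m_1² + … + m_n²)/n)` (amplitude),
- AR(4) coefficients `q_1..q_4` of `t_n = Σ q_i t_{n−i} + w_n`
  (spectral shape; Burg estimation),

for a 24-dimensional feature vector.  A one-vs-one multi-class soft-margin
SVM (`min ½‖w‖² + c Σ ξ_n`) with RBF kernel
`k(x_i, x_j) = exp(−γ‖x_i − x_j‖²)` is trained on a stratified 90 %
partition after per-feature standardization; `(c, γ)` are chosen by 8-fold
cross-validated grid search over `c ∈ (0, 100]`, `γ ∈ (0, 3]`, and the
held-out 10 % gives the reported accuracy and 15×15 confusion matrix.

Because no subject recordings are distributed, a seeded synthetic
generator (`semgpipe.synthetic`) stands in for the cohort: band-limited
(20–450 Hz) resonant Gaussian noise, amplitude- and spectrum-modulated by
per-gesture muscle activation patterns, organized into timed protocol
schedules with per-sample labels and force/torque tracks.  Senior and
young subject profiles differ in pattern separability, signal-to-noise
ratio and maximum strength.  See `docs/methods.md` for the model and its
assumptions.

## Worked example

Run a full default cohort study — 12 senior and 7 young synthetic
subjects, six protocols each, per-subject grid search and evaluation —
from one master seed:

```sh
semgpipe run-all --seed 42 --out results/
```

which prints (a few minutes on one CPU):

```
        accuracy_pct  max_force_N  max_torque_Nm
group
senior         91.88         3.14           5.85
young          97.50         4.53           3.01
accuracy decrease (young - senior): 5.62 points
max-force decrease: 30.5%
```

Read: the young cohort classifies at 97.5 % mean accuracy and the senior
cohort at 91.9 % — a 5.6-percentage-point cost of age-related pattern
blurring, even though maximum grip force drops by ~30 %.  Misclassified
pinch windows land overwhelmingly on the adjacent finger's pinch in the
same arm position (middle ↔ ring especially), the error mode expected
from synergistic forearm co-contraction.  `results/` contains per-subject
feature tables, grid-search surfaces, JSON reports, a
`cohort_summary.csv` (columns `subject, accuracy_pct, max_force_N,
max_torque_Nm`) and the resolved `config.yaml`.

The same stages are available as a library:

```python
from semgpipe import PipelineConfig, run_subject_pipeline, draw_profiles

profile = draw_profiles(1, "young", seed=42)[0]
report, grid, features = run_subject_pipeline(profile, PipelineConfig(seed=42))
print(grid.best, report.accuracy)
```

and as individual subcommands (`semgpipe simulate / features / train /
evaluate`) over documented CSV + JSON artifact formats.

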