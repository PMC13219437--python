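# Methods

## Problem and pipeline

The package classifies perceived stress from short multichannel EEG
recordings. Ground truth comes from the Perceived Stress Questionnaire
(PSQ): a cohort's scores define two symmetric thresholds, mu ± sigma/2, and
only subjects clearly below (non-stressed) or above (stressed) the band
enter the binary problem; the ambiguous middle is excluded. Each retained
subject's signal is cut into fixed-duration windows, 20 time-domain
descriptors are computed per window and electrode, windows are averaged
into one instance per subject (a per-window instance mode also exists),
features are ranked by information gain against the label, and the top-k
columns feed five standard classifiers under 10-fold cross-validation.
Golden Distance — the Euclidean distance of a classifier's published
(Av-NAV, Av-DCO) summary point from the ideal (1, 0) — condenses the
comparison into a single lower-is-better score. Av-NAV and Av-DCO are
accepted as inputs (a reference table of ten operating points ships with
the package); deriving them from base metrics is out of scope.

## Segmentation

Windows are half-open intervals [k·step, k·step + window) in seconds,
0-based in samples. Non-overlapping mode tiles a prefix of the recording
(window = step); overlapping mode slides by a 10 s step under a 20 s
default window (50% overlap — the window length is a free choice here,
only the step is fixed by convention). Trailing partial windows are
discarded rather than padded: a 480 s recording yields exactly 48
non-overlapping 10 s windows per channel, and padding would bias the
amplitude and difference features of the last window.

## Feature conventions

The descriptor set mixes moments, extremum geometry, discrete-difference
magnitudes, energy and histogram entropy. The deliberate numerical choices:

- **std** uses the n−1 divisor; **skew**/**kurt** are 1/n sums of
  standardized third/fourth powers (Gaussian kurtosis ≈ 3, not excess).
- **Latencies** (lmin, lmax) are 1-based first-occurrence indices divided
  by fs, so they lie in (0, T/fs] and ALAR = |amp_max|/lmax never divides
  by zero. First occurrence breaks ties deterministically.
- **mdif1/mdif2** divide the absolute first/second difference sums (taken
  over valid indices only) by N; the **norm** variants divide the same
  sums by N−1 and N−2 — so base and normalized variants differ only in
  divisor.
- **LAR** is read as lmax/amp_max, the mirror of ALAR without the absolute
  value; the referents of "latency" and "amplitude" are otherwise unbound.
- **Entropy** uses 64 equal-width bins spanning [min, max] (configurable)
  and the Shannon sign convention (−Σ c log₂ c ≥ 0); an `entropy_signed`
  toggle restores the raw signed sum. 64 bins is stable for the window
  sizes used here (10 s at 250–2500 Hz); entropy then ranges up to
  log₂ 64 = 6 bits.
- **Degenerate (zero-variance) windows** keep their row: skew/kurt and the
  ratio guards (pps, lar) are set to 0 and a flag is raised, because
  silently dropping rows would change instance counts downstream.

Instance granularity defaults to one row per subject (per-electrode,
per-feature means over windows): the published confusion-matrix totals
imply subject-level instances. The per-window mode is available but mixes
windows of one subject across CV folds, which leaks subject identity; use
it only to study feature stability.

## Labeling

Thresholds use the analyzed cohort's own mean and sample (n−1) standard
deviation by default; externally supplied (mu, sigma) are accepted.
Boundary equality is excluded — "below" and "above" are strict. For
Gaussian scores the excluded band holds 2Φ(0.5)−1 ≈ 38.3% of subjects.

## Information-gain selection

Continuous columns are discretized before the gain computation; the
default is equal-frequency with 10 bins (parameter-explicit and invariant
under monotone transforms of a feature), with equal-width and a supervised
entropy-minimization splitter with MDL stopping as alternatives. Gains are
in bits (log₂), clipped at 0, and bounded by the label entropy. Selection
runs once on the full labeled table, matching a single reported feature
list; a fold-internal variant would avoid the (mild) selection bias of
ranking on data that later appears in test folds, and callers who need
unbiased error estimates should rank inside each training split instead.
k defaults to 10.

## Classifiers and evaluation

The five classifiers are scikit-learn estimators behind a stable naming
surface; hyperparameter names follow the ML-workbench vocabulary they are
usually reported in:

| name | back-end | mapped defaults |
|------|----------|-----------------|
| RF   | RandomForestClassifier | iterations→n_estimators=100, max_depth=10, seed→random_state |
| J48  | DecisionTreeClassifier | entropy criterion, min_leaf→min_samples_leaf=5, confidence 0.15→ccp_alpha=0.015 (pruning strength) |
| KNN  | KNeighborsClassifier | k=5, inverse-distance weights |
| MLP  | MLPClassifier | SGD, learning_rate_init=0.3, momentum=0.2, 500 epochs, one hidden layer of (n_features+2)/2 |
| ABM  | AdaBoostClassifier | 100 decision stumps |

All estimators run inside a pipeline with a min-max scaler fitted on each
training fold: distance- and gradient-based learners need comparable
feature scales (energy and mean differ by orders of magnitude), and the
monotone rescaling leaves tree ensembles unchanged.

Folds are a seeded random partition with sizes differing by at most one
(stratified assignment available); training on 9 folds, testing on 1.
Held-out predictions are pooled into one confusion matrix and all metrics
derive from it (accuracy in percent; precision/recall/F weighted by true
class frequency; Cohen's kappa from the pooled marginals; ROC AUC from
pooled class scores). Per-fold metric averaging is not implemented —
pooling is the unambiguous reading when a single confusion matrix is
reported per classifier.

## Synthetic cohorts

The generator emulates a resting-state cohort well enough to exercise
every pipeline stage, not to model cortical physiology. Each channel is a
unit-variance mixture of 1/f^α background (α = 1), alpha- (8–12 Hz) and
beta-band (13–30 Hz) oscillations with slowly drifting phase, a weak
40–70 Hz noise floor, sparse (~0.2%) impulses, and a mild amplitude
quantization, scaled to a subject-level amplitude. Defaults: 4 electrodes
(AF7, AF8, TP7, TP8), 250 Hz (2500 Hz supported), 480 s, 120 subjects,
stress prevalence 0.45.

PSQ scores are class-conditional normals clipped to [0, 100]. The default
class means (45.6 / 17.6) and within-class SD (6.85) were chosen so the
prevalence-0.45 mixture reproduces a cohort mean ≈ 30.2 and SD ≈ 15.5
while keeping the thresholded labels nearly noise-free with respect to
the generating class (<1% disagreement; ≈19% of subjects fall in the
excluded band under this bimodal mixture, versus ≈38% for a unimodal
cohort with the same moments).

Class structure is planted through per-subject knobs, each with a fixed
between-subject spread: overall log-amplitude (drives std, pp, energy, …),
DC offset (mean), high-band share (the mdif family), quantization step
(entropy), impulse magnitude (kurt) and impulse sign balance (skew).
Planting a feature shifts its knob's mean for the stressed class by
`effect_size` × the knob's spread, so the standardized between-class
difference of the planted feature is ≈ `effect_size`. Knobs are shared
across channels (features correlate across electrodes, as in real EEG).
The three latency features (lmin, lmax, ppt) are not plantable: window
extremum timing is uniform by construction and requesting them raises a
parameterization error. Default planted set: mean, kurt, entropy — three
mutually selective knobs. Knobs overlap for amplitude-coupled features:
planting "std" also moves pp/energy, and the impulse knob mildly moves
amp_max/amp_min; recovery checks therefore compare feature *names* by
their best-ranked column.

What the generator does **not** emulate: dipole/forward physics, blink and
EMG artifacts, non-stationary drift, inter-channel lags, or any actual
stress physiology — the class effect's shape is a free design choice.
Passing recovery tests show the pipeline detects the kind of
time-domain differences it was built to detect; they say nothing about
which differences real stressed cortex produces.

Reproducibility: a cohort is a pure function of its parameters. Subject
k's random stream is `SeedSequence(seed, spawn_key=(1, k))` and the class
assignment stream is `spawn_key=(0,)`, so any subject regenerates
identically regardless of cohort size or order.

## Problem sizes in tests and the acceptance script

The recovery checks run the full pipeline on 120-subject cohorts at
250 Hz × 480 s (the package's study conditions). Monte-Carlo calibration
checks (planted-std shift, null-effect t-tests) use 60 s recordings —
planted effects act on subject-level knobs and are duration-independent —
and the 20-seed gain-ranking recovery uses 120-subject, 60 s cohorts.
These scales are stated here as the package's own test design.

## Known limitations

- Subject-level labels with subject-level instances avoid window leakage,
  but 10-fold CV is still within-cohort; no leave-one-subject-out mode.
- The supervised MDL discretizer is O(n²) in the worst case; fine for
  cohort-sized tables, not for per-window tables with many thousands of
  rows.
- Golden Distance consumes published operating points; the package cannot
  derive Av-NAV/Av-DCO from its own confusion matrices.
- MLP convergence warnings at small n are expected (500 SGD epochs on tiny
  folds); results remain deterministic under the fixed seed.
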