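# Methods

## Classification task

One observation is one *bin*: a contiguous sixth of a 72-hour animal-week
recording (≈12 hours, ~48 samples at 15-minute resolution) across four
behavioural channels. Each bin carries the label of its animal's group —
naive (0), injured (1), sham (2). The task is three-way classification of
bins; no information about which animal or week a bin came from is given to
any model.

## Synthetic cohort generator

The generator emulates the statistical structure of an HCA study without
modelling cage micro-behaviour. Every channel of every animal-week follows a
single cosinor

    x(t) = m·f_m(g, w) + a·f_a(g, w) · cos(2π (t − φ) / 1440) + ε(t)

with mesor `m`, amplitude `a`, acrophase `φ` (minutes) shared by the cohort,
and per-group/week factors `f_m`, `f_a` expressing injury and recovery.

Channel defaults (chosen to sit in the plausible range for adult mice in a
36 × 48 cm cage and fixed as *the* study conditions for all tests):

| channel        | mesor | amplitude | noise sd                 |
|----------------|-------|-----------|--------------------------|
| distance (mm/15 min) | 8000  | 5000 | 800 (10% of mesor)       |
| temperature (°C)     | 36.8  | 1.0  | 0.2 (physiological)      |
| separation (mm)      | 150   | 60   | 15 (10% of mesor)        |
| transitions (count)  | 30    | 18   | Poisson with cosinor rate |

Noise is Gaussian except for transitions, which is a count and is drawn from
a Poisson distribution whose rate is the (clipped) cosinor; with that
channel's noise disabled the rounded rate is returned instead. Distance and
separation are clipped at 0 after noise; temperature is clipped to the
30–42 °C physiological range, which the defaults never reach in practice.
All randomness flows from one integer seed; identical configurations are
bitwise-reproducible.

Injury effects (multiplicative factors on amplitude and mesor, weeks 1–5):

* **injured** — amplitude 0.30, 0.45, 0.60, 0.70, 0.80; mesor (activity
  channels) 0.50, 0.60, 0.70, 0.80, 0.85. A strong week-1 deficit with
  partial recovery that does not reach baseline within the window, as
  expected for a controlled cortical impact.
* **sham** — amplitude 0.70, 0.80, 0.85, 0.90, 0.95; mesor 0.85, 0.90,
  0.92, 0.94, 0.96. A milder, faster-recovering craniotomy effect.
* Temperature mesor factors stay ≥ 0.99 in both groups (a 3–4 °C drop in
  core temperature would not be a behavioural effect but a moribund animal);
  the rhythm blunting acts through the amplitude factors instead.

The recovery trajectories were chosen so that no (amplitude, mesor) pair of
one group coincides with another group's pair in any week — classes stay
identifiable in principle — while late-recovery injured weeks approach the
sham trajectory, keeping the problem non-trivial. Factors are non-decreasing
in week (recovery) and the injured week-1 amplitude factor lies below the
sham one. Weeks beyond the schedule reuse the final factor (plateau).

What the generator deliberately does **not** emulate: inter-animal
variability (all animals of a group share parameters), ultradian structure,
within-week drift, sensor dropout, and spatial interaction beyond a scalar
separation channel. Consequently, passing tests demonstrate that the
pipeline recovers planted group structure under realistic noise — not that
accuracies on real recordings would match. Real home-cage data is noisier
and its classes overlap far more, so accuracies measured on synthetic
cohorts are expected to exceed those achievable on real exports.

Two cohort shapes are predefined. `default_config`: 4 naive × 1 week,
6 injured and 6 sham × 5 weeks (64 animal-weeks → 384 bins).
`study_shape_config`: 16 naive, 54 injured, 48 sham animal-weeks, matching
the published dataset's class counts (96/324/288 of 708) after 6-binning.

## Preprocessing conventions

* **Binning** — `numpy.array_split` semantics: with `n` samples and `k`
  bins, the first `n mod k` bins receive one extra sample (290 over 6 →
  49, 49, 48, 48, 48, 48). Concatenating segments reproduces the record.
* **Sequence length** — bins are zero-padded at the tail to 48 steps;
  longer bins (the 49-sample leading bins) are tail-truncated. Both the
  target length and bin count are configurable (bin counts 1–20).
* **Standardisation** — z-scores fitted on training data only. Record mode:
  per feature column. Sequence mode: per channel over *unpadded* positions,
  with padded positions re-zeroed after the transform so padding stays
  exactly 0. Zero-variance features get sd = 1 and a logged warning.
* **Class weights** — the balanced convention `w_c = N/(K·n_c)`, so
  `Σ n_c w_c = N` and the minority class receives the largest weight.
* **SMOTE** — minority classes are topped up to the majority count with
  points `x_i + u (x_j − x_i)`, `u ~ U[0,1]`, `x_j` among the k = 5 nearest
  same-class neighbours (k capped at class size − 1). Originals are
  preserved verbatim; the provenance of each synthetic point is returned so
  its geometry is checkable. SMOTE applies to shallow-model *training* data
  only — never to evaluation folds, never to the sequence dataset, and not
  inside the LOOCV comparison (resampled folds would not be comparable).

## Scaleograms

The deep model's second input is the continuous wavelet transform magnitude
of each standardized sequence: Morlet wavelet, integer scales 1–16, giving a
16 × 48 image whose four behavioural channels are stacked as image channels.
Magnitude (not power or real part) is used; the family and grid are
configurable. Scaleograms are computed *after* per-fold standardisation so
the image branch sees one scale across folds and cannot leak held-out
statistics.

## Models

The neural networks run on a compact in-repo numpy engine (`homecage.nn`)
with manual reverse-mode gradients (verified against central finite
differences in the test suite), Adam, and class-weighted sparse categorical
cross-entropy with L2 kernel penalties (`λ‖w‖²`, gradient `2λw`). Parameters
and activations are float32; gradient-check tests switch the engine to
float64. Given one seed and single-threaded BLAS, builds and training runs
are bitwise-reproducible.

Dual-branch network defaults (all configurable; widths were fixed
heuristically, not tuned per dataset): Conv1D blocks 32 and 64 filters,
kernel 3; LSTM 64 units; Conv2D blocks 16 and 32 filters, kernel 3×3; dense
64; dropout 0.3; L2 1e-3; Adam lr 1e-3; batch 32; 100 epochs (15 in
reduced-scale runs). Convolutions use stride 1 with 'same' padding and
pool-2 max pooling, so a length-48 input survives two pooling stages
(48 → 24 → 12 in time; 16 × 48 → 4 × 12 in the image branch). The FFNN uses
two hidden dense layers (32, 32) with batch normalisation between dense
layers and a softmax output. The SVM keeps the library's default RBF kernel
(only C = 1.0 and the one-vs-one scheme are fixed); the random forest is
otherwise default with max depth 4.

## Evaluation

Leave-one-out cross-validation retrains the model for every observation,
recomputing standardisation, class weights and scaleograms inside each fold
from the training portion only. A training fold that loses a class entirely
is reported as an invalid fold, never silently skipped. For reduced-scale
runs the harness can evaluate a stratified subsample of folds
(`max_folds`); each selected fold still trains on all other observations.
Per-fold model seeds derive from the run seed via `numpy.SeedSequence`.

Metric conventions: 0/0 precision or recall is defined as 0 (a class never
predicted gets precision 0); macro-F1 is the unweighted mean of per-class F1
(not the harmonic mean of macro precision and recall); weighted variants are
reported alongside. Softmax argmax ties break toward the lowest class index.
PCA components have their sign fixed so the largest-magnitude loading is
positive.

## Reduced-scale headline run

The acceptance script and the heaviest test evaluate all four models on the
default 384-bin cohort with 90 stratified LOOCV folds and 15 training epochs
for the neural networks — about 15 minutes on one CPU, dominated by the deep
model's per-fold retraining. A full 384-fold run of the deep model is the
default outside tests and scales linearly (~4× longer).

## Known limitations

* The published study's 290 samples per 72-hour session slightly exceeds
  72 h / 15 min = 288 intervals; the origin of 290 is not documented, so the
  generator exposes `samples_per_week` (default 290) rather than deriving it.
* The engine implements exactly the layer set these architectures need; it
  is not a general deep-learning framework (no GPU, no autodiff graph).
* Real HCA exports vary in column naming; `read_hca_csv`'s `column_map`
  adapts them, but vendor binary/video formats are out of scope.
* Statistical comparison between models (significance testing) is not
  implemented; the evaluation reports point metrics only.
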