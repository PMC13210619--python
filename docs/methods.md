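# Methods

This note documents the generative model behind the synthetic cohorts, the
feature and evaluation pipeline, the numerical choices, and what the tests
do and do not establish about real EEG data.

## The problem setting

Resting-state EEG depression screening compares patients with major
depressive disorder (MDD) against healthy controls (H) using multichannel
recordings segmented into fixed-length epochs. Two design hazards dominate
the credibility of reported accuracies: raw subject identifiers reused
across diagnostic class folders (so that naive grouping merges different
people), and train/test splits drawn at the epoch level (so that a
classifier can recognise individuals rather than disease). The package
implements the corrected protocol — composite subject keys, strictly
subject-wise repeated holdout, subject-level aggregation of segment
probabilities — together with the feature families, baselines, and
ablations needed to benchmark it, and a generator that reproduces exactly
the statistical structure this analysis assumes.

## Synthetic cohort generator

Each subject's eight-channel signal is a sum of

* a 1/f^x aperiodic background (default exponent 1.0, variance 40 µV²),
  synthesized by spectrally shaping white noise;
* five band-limited Gaussian processes, one per canonical band, produced by
  4th-order Butterworth band-pass filtering of white noise and rescaled to
  unit variance before weighting. Baseline band variances (µV²): delta 54,
  theta 27, alpha 54, beta 32.4, gamma 12.6 — i.e. roughly 30/15/30/18/7%
  relative power and ~15 µV total RMS, comfortably inside a 100 µV
  amplitude-rejection threshold while leaving realistic headroom;
* a shared alpha-band latent source for the designated fronto-parietal
  pairs (F3–P3, F4–P4). With coupling weight w, each coupled channel's
  alpha component is sqrt(1−w)·private + sqrt(w)·shared, which keeps the
  alpha variance fixed while making expected magnitude-squared coherence an
  increasing function of w with a w = 1 limit of 1;
* artefact bursts: ~200 ms Hann-windowed transients of 150–400 µV peak
  amplitude on a random channel, arriving as a Poisson process (default 2
  bursts/min). Only their amplitude matters to the rejection rule, so no
  attempt is made at ocular/EMG morphology realism.

Class effects are planted multiplicatively on the per-band, per-channel
variance gains:

* patients' beta variance at F3/F4/C3/C4 is multiplied by
  `effect_beta_gain` (default 1.5);
* patients' frontal alpha variance is tilted right-vs-left by
  `effect_alpha_asym_shift` (default 0.3: right gains ×(1+s), left
  ×(1−s) at Fp1/Fp2 and F3/F4), shifting the (R−L)/(R+L) asymmetry by ≈ s;
* patients' fronto-parietal coupling weight is lower (default 0.3 vs 0.6).

Subject identity enters through a stable per-band lognormal gain
fingerprint with log-scale SD `fingerprint_sd` (default 0.15), drawn once
per subject with a −σ²/2 mean correction so the fingerprint multiplier has
expectation exactly 1 — this is what makes the planted patient/control
mean beta-gain ratio equal `effect_beta_gain` exactly, and it is the
mechanism that enables segment-level identity leakage when splits are
drawn carelessly.

Eyes-open/eyes-closed structure: EC recordings get ×1.25 alpha variance,
EO ×0.9. Each subject has both conditions with probability 0.7, EO only
0.15, EC only 0.15; per-condition durations are uniform on 90–130 s. With
4 s epochs and the default artefact rate this yields ≈ 37 accepted epochs
per subject, i.e. ≈ 1600–1800 accepted training segments per repeat for
the default 31/25 cohort — chosen from the yield arithmetic to sit in a
realistic range for cohorts of this size.

Determinism: every cohort is a pure function of (spec, seed). Per-subject
streams are derived by seeding a SeedSequence with (cohort seed, class
index, subject index), so a subject's parameters regenerate bit-identically
and are independent of enumeration order. Recordings are written as flat
float32 binary plus a JSON sidecar (channels, rate, condition, µV unit);
the cohort reader also accepts EDF files in the same folder layout when
MNE-Python is importable.

The writer restarts raw IDs (S1, S2, …) in each class folder, so every ID
up to min(n_patients, n_controls) appears in both folders — reproducing
the identity pathology on purpose. A manifest records ground-truth
parameters for recovery tests.

## Preprocessing

0.5–45 Hz 4th-order Butterworth band-pass applied forward-backward
(zero-phase; ≈ −27 dB at 60 Hz after the two passes), epoching into 4 s
non-overlapping windows (trailing partial windows discarded), and
amplitude rejection at 100 µV peak (a segment is dropped iff any sample on
any channel exceeds the threshold). Epoch length, filter cutoffs and the
rejection threshold are package defaults, chosen as: ≥ 8 alpha cycles per
epoch, margin around the 1–40 Hz analysis bands, and the conventional
amplitude criterion, respectively. All three operations are stateless per
segment and never read subject identity, class or split assignment — the
leakage-safety property the tests assert by relabeling. Anything *fitted*
(imputation medians, feature standardisation, per-channel z-scores) lives
with the models and is estimated on training subjects only.

## Features

Welch PSD with 2 s Hann windows and 50% overlap (0.5 Hz resolution, so the
delta band spans six bins); band powers integrate the PSD over half-open
intervals [low, high) so adjacent bands never share a bin. Relative powers
divide by the five-band sum per channel; log-absolute powers floor at
ε = 1e−12 before the natural log (the floor value ≈ −27.6 is far outside
the physiological range and hence flaggable). Asymmetries use absolute
band power in (R−L)/(R+L) form (scale cancels either way); the ten
asymmetry features average the two frontal pairs (Fp1–Fp2, F3–F4) into a
frontal site value and the two posterior pairs (C3–C4, P3–P4) into a
centro-parietal value, per band — the only grouping of the four
homologous pairs into two sites consistent with a 10-feature count.

Coherence uses 1 s Welch windows (50% overlap). This differs from the PSD
window deliberately: magnitude-squared coherence estimated from K windows
has a noise floor near 1/K for independent signals, so the seven windows a
4 s epoch provides put the floor near 0.14, whereas 2 s windows (K = 3)
would leave it at ≈ 1/3 and swamp the planted coupling contrast. The α and
β bands at 1 Hz resolution still span 4 and 18 bins.

Scale behaviour, verified by tests: multiplying a segment by c > 0 leaves
relative power, asymmetry and coherence features bit-for-bit unchanged and
shifts every log-absolute feature by exactly 2 ln c.

## Models

* Extra Trees: 300 trees, no depth limit, Gini criterion, balanced class
  weights (scikit-learn). Exposes normalised Gini importances.
* MLP: median imputation → standardisation → MLPClassifier with hidden
  layers (128, 64), ReLU, L2 1e−4, Adam, max 200 iterations, early
  stopping on an internal 15% validation fraction — all inside a sklearn
  Pipeline so every statistic is fitted on training rows only.
* Raw-signal nets, built on a small numpy layer engine written for this
  package (grouped 1-D convolution, batch norm, max/avg/adaptive pooling,
  dropout, Adam, BCE-with-logits):
  * compact 1D CNN — 8→32 (k7), 32→64 (k5), 64→128 (k5) conv blocks with
    batch norm + ReLU, max pooling (width 4) after the first two blocks and
    adaptive average pooling after the third, dropout-0.5 head with 64
    hidden units, single logit. Pool widths and head dropout are package
    choices where the block structure leaves them open.
  * EEGNet-style — per-channel temporal filtering (8 temporal filters,
    kernel = half the sampling rate = 128 samples at 256 Hz), a depthwise
    spatial convolution across the 8 electrodes with depth multiplier 2,
    then a separable convolution with 16 pointwise filters; ELU, average
    pooling (4 then 8), dropout 0.5.
  * shallow-ConvNet-style — 40 temporal filters of length 25, 40 spatial
    filters, square activation, mean pooling (window 75, stride 15),
    logarithmic compression, dropout 0.5.

  Training: BCE-with-logits, Adam 1e−3, batch 64, max 25 epochs, early
  stopping with patience 5 on a subject-wise inner validation split (20%
  of training subjects, stratified); best-validation-loss weights are
  restored. Per-channel z-score statistics come from the inner-training
  segments only and are reused unchanged for validation and test. Batch
  norm uses momentum 0.3 with first-batch initialisation of the running
  stats: at the small per-epoch batch counts this package targets, slower
  averages lag the weights and corrupt the early-stopping signal.

Class order is fixed as (H = 0, MDD = 1) everywhere; MDD is the positive
class for sensitivity and precision. Every fitted model carries a
provenance tag naming its training subject set, and the prediction path
raises if an evaluation subject appears in that tag.

## Evaluation protocol

Ten repeats of stratified subject-wise holdout with split seeds 42..51.
Per-class test counts use round-half-up with a largest-remainder
correction toward the rounded overall target (31/25 at fraction 0.2 →
6 MDD + 5 H test subjects); the test fraction is configuration, not a
constant. Segment probabilities of each held-out subject are averaged and
thresholded at 0.5, with the tie classified as MDD (deterministic,
documented). Metrics are computed from the subject-level 2×2 confusion
counts — balanced accuracy, sensitivity, specificity, precision, F1, MCC
(zero when a marginal is empty) — plus rank-statistic AUROC with 0.5 tie
credit on the aggregated subject probabilities. Cross-repeat summaries
report the mean, the plain sample SD of the ten per-repeat values, and a
10,000-resample percentile bootstrap CI of the mean. The bootstrap
intervals are descriptive summaries of the ten operating points, not
population-level confidence bounds.

The top-K ablation refits per repeat on the importance-sorted top-K
columns; the K = 90 run therefore uses a different column order than the
canonical-order baseline, and because the tree ensemble randomises
candidate features by column index, the two runs legitimately differ by a
small amount. The report keeps both rather than deduplicating them.

## Problem sizes

The default experiment suite runs Extra Trees and the MLP; the conv nets
are enabled explicitly (`keep_raw=True` plus the model id) and are
exercised in tests at reduced scale (short epochs, few epochs of
training). Chance-level, fingerprint-leakage and effect-isolation runs use
shorter recordings (30–60 s per condition) and, for the isolation checks,
12/12-subject rosters; the headline effect-recovery run uses the full
default 31/25 cohort. These sizes are the package's chosen desk-scale
study conditions and are what `scripts/acceptance.py` reproduces.

## What the synthetic results do and do not show

Passing tests establish that the pipeline recovers planted effects of
realistic sign and location, stays at chance when no effect exists,
demonstrates segment-wise leakage inflation when (and only when) stable
subject fingerprints exist, and computes its metrics and estimators
correctly against independent oracles. They do not certify accuracy on
real clinical EEG: the generator's Gaussian band processes lack
nonstationarity, true 1/f knee behaviour, ocular/EMG artefact structure,
volume-conduction correlations between neighbouring electrodes, and
medication or comorbidity confounds. Numbers obtained on synthetic cohorts
are therefore statements about the pipeline, not about depression
detectability.

## Known limitations

* Coherence here is undirected linear coupling; phase-based or directed
  measures are out of scope.
* The identity-correction reader assumes the class-folder layout with a
  configurable folder-name alias table; exotic file naming beyond
  `<raw_id>_<condition>.<ext>` is not parsed.
* The numpy conv-net engine is single-threaded and deliberately minimal;
  it is adequate for desk-scale cohorts, not for large-scale training.
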