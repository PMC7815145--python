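# Methods

This note records the models, conventions and design choices behind
`squeaksort`, in the order data flows through the pipeline.

## Synthetic call generator

The generator (`squeaksort.synth`) emulates mouse-pup ultrasonic
vocalizations as frequency-modulated sinusoids whose spectrogram contour
realizes the defining silhouette of each of the ten Scattoni-style call
categories. Each call is rendered phase-continuously from a per-sample
instantaneous-frequency trajectory, scaled to a peak amplitude, windowed
with 0.5 ms raised-cosine edges at every voiced-run boundary (to bound
spectral splatter) and optionally mixed with stationary white Gaussian
noise at a prescribed SNR.

Contour families:

| class | contour |
| --- | --- |
| flat | constant frequency |
| upward / downward | linear sweep over the modulation depth |
| chevron | half-sine arch (rise then fall, single interior maximum) |
| complex | sinusoidal contour with `d ≥ 2` direction changes |
| frequency steps | piecewise-constant with `n ≥ 1` jumps ≥ 10 kHz |
| two syllable | two voiced runs separated by a silent gap |
| short | flat, total duration ≤ 5 ms |
| harmonics | fundamental plus one overtone at 2f, −6 dB |
| composite | two simultaneous inharmonic tones (ratio 1.4) |

Because published category definitions are silhouettes rather than numeric
cut-offs, the shape thresholds (flat tolerance ±3 kHz, short ≤ 5 ms, step
jump ≥ 10 kHz, sweep range ≥ 12.5 kHz) are configurable defaults chosen to
match common practice in the pup-call literature. With noise disabled, a
rule-based shape classifier recovers the generating category from the
trajectory alone with 100% agreement — the generator's central invariant,
exercised in the test suite and the acceptance script.

Default sampling ranges describe a realistic pup repertoire: fundamentals
50–90 kHz (40–58 kHz for harmonics so the overtone stays below the 125 kHz
Nyquist limit), durations 30–100 ms (2–5 ms for short, 60–140 ms for
two-syllable calls), SNR 20–40 dB. The class-frequency mix is anchored to a
strongly imbalanced repertoire (minority *upward* ≈ 2.5%, majority
*frequency steps* ≈ 24.9% of calls); the two genotypes (WT/KO) differ
**only** in this mix — the simulator deliberately encodes no acoustic
genotype effect, so any per-genotype performance difference on synthetic
data reflects class composition alone.

What the simulator does *not* model: colored background noise, overlapping
calls, reverberation, amplitude modulation within calls, jitter of the
contour, pup-age effects, and the fuzzy class boundaries of real
repertoires. Synthetic classes are therefore far more separable than
biological ones: passing the recovery benchmarks below shows the pipeline
is implemented correctly, not that it would reach the same numbers on real
recordings (where published accuracies for this 10-class task are around
74–83%).

## Spectrograms and call detection

STFT defaults: 250 kHz sampling, 512-point FFT with a Hamming window of
the same length (no zero padding), 75% overlap (hop 128 samples), giving
488.28 Hz frequency resolution and 0.512 ms per frame. Magnitudes are
expressed in dB relative to the maximum of the recording (an Avisoft-like
convention; the reference is arbitrary for all downstream consumers since
features are either frequency-valued or relative). The 30 kHz high-pass is
applied by dropping spectrogram rows below the cutoff — exact, and
sufficient because all later processing is spectrogram-based. Calls
shorter than one analysis window are tail-padded with zeros.

Detection marks a frame voiced when **any** retained bin exceeds the
−80 dB threshold (a maximum-over-frequency criterion), takes maximal
voiced runs, and merges runs whose silent gap is shorter than the 10 ms
hold time. Frames and bins are 0-based; intervals half-open.

Fixed-size images for the CNN map the retained band (30 kHz–Nyquist)
linearly onto 192 rows and pad (with the segment floor value, at the tail)
or center-crop the time axis to 834 frames, then min-max scale to [0, 1]
per image; a constant segment maps to all zeros. Padding rather than
stretching is deliberate: absolute call duration is itself a class cue
(e.g. *short*), and stretching would erase it. An interpolation-based
resize mode exists for callers who do want duration-normalized images, and
a "downscale" mode (render full-size, then block-max-pool the image)
produces reduced-resolution inputs that keep relative durations visible
and thin spectral lines intact.

## Features

The 20 "standard features", in the fixed order used everywhere: duration
(ms); peak-to-peak (range of the raw waveform over the call); the 50% and
75% spectral-energy quartile frequencies of the first voiced frame (linear
interpolation of the cumulative energy over bins); peak frequency and peak
amplitude at the first and last voiced frame; their max and mean; and the
"entire" statistics (min/max/mean/sd as applicable) over every frame
between call start and end, plus the standard deviation of the per-frame
maximum supra-threshold frequency.

Two conventions the feature names leave open are fixed as follows and
asserted by tests: plain max/mean statistics run over **voiced frames
only** (above the detection threshold), while "entire" statistics run over
**all** frames between start and end; quartiles operate on the **energy**
(squared-magnitude) spectrum. Both are configurable interpretations rather
than community-standardized definitions. All standard deviations are
population (ddof = 0). Standardization is a z-score with training-set
statistics (population sd; zero-variance columns pass through as zeros)
and is always fitted inside each cross-validation fold's training portion.

## Class imbalance

Class weights follow inverse frequency, `w_c = N/(K·n_c)`, normalized to
average 1 — the standard realization of "smaller class, larger weight".
Random oversampling duplicates uniformly chosen minority rows until every
class matches the majority count; downsampling keeps a uniform subset at
the minority count. Both operate on the training split only, by
construction of the API. Spectrogram-shift augmentation exists as an
optional transform but is off by default: class weighting is the strategy
used for the CNN, oversampling for the feature models.

## Classifiers

All neural models run on a small in-repo numpy engine (`squeaksort._nn`):
im2col convolutions over BLAS, ceil-mode 3×3/stride-2 max pooling,
inverted dropout, batch normalization, softmax + class-weighted
categorical cross-entropy, Adam. Weight init is scaled-uniform with limit
`sqrt(6/(fan_in+fan_out))`. Everything is float32 and deterministic given
the seed (single-threaded).

- **CNN**: conv blocks 32/64/64/128/128 with kernels 7×7, 5×5, 3×3, 3×3,
  3×3, stride 1, "same" padding (unstated conventions resolved as: ReLU
  conv activations, matching the dense layer; same padding so five pools
  shrink 192×834 to 6×27 before flatten). Dropout rates 0.2/0.3/0.4/0.5
  attach to blocks 2–5 in that order; none after block 1. Then dense 1024
  (ReLU), dropout 0.5, batch norm, dense softmax. Adam, lr 10⁻³, batch
  32, 200 epochs at full scale.
- **MLPs**: hidden widths (32,64), (32,64,128), (32,64,128,256),
  (32,64,128,128,64,32), (16,32,128,128,32); tanh hidden, softmax out;
  lr 10⁻⁴, 500 epochs, full batch (the whole training set per update).
  The optimizer is Adam here too — fixed for the CNN by its training
  recipe, and adopted for the MLPs as this package's choice.
- **Stacking**: the five MLPs as base learners; meta learner (1024,128,32)
  on the concatenated 5×10 base outputs. **Auto-context**: base configs
  2–4; meta learner (128,128) on 3×10 base outputs plus the original 20
  features. Meta learners train on out-of-fold base predictions (5-fold)
  to avoid meta-overfitting — the protocol leaves this unspecified.
- **SVM ensembles**: one-vs-all (10 binary SVCs, maximum-confidence
  decision) and one-vs-one (45 SVCs, majority vote, ties to the lowest
  class index). Best setting RBF kernel, C = 5000, γ = 5·10⁻⁴ on the
  standardized 20 features, no PCA. "Gaussian" and "RBF" name the same
  kernel family and are treated identically. The grid search is exhaustive
  over {rbf, linear, polynomial, sigmoid} × 6 γ × 8 C × {no PCA,
  15,13,11,9,7,5,3 components} = 1536 combinations with stratified 5-fold
  CV on the training split; tests and the acceptance script exercise
  reduced grids, the full grid being a multi-hour run.
- **Random forest**: scikit-learn, 200 or 500 trees (default 500).

## Evaluation

Outer 10-fold stratified cross-validation supplies the test sets; within
each fold the remaining 90% is split 80/20 into train/validation (the
validation part is held out for monitoring; models here train without
early stopping). A literal repeated-80/20-holdout scheme is available via
`SplitPlan(scheme="holdout")`, since "10-fold CV" and "80/20 split"
descriptions of such protocols admit either reading. Precision is diagonal
over
column sums, recall diagonal over row sums, accuracy trace over total;
headline values are macro averages excluding zero-denominator classes;
aggregate values are mean ± sd over folds. Confusion matrices are
row-normalized by true-class counts. Scoped runs (entire / KO / WT) and a
9-class variant (harmonics dropped before splitting) mirror the analysis
layout of genotype-comparison USV studies.

## Reduced-scale benchmark sizes

The recovery benchmarks in `tests/test_acceptance.py` and
`scripts/acceptance.py` use problem sizes chosen for a single-CPU desk
run: 200 noiseless calls per class; CNN at 20 epochs on 48×64
"downscale"-rendered images (a 192-row × 256-frame pad-crop render
max-pooled 4×4 — max-pooling rather than averaging, so thin spectral
lines, sharp step edges and relative call durations all survive the
reduction); SVM-OVA on the
20 standardized features; the imbalance echo on 3000 calls with the
default noisy sampler and 5-fold CV. At these sizes the CNN reaches ≥ 90%
and SVM-OVA ≥ 85% test accuracy — thresholds that are properties of this
repository's synthetic benchmark, not claims about real data.

## Numerical details and degenerate inputs

- dB floor −140 dB guards `log(0)`; an all-silent recording maps to the
  floor everywhere and detection returns no calls.
- Feature extraction raises on segments with no supra-threshold frame;
  single-frame segments yield length-1 tracks with zero spreads.
- Min-max image scaling maps constant segments to all zeros.
- Argmax tie-breaks everywhere (decision rules, vote counts) resolve to
  the lowest index, documented in the decision functions.
- Oversampling/downsampling, fold construction, weight init, dropout and
  batch shuffling all draw from explicit seeds; identical seeds give
  bit-identical datasets, models and predictions.

## Known limitations

The simulator's idealized contours make the synthetic task much easier
than real USV classification; ensembles and grid search are exercised at
reduced scale; the CNN engine is CPU-bound numpy, adequate for the
reduced benchmark but not for 48k-call training runs; and WAV I/O assumes
mono PCM recordings.
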