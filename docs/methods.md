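# Methods

This note documents the models, parameters and numerical choices behind
`icgperf`, and what the synthetic experiments do and do not demonstrate.

## Problem setting

A laparoscopic video stream shows bowel tissue after intravenous
indocyanine green (ICG). Perfused tissue fluoresces; in the endoscope's
RGB overlay the fluorescence appears in the green channel. Given an
operator-selected rectangular ROI, the system decides per frame whether
the ROI shows *adequate* (label 1) or *inadequate* (label 0) perfusion.
Two failure modes define the inadequate class: too little green
overall, and spatially non-uniform green (partial diffusion across the
segment).

## ROI tracking

The tracker is a Minimum Output Sum of Squared Error (MOSSE) adaptive
correlation filter. The ROI window is converted to grayscale (ITU-R 601
luma — tracking is deliberately decoupled from the green channel used
for perfusion), log-compressed (`log(1+p)`), normalised to zero mean /
unit norm, and tapered with a Hann window. The filter `H` is learned in
the Fourier domain against a Gaussian target response (σ = 2 px)
centred on the ROI, initialised by aggregating over 8 small random
affine perturbations (rotation ±0.1 rad, scale 0.95–1.05) of the first
patch, and updated per tracked frame with exponential forgetting at
learning rate η = 0.125.

Tracking confidence is the peak-to-sidelobe ratio (PSR) of the response
map: `(peak − mean(sidelobe)) / std(sidelobe)`, with the sidelobe
defined as everything outside an 11×11 window around the peak. The
first row-major peak breaks ties; a zero-variance sidelobe returns an
infinite PSR sentinel (documented: unambiguous peak, unmeasurable
confidence). PSR below 8.0 pauses the tracker — the filter and the last
box are left untouched, no label is emitted — and PSR at or above 8.0
on the window at the last box resumes it. These constants are the
canonical published MOSSE recipe; all are exposed in `TrackerConfig`.

Design choices made here: integer peak localisation (sub-pixel
interpolation is an extension point, not needed for ROI-box stability);
no full-frame re-detection while paused — the search window stays where
the target vanished, which matches the pause/resume use case (a surgeon
briefly covering the segment) and keeps the state machine minimal. The
tracker consequently will not re-acquire a target that reappears far
from where it was lost; the pipeline then stays paused and logs it.

## Feature extraction

The ROI is split into 20 vertical slices via the floor partition
(slice *i* covers columns `⌊iW/20⌋ … ⌊(i+1)W/20⌋−1`): slices are
disjoint, cover every column, and widths differ by at most one pixel.
Per slice, the 256-level green histogram is summarised by its
thresholded area `A_i = Σ_{l≥k} count_i(l)·[b(l+1)−b(l)]`.

* `k = 25` by default (the value that gave the best classification
  performance in the method's clinical evaluation), configurable.
* Bin edges default to `b(l) = l` (unit widths), making `A_i` exactly
  the number of slice pixels with green ≥ k; the general weighted form
  is implemented for non-unit binnings.
* Upper bound fixed at 255: frames are 8-bit per channel.
* No normalisation by slice size by default (mirroring the original
  protocol); a `normalize` flag divides by the slice pixel count, which
  makes features comparable across ROI sizes.
* "Green" is the G plane of the logical RGB triple; frame readers must
  deliver RGB (the imageio-based readers here do).

Useful identities, all enforced by tests: with k=0 the areas partition
the ROI pixel count; areas are non-increasing in k; the vector is
invariant to pixel permutations within a slice.

## Classifier zoo and training protocol

* One-hidden-layer feed-forward networks: hidden width 10–100, ReLU /
  tanh / sigmoid, single sigmoid output unit.
* Two-hidden-layer networks: widths from {50, 70, 90} per layer, any
  activation pair, 2-unit softmax head.
* SVM baselines: linear and Gaussian kernels (Gaussian bandwidth by the
  median heuristic, γ = 1/(2m²) with m the median pairwise distance).

Networks train with binary cross-entropy and Adam (lr 0.001, β₁ 0.9,
β₂ 0.999 — canonical defaults), batch size 5, 100 epochs. Weights start
from a uniform fan-in scheme `U(±1/√fan_in)`; initialisation and epoch
shuffling draw from a single seeded generator, so train→predict is
bit-reproducible. The forward/backward pass is implemented directly in
NumPy and is verified against central finite differences in the test
suite, and its converged accuracy against scikit-learn's MLP on the
same features.

The decision rule is `label = 1 iff score > 0.5`; a score of exactly
0.5 classifies as inadequate. The tie-break is deliberate: an uncertain
assessment should flag the segment for surgeon review, not pass it.

Features are fed to the networks unscaled (they are counts, and the
original protocol used none). SVMs accept an optional standardisation
flag, off by default for protocol parity.

## Model selection and statistics

Every grid configuration is scored by K=10-fold cross-validation:
folds are shuffled (seeded) but not stratified by default — plain
K-fold is the protocol being reproduced; a `stratified` flag exists
because unstratified small folds are noisy under imbalance. Per-fold
accuracy is percent correct on the held-out fold; the summary is
mean ± 1σ repeatability with the sample (n−1) standard deviation.
Ranking is by mean accuracy, ties broken by smaller σ, then by fewer
trainable parameters (ties never occur in practice; the rule just makes
ranking total). The winner is retrained on the full dataset and carries
its CV record for provenance.

The activation-function comparison takes the one-hidden-layer sub-grid
(10 widths × 3 activations of mean accuracies), runs a one-way ANOVA
(Fisher F) across the three activation groups, then the three pairwise
paired t-tests (paired by hidden width), two-sided, all at α = 1 %.
Two-sided is the conservative reading of "which group differs".
Exact tail probabilities are reported at full precision. Degenerate
inputs (zero within-group variance, identical paired differences) raise
errors instead of returning sentinel p-values: a silent p = 0 would
fabricate significance. The package ships the published 3×10 accuracy
grid from the method's clinical evaluation as a fixture
(`icgperf/data/reference_activation_accuracies.csv`); on it, all four
tests reject, reproducing the published conclusion that the ReLU
networks genuinely differ from the tanh and sigmoid groups.

## Synthetic data: what it emulates, what it does not

The clinical videos are unavailable, so the generator produces ROI
patches with the statistical structure the pipeline assumes:

* green channel per-pixel `clip(round(N(μ, σ_g)))` with μ =
  `green_mu_high` on the leftmost `perfused_fraction` of columns and
  `green_mu_low` elsewhere; red/blue tissue background `N(μ_c, σ_n)`;
  8-bit quantisation; one seeded generator per call (byte-identical
  reruns).
* Defaults: 64×48 ROI, μ_high 180, μ_low 20, σ_g 12, background means
  (80, 70), σ_n 10. The label is fixed by the generating parameters —
  adequate iff the ROI is fully covered (`perfused_fraction = 1`) with
  μ_high ≥ 150 — never by the extracted features, so no label leakage
  into the pipeline under test.
* The default dataset is 470 samples (the clinical dataset's size) at
  50/50 class balance — the original balance is unreported; 50/50 keeps
  CV accuracy interpretable against a 50 % chance floor. The inadequate
  half splits 50/50 between the low-green and non-uniform modes (both
  failure modes appear in the clinical material). Per-sample jitter:
  bright means U[150, 230], dim means U[5, 20], non-uniform coverage
  U[0.3, 0.7]. Dim means sit below k = 25 by construction: k's purpose
  is to exclude low-green pixels, i.e. tissue without adequate ICG
  uptake should contribute (almost) nothing to the histogram area.
* Tracking sequences place a bright green target with a frozen,
  spatially smoothed texture (Gaussian-filtered noise, σ 2.5 px,
  amplitude 25) on a per-frame-noise background, translating at an
  integer velocity. Fluorescent tissue is smoothly mottled rather than
  white-noise textured, and the smoothness also provides the
  low-frequency structure real targets give a correlation tracker.
  During an occlusion interval the target is not drawn, its position
  freezes, and the truth box is recorded absent; it reappears where it
  vanished, matching the tracker's stay-put pause semantics.

What passing on this generator shows: the feature algebra is exact, the
tracker's state machine and localisation behave as specified, and the
training/selection/statistics protocol is implemented correctly and is
seeded-deterministic end to end. What it does not show: performance on
real surgical video — no specular highlights, instrument clutter,
breathing motion, ICG wash-in dynamics, or camera noise are modelled,
and the synthetic classes are far cleaner than clinical frames. The
near-perfect synthetic CV accuracy (≈ 99–100 %) should be read as a
correctness check of the pipeline under separable conditions, not as a
clinical performance claim.

## Problem sizes and runtime

The test suite and the acceptance script size their experiments for a
single CPU: 470-sample datasets for all CV runs, 60–100-frame tracking
sequences, 1000-patch oracle sweeps, and a reduced grid (full
one-hidden-layer sub-grid + SVMs + 9 two-layer rows at 10 epochs) for
the structural model-selection checks; the full 113-configuration grid
at 100 epochs is available through `icgperf evaluate` and
`default_grid()`.

## Known limitations

* No scale/rotation adaptation in the tracker, no full-frame
  re-detection, and throughput depends on hardware (latency is logged,
  never asserted).
* Video container decoding requires an imageio plugin with an ffmpeg
  backend; directories of PNG/TIFF frames are the always-available
  input path, and annotated output is written as PNG frames.
* Scores are not calibrated clinical probabilities; the binary output
  is a decision aid, not a diagnosis.
* Exact replication of the clinically reported accuracy table is
  impossible without the original videos; the statistics stage instead
  verifies the published decisions on the published table.
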