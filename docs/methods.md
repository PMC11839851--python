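# Methods

`spectvote` studies how the reference label handed to a binary image
classifier during training should encode disagreement between human
readers, and how the classifier's sigmoid output can then be used to
separate *certain* from *inconclusive* cases.  Everything runs on a
synthetic DAT-SPECT slab cohort, so the package is self-contained and
deterministic; this note records the models, conventions and parameter
choices, and what the synthetic setting can and cannot show.

## The classification problem

A DAT-SPECT slab image (a 2D average of transversal slices through the
striatum) is classified as "normal" (0) or "Parkinson-typical reduction
of the striatal signal" (1).  A panel of R = 3 readers supplies
independent binary votes per scan.  Most scans are unanimous; the
difficult ones near the class boundary are not.  The source of label
uncertainty is *class overlap* — genuinely ambiguous images — not
annotation sloppiness, and the generator is built around that premise.

## Synthetic cohort

**Phantom.**  Each scan is a 64×64 single-channel image at 3 mm/pixel
(a 224×224 fidelity mode exists for architecture checks but is not used
for training).  A uniform elliptic "brain" background of intensity `b`
carries four hard-edged striatal regions (caudate head + putamen per
hemisphere).  At severity `s = 0` every striatal pixel has intensity
`b·C` with contrast `C = 4`.  As `s` rises the putaminal signal factor
falls first (`max(0, 1 − 1.6·s)`) and the caudate follows more slowly
(`1 − 0.85·s²`), mimicking the posterior-to-anterior degeneration
pattern; a left/right asymmetry parameter (default 0.3) makes one
putamen lead.  The noise-free striatal ROI mean is strictly decreasing
in `s`, so severity is a recoverable image feature.  Gaussian pixel
noise (sd 0.6, ~6 % of background) is added, then a point-spread blur
(8 mm FWHM in-distribution) is applied; FWHM values convert to the
Gaussian sigma via `FWHM / (2√(2 ln 2))`.

**Augmentation.**  Each scan yields 2 reconstruction variants × 6
smoothing levels = 12 instances.  The "no attenuation/scatter
correction" variant multiplies the background by 1.25 and compresses
the contrast term by 0.75.  The six smoothing levels are 0, 10, 12, 14,
16 and 18 mm FWHM; the unsmoothed instance is taken as the sixth level.
Noise is drawn once per (scan, variant) and shared across smoothing
levels, so heavier smoothing visibly suppresses the same noise
realization, as in reconstructed emission images.

**Severity distribution and reader panel.**  Severity follows a
three-part mixture: a "normal" component `0.44·Beta(2,4)`, a "reduced"
component `0.56 + 0.44·Beta(2,4)`, and a thin uniform boundary band
(width 0.06, mass 7.6 %, centred at 0.4882, slightly below the class
boundary 0.5).  Each reader votes "reduced" iff `s + u > 0.5` with
*bounded* uniform perceptual noise `u` (sd 0.03, hence |u| ≤ √3·0.03):
scans farther than ~0.052 from the boundary are always unanimous.  The
band centre, band mass and reduced-component weight were calibrated
jointly (by numerical integration of the binomial vote-pattern
probabilities over the band) so that the four vote patterns occur at
the target rates 46.1 / 2.0 / 2.8 / 49.1 % — i.e. 95.2 % unanimity and
4.8 % discrepancy, with single-dissenter patterns more common on the
normal side.  A 20,000-scan Monte-Carlo check reproduces all four rates
within ±0.3 percentage points.

**Out-of-distribution profiles.**  Two test-only cohorts shift the
acquisition characteristics while keeping the severity model: a
PPMI-like profile (point-spread 11 mm — slightly lower resolution,
noise ×1.1, class prevalence re-weighted to 67.9 % reduced) and an
MPH-like profile (point-spread 5 mm, contrast term ×1.5, noise ×0.5,
prevalence 51.1 %).  OOD scans have a single instance and a single
reference label (the generator's true class), matching the "testing
only, one reference standard" role of such cohorts.

**Determinism.**  All randomness flows from one cohort seed through a
`SeedSequence.spawn` tree (per-scan children for severity, votes, and
per-variant noise), so cohorts are pure functions of their config.

## Reference-label schemes

For votes `v_1..v_R` (R = 3):

* **MVT** (majority vote): target `1` iff more than R/2 votes are 1.
  Even-panel ties would resolve to "reduced" (never triggered at R=3).
* **RVT** (random vote): at *every presentation* of a sample one vote is
  drawn uniformly from a single run-level stream that is seeded once and
  never reset, so a discrepant scan can carry different labels across
  epochs.  (Whether the original scheme re-drew per batch iteration or
  per epoch is unknowable from the recipe; per-presentation drawing is
  the simplest faithful choice and is what the package implements.)
* **AVT** (average vote): target `(Σv_i)/R ∈ {0, 1/3, 2/3, 1}` — the
  full discrepancy information in a single fractional label.

MVT/RVT use binary cross-entropy (evaluated in logit space); AVT uses
mean squared error on the sigmoid.  `E[RVT label] = AVT label`, so RVT
is a stochastic relaxation of AVT.

## Network

The classifier is an 18-layer residual network modified to a single
input channel and a single output node: 7×7/2 stem convolution (64
filters, no bias) + batch norm + ReLU + 3×3/2 max pool; four stages of
two basic blocks with widths (64, 128, 256, 512) and stride-2 entry
with 1×1 projection shortcuts for stages 2–4; global average pooling
and a 512→1 linear head whose sigmoid is the output.  Convolutions are
He-initialized; the head uses uniform fan-in initialization.  All
convolutions are bias-free (batch norm follows); batch norms are
affine.  In fidelity mode (224×224) this gives exactly 11,170,753
trainable parameters (44.68 MB at 4 bytes each), reconciled
layer-by-layer in the tests against a closed-form accounting.

The *desk mode* used for the experiments keeps the identical topology
with width multiplier 0.25 (widths 16–128, ~0.7 M parameters) and
64×64 inputs, which trains in minutes on one CPU core.  The layers,
backpropagation and Adam optimizer are implemented in numpy inside the
package (`spectvote.nn`, im2col convolutions); all backward passes are
verified against finite differences in the test suite.

## Training

Adam (lr 1e-4, default betas), batch size 64, 20 epochs, mean batch-loss
reduction, no weight decay, no schedule, no early stopping; the
final-epoch weights are used — validation data are reserved exclusively
for the inconclusive-interval construction.  Inputs are normalized per
image by the background-ROI mean (a distribution-volume-ratio-like
reference-region convention) and shifted so background sits at 0.
Evaluation is per image: each of the 12 instances of a test scan is a
case.  Splits are scan-level 60/20/20 with deterministic largest-
remainder rounding; the same K splits are reused for all three methods,
and for each realization all methods start from identical initial
weights.

## Inconclusive intervals

For a validation set of n sigmoids and a target proportion p, k =
round(p·n/2) (half-up) cases are selected on each side of 0.5 (the k
closest to the threshold per side; values exactly at 0.5 count as
"below", matching the ≤ 0.5 decision rule; distance ties break by input
order).  Bounds are placed at the midpoint between the outermost
included and the nearest excluded case — a convention chosen so that
membership of unseen test values equal to a boundary case is
unambiguous; when a whole side is included the bound sits on the
outermost value itself, and a side that cannot supply k cases is taken
whole and flagged.  Membership is inclusive (`lower ≤ s ≤ upper`).
Re-applying an interval to its own validation set recovers exactly 2k
cases (for distinct sigmoid values), and the 50-interval grid over
p = 0.2 %, …, 10.0 % is nested.  The construction is validated against
exhaustive equal-sided enumeration on random small sets.

## Evaluation

* **Balanced accuracy** `100·(sens + spec)/2`, computed per certainty
  stratum; a stratum missing one class yields an *undefined* value that
  propagates as a gap, never as 0 or 100.
* **Certainty curve / AUC**: balanced accuracy in certain cases versus
  the proportion of inconclusive cases *observed* in the evaluated set
  (duplicate abscissae collapse to the largest-target point).  The AUC
  is the trapezoid integral over observed proportions in [0.2 %, 10 %],
  scaled by the maximal area, so constant 100 % accuracy gives AUC 100.
  Endpoints are obtained by linear interpolation between neighboring
  points (constant extension at the extremes); at desk scale observed
  proportions are coarse, so points outside the range legitimately
  anchor the interpolation.
* **Observed-vs-target regression**: slope `Σxy/Σx²` through the
  origin; slope > 1 means more test cases are flagged inconclusive than
  intended.
* **Distance contrast**: mean |sigmoid − 0.5| for reader-consistent vs
  reader-discrepant cases with normal-approximation 95 % CIs.  The
  package reports this contrast (and corrected t-tests on per-
  realization gaps) instead of a repeated-measures ANOVA, which adds
  machinery without changing the directional question.
* **Corrected resampled t-test** (Nadeau–Bengio): for K paired metric
  values from K overlapping random splits,
  `t = mean(d)/√((1/K + ρ)·var(d))` with unbiased variance, df = K−1,
  and ρ = n_test/n_train = 1/3 for the 60/20/20 design (overridable).
  As ρ→0 it reduces to the classical paired t-test; zero-variance
  inputs degenerate explicitly (t = 0, p = 1 when the mean is also 0).

## Problem sizes

The bundled experiment (`spectvote run`, `scripts/acceptance.py`, and
the behavioural tests) uses 200 scans (2400 images), K = 3
realizations, the width-0.25 / 64×64 network and 12 training epochs —
the scale at which the full three-method, three-realization experiment
runs in minutes on a single core.  (The 20-epoch default of
`TrainingConfig` is the full-scale recipe; the desk experiment shortens
it, since at 23 weight updates per epoch the loss has plateaued well
before epoch 12.)  Structural checks (20,880-image augmentation
arithmetic, 12,528/4,176/4,176 split sizes) run at the full 1740-scan
scale, which costs only seconds because they do not train networks.

## What the generator does not emulate

No projection-space physics (attenuation, scatter, collimator
response), no reconstruction algorithm, no spatial normalization, no
kinetic modelling; anatomy is schematic (hard-edged ellipses, uniform
background).  Reader behaviour is a threshold-plus-bounded-noise model
with identical thresholds — no inter-reader bias, drift or correlated
errors.  Consequently, passing tests show that the *methods* behave as
designed under controlled class overlap: that uncertainty-aware labels
(RVT/AVT) keep genuinely ambiguous cases near the decision threshold,
that the resulting inconclusive intervals are narrower and transfer
better out of distribution, and that the evaluation machinery is
arithmetically correct.  They do not certify accuracy levels on real
DAT-SPECT, where image statistics, reader behaviour and prevalence are
richer.

## Known limitations

* Desk-scale test subsets (480 images) make per-realization certainty
  AUCs coarse; method differences in AUC are small relative to
  realization noise at this scale (they were statistically
  indistinguishable on in-distribution data at full scale too), so the
  AUC comparison is the least stable of the directional checks.
* The numpy training core is single-threaded and eager; it is exact but
  roughly an order of magnitude slower than an optimized GPU stack, so
  fidelity-mode (224×224) training is out of desk reach by design.
* Bound conventions for the inconclusive interval (midpoint placement,
  half-up rounding, ≤ 0.5 as "below") are one reasonable resolution of
  an under-specified construction; alternatives shift bounds by at most
  one inter-case gap.
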