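# Methods

## Pipeline model

A sample is a pair: a mean reflectance spectrum of a pod region (462 bands
on a uniform grid over 386–1004 nm, ≈1.34 nm spacing) and an sRGB image of
the same pod, plus a storage-day label in {Day1, Day3, Day5, Day7} encoded
0–3. The pipeline assumes the spectrum is already spatially averaged over
the pod ROI (it consumes ROI-mean spectra, not hyperspectral cubes) and
that images are color-consistent (no per-image illumination correction is
applied).

### Multiplicative scatter correction (MSC)

Scatter is modelled as a per-sample affine distortion `x_i = b_i·t + a_i`
of a common reference. The reference ("ideal spectrum") is the dataset
mean; each sample is regressed on it by ordinary least squares and
corrected as `(x_i − a_i)/b_i`. For an exactly affine family this collapses
all samples onto one curve (the fit-then-apply residual is at rounding
level, asserted in the tests at 1e-8). Degenerate cases raise rather than
propagate: a constant ideal spectrum (no regression direction) and a fitted
slope with `|b| ≤ 1e-8` (correction would divide by ≈0).

Whether to correct before or after any band ablation is a pipeline choice;
here correction always precedes scoring and ablation, and band scores are
computed on corrected spectra (scatter left in place would drown the
band–label dependence in slope noise).

### Fusion

The corrected spectrum is reshaped row-major, ascending in wavelength, to a
22×21 plane (`plane[0, 0]` = band 0, `plane[1, 0]` = band 21), and stacked
behind the 22×21×3 RGB image as channel 3. Element counts balance exactly
(1848 = 1386 + 462) and both sources are recoverable bitwise from the
tensor. The two modalities have incompatible native scales, so each is
brought to [0, 1] independently before stacking: RGB by its natural unit
(or 8-bit) range, the spectral plane by per-sample min–max. Joint scaling
was the alternative; per-modality was chosen so that neither channel's
dynamic range is dictated by the other.

RGB downsampling is an exact area average (interval-overlap weight
matrices), which reduces to a plain block mean for integer factors and
conserves total intensity for fractional ones. The green-intensity color
statistic is the CIELAB hue `H = atan2(mean b*, mean a*)` over the pod
ROI (sRGB, D65); the two-argument arctangent keeps the quadrant, and mean
chroma below 0.05 (far below perception) is defined as hue 0, where the
ratio form is undefined.

### The residual classifier

Input: `(n, 22, 21, 4)` channels-last (transposed internally to NCHW).
Architecture: conv1 (kernel 3, stride 1, padding 1, in→64 channels, batch
norm, ReLU), then four stages of residual computation totalling 8 modules —
stage 1 has two plain residual modules; stages 2–4 each have one
downsampling module followed by one plain module, with channel widths
doubling (64/128/256/512) — then global average pooling and a linear head
to 4 classes. Every module computes `relu(h(x) + F(x, w))` with branch
`F = conv→BN→ReLU→conv→BN`; `h` is the identity in plain modules and a
kernel-1, stride-2, batch-normed convolution in downsampling modules
(whose branch's first convolution also has stride 2). Spatial sizes run
22×21 → 11×11 → 6×6 → 3×3.

The network is implemented directly in NumPy (im2col convolution, batch
normalization with running statistics, hand-written backward passes, Adam),
with every layer gradient verified against central finite differences in
the test suite. Weight init is He-normal; BN uses eps 1e-5, momentum 0.1.

Training defaults: Adam, learning rate 1e-3, batch 32, 100 epochs,
stratified 70/30 split with the test share rounded up (416 samples → 125
test). No validation split is carved out of the training data;
final-epoch weights are reported by default, with best-epoch retention (by
training loss) behind `keep_best`. Prediction is the score argmax with
ties broken to the lowest class index. Width (`base_channels`), depth
structure and input channels are configurable, so RGB-only (3) and
spectral-only (1) ablations use the same architecture.

### Baselines

Decision tree (entropy criterion), random forest (100 trees), AdaBoost and
KNN (k = 5, Euclidean) via scikit-learn, on row-major flattened features
(1386 RGB, 462 spectral, 1848 fused). AdaBoost uses the multi-class staged
additive (SAMME) formulation with **depth-2** base trees: a depth-1 stump
is generally not better than random guessing across four classes, which
the staged scheme requires, and in practice stump ensembles stall near 50%
on all three sources. Depth 2 is the smallest base learner that can carve
a four-class feature space.

### Band selection

Per-band distance correlation against the numeric label (0–3, ordinal):
pairwise absolute-distance matrices, double centering, population-style
1/n² normalization (the oracle in the tests uses the same convention), and
`dCor = dCov/√(dVar_x·dVar_y)`, clipped at tiny negative rounding before
the square roots. A constant input has zero distance variance; the score
is defined as 0 with a warning. Selection is strict (`score > threshold`,
default 0.7). Ablation zeroes unselected columns and is idempotent.

### Evaluation

Metrics come from the 4×4 confusion matrix by one-vs-rest reduction;
"average" precision/recall/F1 are macro (unweighted class means — classes
are balanced by construction). A class never predicted has precision 0 by
convention and is flagged in the report. The Wilson score interval uses the
two-sided normal quantile with no continuity correction and is clamped to
[0, 1]; for 125 trials at p̂ = 0.976 and 95% confidence it evaluates to
(0.9318, 0.9918).

## The synthetic generator

The generator defines the conditions under which the pipeline is tested.

**Spectra.** A smooth template (sum of Gaussian peak/trough terms and a
sigmoid NIR shoulder) with its global maximum at the grid point nearest
562 nm and minimum near 688 nm. Class signal is added as
`level · class_step · profile(λ)`, where the level is the storage-day code
(identity map by default) and the profile is a sum of flat-top (Tukey)
lobes confined to the planted windows 507–617, 659–681, 695–764 and
967–993 nm — negative on the green peak (chlorophyll loss), positive on
the red edge and NIR, strongest near 670 and 980 nm. Scatter is applied as
`x → b·x + a` with `b` log-normal (sd 0.05) and `a` normal (sd 0.02), and
i.i.d. Gaussian noise (sd 0.003 reflectance units, appropriate for spectra
already averaged over many ROI pixels) is added last. `class_step` = 0.036
puts the weakest planted band several noise standard deviations of label
signal above the floor, so planted windows score above the 0.7 distance
correlation observed for informative wavelengths on real pods.

One design point deserves emphasis. Because the MSC reference is the
dataset mean, it contains the average class signal; the per-sample slope
fit then leaks label information into *every* band of the corrected
spectra, which would make uninformative bands spuriously label-correlated.
The generator therefore solves the last two lobe weights (Newton iteration
on two closed-form constraints) so that the signal profile is orthogonal
to the MSC reference direction and has zero band mean. With this balance
the corrected unplanted bands sit at the null dCor level (≈0.1 at n = 416)
while planted bands score ≈0.85–1.0. The truth record stores the exact
planted indices and the per-sample scatter coefficients.

**Images.** A pod-shaped ellipse on a dark background; fill color
interpolates green→yellow with the class level, brown spots arrive as a
Poisson count (expected 0/2/5/9 per class) with random centers and radii
2–5 px inside the pod, and mild pixel noise (sd 0.01) is added. Rendering
is deliberately cartoonish: the contract is monotone class structure
(green:red ratio decreasing, expected spot area non-decreasing), not
realism.

**Complementary mode.** `spectral_class_map=(0, 1, 2, 2)` and
`rgb_class_map=(0, 0, 2, 3)` make Day5/Day7 spectrally identical and
Day1/Day3 visually identical — the situation where each single source has
an accuracy ceiling of 75% and only the fusion can resolve all four
classes.

**What passing these tests does and does not show.** The generator matches
the real data's statistical skeleton (band count and grid, peak/trough
placement, informative windows, scatter family, monotone visual decay) but
not its texture: no hyperspectral cubes or spatial spectral variation, no
camera optics, illumination gradients or color-calibration error, no
biological variance between pods of the same day, and class signal that is
exactly linear in storage level. Success here demonstrates that the
pipeline's machinery is correct and that fusion helps when the modalities
carry complementary information; it does not certify accuracy figures on
real pods.

## Problem sizes in the shipped tests

The test and acceptance runs use desk-scale conditions chosen once:
band-recovery at the full study size (104 pods per class, n = 416; 5
seeds), and the three-source comparison at 32 pods per class with an
8-channel-wide network trained 15 epochs (5 seeds, median). Full width (64)
remains the package default for real use.

## Known limitations

- The NumPy engine is CPU-only and unoptimized beyond im2col/BLAS; it is
  sized for 22×21 inputs, not general imagery.
- MSC assumes the affine scatter family; wavelength-dependent scatter is
  out of scope (no SNV, detrending or Savitzky–Golay smoothing).
- The distance-correlation scan treats bands independently; it does not
  decorrelate neighbouring bands or control family-wise selection error.
- Automatic pod segmentation is not provided; ROIs are boxes or masks
  supplied by the caller (the generator's pods are centered by
  construction).
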