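# Methods

## Spectrum model and preprocessing

A grain spectrum is a vector of scattering intensities on a shared Raman
shift axis, nominally 200–3400 cm⁻¹ at 1.4 cm⁻¹ resolution.  The
canonical grid includes both endpoints: 2287 points with an effective
spacing of 1.39983 cm⁻¹ (the nominal 1.4 cm⁻¹ resolution).  Spectra on
other uniform grids are accepted; all spectra in one dataset must share
an axis.  On-disk spectra are plain two-column text ("PRN-style"); files
with several intensity columns are treated as co-added scans and
averaged, with the scan count kept in metadata (whether the instrument's
four scans were stored separately or pre-averaged is not knowable from a
two-column file, so averaging is the conservative reading).

Preprocessing has three stages, all deterministic:

1. **Normalization.**  Per-spectrum min–max scaling to [0, 1].  This is
   the simplest map that removes the arbitrary intensity dimension
   (laser focus and grain position change overall intensity by tens of
   percent while band ratios stay stable); a constant spectrum is a
   degenerate-range error.  Normalization is applied *before* filtering
   so that the difference signal and the downstream images live on a
   common scale; applying it after the first filter pass would merely
   rescale the difference signal per spectrum.
2. **Baseline estimate.**  A zero-phase (forward–backward) Butterworth
   low-pass, order N = 2, critical frequency Wn = 0.002 as a fraction of
   Nyquist.  At the canonical grid this cutoff corresponds to structure
   broader than ~1400 cm⁻¹, so the output y₁ follows the fluorescence
   baseline but not the vibrational bands.  Edge handling is
   odd-reflection padding of length 3(N+1) = 9 at each end (the
   `filtfilt` convention), which makes results reproducible
   bit-for-bit.  Note the zero-phase property is a steady-state
   statement: within ~200 samples of the ends, the finite padding leaves
   a transient, which is why property tests compare interiors.
3. **Difference and second pass.**  X = x − y₁ removes the baseline; a
   second zero-phase pass (N = 2, Wn = 0.03) over X suppresses
   high-frequency clutter, giving Xₛ, the signal from which crest
   windows are cut.  The identity x = X + y₁ holds exactly in floating
   point (X is literally the subtraction).

`detect_peaks` (prominence ≥ 5% of the signal maximum by default) is
diagnostic only — it reproduces the "ten obvious crests" view of the
difference signal — and plays no part in the pipeline, which uses seven
fixed reference crests.

## Crest windows and the 28 × 28 fold

The seven reference crests (480, 865, 941, 1129, 1339, 1461,
2910 cm⁻¹) are starch (amylum) and sugar bands.  For each crest, the
grid index nearest the reference shift is taken (ties to the lower
index) and the window Xₛ[c−56 … c+55] (112 points, center included) is
cut.  Two conventions here are fixed and documented rather than derived:
"forward" means toward lower indices (any 56/55 split yields 112
points), and windows come from Xₛ, the final product of preprocessing.

Each window splits into four consecutive 28-point segments.  Segment s
of crest w becomes image column 4w + s, with the segment running down
the 28 rows: `pixels[r, 4w+s] = window_w[28s + r]`.  The fold is a pure
rearrangement of the 7 × 112 = 784 extracted values — `unfold_image`
inverts it exactly — and whether segments form rows or columns is an
orientation convention with no effect on a permutation-invariant-input
classifier; the column layout is chosen so each crest occupies a
contiguous 28 × 4 block.  No per-image rescaling is applied; pixels keep
the normalized-signal scale (typical magnitudes 0.0–0.4).

## Capsule network

For a 28 × 28 input the architecture is fixed in topology:

| stage | operation | output |
|---|---|---|
| Conv1 | valid 9 × 9 conv, stride 1, ReLU | C₁ × 20 × 20 |
| primary caps | valid 9 × 9 conv, stride 2 | C₂ × 6 × 6 → (C₂/8)·36 capsules of 8-D, squashed |
| class caps | W_ij transform + routing | 3 capsules of 16-D |

Defaults C₁ = C₂ = 256 give 32 capsule types and 1152 primary capsules;
the convolutions are valid (unpadded) because only that reproduces the
20 × 20 and 6 × 6 grids.  Routing is full-link — every primary capsule
routes to every class capsule — with log-priors b initialized to zero
(so the first coupling coefficients are exactly 1/3), three iterations
by default, and the agreement update b ← b + v·û applied between but
not after iterations.  The squashing nonlinearity is computed as
s·‖s‖/(1 + ‖s‖²), algebraically identical to the usual form but with no
division by ‖s‖, so the zero vector needs no special casing.

Because no reconstruction decoder exists in this architecture, the loss
is the separation margin loss alone:
Σ_j [T_j max(0, m⁺−‖v_j‖)² + λ(1−T_j) max(0, ‖v_j‖−m⁻)²] with
m⁺ = 0.9, m⁻ = 0.1, λ = 0.5.  It is zero exactly when the true class's
capsule length reaches m⁺ and all others are at or below m⁻.

The implementation is NumPy throughout.  Convolutions use an im2col
matrix-product formulation; backpropagation is hand-written and *exact*,
including through every routing iteration (the softmax couplings and
agreement updates are differentiated, not frozen) — an earlier variant
that treated the couplings as constants showed 10–30% relative gradient
error at three iterations.  Gradients are verified against central
finite differences to ~10⁻⁷ relative error in the test suite.

Initialization: He-scaled Gaussians for conv weights, zero biases, and
N(0, 0.1) for the W_ij transforms; all draws come from one seeded
generator, so a seed fully determines the parameters.  The optimizer is
Adam with batch size 16.  The default learning rate is 3 × 10⁻³: at
1 × 10⁻³ the margin loss reliably stalls on a plateau where the network
predicts the majority class (held-out accuracy pinned at the majority
prevalence for tens of epochs), while 3 × 10⁻³ escapes it within a few
epochs and 5 × 10⁻³ is unstable.  Classification takes
argmax_j ‖v_j‖.  When a held-out set is supplied during training, the
best-scoring epoch's weights are kept (early stopping by restoration);
per-epoch loss and accuracies are recorded at full precision.

## Training protocol

The split is stratified per variety: exactly `per_variety_test` grains
(default 8) of each variety are drawn uniformly at random, seeded, into
the test set.  With the field study's per-variety counts
(32, 34, 32, 34, 34, 34, 33) this yields the 177-train / 56-test split;
with the full 7 × 35 synthetic dataset it yields 189/56.  Outlier
screening is available but off by default: the rule — drop images whose
total pixel intensity is more than z robust standard deviations
(median/MAD) from their variety's median — is a documented stand-in for
an unspecified manual screening step and is not claimed to reproduce any
particular removal.

## Synthetic data generator

The generator emulates the statistical structure the pipeline relies
on, not any particular instrument:

* smooth fluorescence baseline: a quadratic trend plus a broad sinusoid
  (period 4500 cm⁻¹), amplitudes and phase varying per sample, scaled by
  `baseline_scale` (default 300 a.u.).  The period is deliberately far
  above the first filter's cutoff wavelength so the baseline is
  genuinely removable by the difference step — the working assumption
  the preprocessing makes about real fluorescence;
* seven Gaussian bands (σ = 8 cm⁻¹, ≈19 cm⁻¹ FWHM) at the reference
  crests.  Mean amplitudes are 950, 520, 1350, 820, 430, 470, 1100 a.u.;
  the three classes multiply the starch/sugar crests (480, 941,
  1129 cm⁻¹) by 1.0, 1.2 and 1/1.2 respectively (~20% gaps between
  adjacent classes);
* per-sample lognormal jitter: one overall intensity factor (CV 10%,
  removed by normalization) and independent per-band factors (CV 3% —
  band ratios in co-added spectra are far more stable than absolute
  intensities); a small per-variety band multiplier (CV 2%) emulates
  variety-level variation within a class; white detector noise
  (σ = 6 a.u.), all clipped at zero;
* the default template is the field study's design: 7 varieties × 35
  grains with labels LJ47/KY131/LJ11/HH311 → 0, QJ1 → 1, SJ13/HJ313 → 2
  (245 spectra, class counts 140/35/70).  Seeds are spawned
  hierarchically (master → variety → sample), so one variety's branch
  can change without touching the others.

What the generator does **not** emulate: cosmic-ray spikes, detector
etaloning, wavenumber calibration drift, band asymmetry, or the true
(unknown) within/between-class variance of real grain spectra.
Consequently the synthetic benchmark demonstrates that the pipeline
recovers a class signal of the assumed form — concentrated in crest
amplitude ratios — and that the capsule network trains correctly; it
does not certify the accuracy achievable on real grains.  The negative
control (identical class profiles) confirms the complement: with no
injected signal, held-out accuracy stays at the majority-class level.

## Numerical and scale choices

* Training runs used in the automated checks use reduced widths
  (C₁ = 32, C₂ = 64, i.e. 288 primary capsules) and 40 epochs — chosen
  as the package's standard desk-scale configuration; the default
  256/256/1152 configuration is identical in code path and is exercised
  at forward-pass scale in the tests.
* Accuracy is reported in percent at full precision; logs round to the
  nearest integer.
* Checkpoints are single `.npz` archives keyed by layer name with the
  config and seed embedded; loading validates tensor shapes.
* Image text files round-trip at 9 significant digits; spectrum files
  at full float precision.

## Known limitations

* The second filter pass is applied to the whole difference signal
  before windowing; windowing first and filtering per window would give
  slightly different edge behavior near crests.
* The capsule network is CPU-bound NumPy; the full-width configuration
  trains at roughly a minute per epoch on one core, so practical
  experimentation favors the reduced widths.
* `shift_to_index` assumes the axis covers each reference crest with at
  least the window margin; truncated spectra fail with a window-bounds
  error rather than padding.
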