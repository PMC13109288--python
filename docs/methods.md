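# Methods

This note documents the models, conventions and numerical choices behind
`ctnodes`, and what the synthetic experiments do and do not demonstrate.

## Reduced-dose CT simulation

**Dose model.** CT quantum noise variance is inversely proportional to tube
current, hence to the dose fraction *d*. Writing σ_full for the noise
already present in the full-dose image, the simulated *d*-dose image is

    I_d = I_full + σ_add · n,   σ_add = σ_full · sqrt(1/d − 1),

with *n* a zero-mean, unit-variance correlated noise texture. Total variance
then satisfies σ²(d) = σ_full²/d. At *d* = 1 the input is returned
bit-identically; the lesion mask drawn on the full-dose volume is valid at
every dose because anatomy never moves.

**Noise texture.** The texture is generated the way CT noise arises
physically: white Gaussian noise is drawn in the sinogram domain
(parallel-beam geometry, 180 uniformly spaced angles over 180°, one detector
bin per image column), filtered per projection, and backprojected
(`skimage.transform.iradon` without its own filter). Under FBP theory the
reconstructed noise NPS is |H(f)|² times the backprojection transfer
(≈ 1/f, times the detector-interpolation rolloff); the per-projection
filter H is therefore an apodized ramp shaped so that the achieved radial
NPS equals the estimated target profile S(f). Because the discrete
transfer deviates from the continuum (interpolation spreads power across
frequencies), the filter is calibrated empirically: the white-noise transfer
is measured once per geometry from a seeded 32-realization ensemble and one
fixed-point correction against the achieved ensemble NPS is applied; both
are cached. Each realization is normalized to zero mean and exactly unit
standard deviation inside the reconstruction circle, and is zero outside it
(voxels outside the circle are not reconstructed and are left unmodified).
Noise is drawn independently per axial slice, matching the in-plane
correlation and across-slice decorrelation of 2D FBP noise.

**Noise estimation.** σ_full is estimated robustly: the volume is convolved
with the 3×3 second-difference kernel [[1,−2,1],[−2,4,−2],[1,−2,1]], and the
median absolute deviation of the response inside the reconstruction circle
is scaled to a Gaussian σ. The kernel's response depends on the noise
texture (for white noise the factor is exactly 6; band-limited CT noise
responds less), so the reading is divided by the response factor
sqrt(Σ S₂|K|² / Σ S₂) computed from the estimated 2D noise power spectrum
S₂ — this keeps the estimator approximately unbiased for any texture and
makes the total-noise law (σ(d) ≈ σ_full/√d when re-estimated on simulated
output) self-consistent. The NPS is estimated from Gaussian-high-pass
residuals (σ = 2 voxels) over the most homogeneous quarter of 32×32
in-plane patches inside the circle, Hann-windowed periodograms compensated
for the known high-pass transfer (clamped at 0.05 near DC, where the
residual carries no reliable information; the DC bin is zeroed), radially
averaged into 8 bins and normalized to unit sum. Adding a constant HU
offset leaves the model unchanged.

**Options and limits.** Non-stationary (attenuation-dependent) noise
amplitude is available as an explicit opt-in (`attenuation_weighting`):
noise is modulated by the smoothed local attenuation (HU + 1000)/1000
normalized to unit mean. It is off by default because no quantitative
spatial-modulation model is established here. Scatter, beam hardening,
tube-current modulation and iterative-reconstruction noise are out of scope.

## Lesion-wise evaluation

* **Components**: 26-connectivity (configurable), deterministic relabeling
  by first-voxel order.
* **SAD**: twice the maximum over axial slices of the in-plane Euclidean
  distance transform — the largest inscribed-circle diameter on any axial
  slice, the clinical short-axis convention. A single-voxel component scores
  the minimum in-plane spacing.
* **Size strata**: closed on the left — ignored < 3 mm ≤ small < 8 mm ≤
  large. Thresholds are parameters.
* **Hit criterion**: any-voxel overlap by default; an optional IoU threshold
  is available. Any-overlap is the weakest consistent reading of a
  lesion-wise TP and the one used for the published-count comparisons.
* **FP exclusion**: predicted components overlapping *only* ignored
  (< 3 mm) nodes are excluded from the FP count — nodes deemed clinically
  insignificant should not penalize their detection.
* **Undefined ratios** (zero denominator) are reported as undefined, never
  silently 0.
* **DSC conventions**: both masks empty → 1.0; one empty → 0.0.
* **HD95**: the 95th percentile of each directed set of boundary-voxel
  distances (boundary = mask minus its 6-connectivity erosion; distances via
  exact EDT with anisotropic spacing), then the maximum of the two
  directions. Undefined when either mask is empty; such cases are excluded
  from aggregation and counted.
* **Units of aggregation**: the "all sizes" summary is reported both
  per-volume (union of eligible nodes vs. the prediction) and per-node; size
  strata are necessarily per-node. Per-node scores compare each reference
  node with the union of predicted components overlapping it; an unmatched
  node contributes DSC 0 and an undefined HD95.

## Dose-response statistics

Volumes are measured at every dose, so dose is a within-subject factor. The
one-way repeated-measures ANOVA (via `pingouin.rm_anova`) reports the
uncorrected and Greenhouse–Geisser-corrected p; with two conditions F equals
the squared paired t. Post-hoc comparisons are two-sided Wilcoxon
signed-rank tests (zero differences dropped; exact null for ≤ 25 non-zero
pairs, normal approximation with continuity correction otherwise) with
Bonferroni adjustment, default pair set full dose vs. each reduced dose;
α = 0.05. Dose-response curves are ordinary least squares of a metric on
ln(dose); R² is invariant to expressing dose as a fraction or percent, and a
constant series is assigned R² = 0. A degenerate ANOVA (zero error variance)
is flagged rather than reported as an infinite F.

## Synthetic phantoms

Phantoms emulate the aspects of body CT that this analysis exercises:
a soft-tissue background (40 HU) with a smooth low-frequency field
(±10 HU), a few large smooth organ-like blobs (−30 to 20 HU), and many
non-touching quasi-ellipsoidal nodes with log-normal SADs (median ≈ 5.5 mm,
truncated to 1–30 mm so that all three size strata occur), contrast 30–60 HU
above background, random in-plane orientation and axis ratios 1–1.6. The
node's middle axial cross-section has minor diameter equal to the sampled
SAD, matching the axial SAD convention; the z semi-axis is clipped to the
stack. Mildly correlated acquisition noise (σ = 10 HU, Gaussian kernel 0.8
voxels) provides the full-dose noise floor. Default geometry 64×128×128
voxels at 1 mm isotropic — sub-millimetre body-CT sampling at a size where a
volume × dose grid runs in minutes on one CPU. Placement is rejection
sampling with a cap of 100 retries per node; failure raises an error naming
the count achieved. Not modelled: bone, air, contrast phases, anatomically
realistic organs, mass-vs-node ambiguity. Passing phantom tests therefore
demonstrates the *machinery* (simulation laws, lesion-wise counting, score
computation, statistics), not clinical performance on real anatomy.

Mask perturbation (`perturb_mask`) produces controlled "predictions":
per-size-class miss probabilities, per-node signed boundary jitter
(erode/dilate, with guards so a node is never accidentally erased, merged
into, or extended over a neighbour), and false-positive blobs placed
strictly in background with a separation margin. Every action is logged, so
lesion-wise FN/FP counts can be verified against the log exactly.

## Toy segmenter

The built-in segmenter exists to exercise the pipeline end to end. It
smooths the volume (Gaussian, σ = 1 voxel), then thresholds at the HU
window floor (60 HU) plus `cfar_k` = 2 estimated noise standard deviations
— a constant-false-alarm-rate-style margin — followed by a 1-voxel
morphological opening and a 10-voxel minimum component size. The adaptive
margin is the mechanism that produces a
realistic dose response: as injected noise grows, the detector must become
more conservative to keep false alarms bounded, so the faintest and
smallest lesions drop out first and sensitivity falls monotonically with
dose while precision stays comparatively high. A fixed threshold, by
contrast, degrades non-monotonically (symmetric noise pushes as many voxels
into the window as out of it) and floods the image with false components at
the lowest doses.

## Reproducibility

All randomness flows from one master seed through
`numpy.random.SeedSequence(master, spawn_key=(stage, volume, dose))`
(stage 0 = phantom generation, stage 1 = dose noise); derived seeds are
recorded in the run manifest together with σ_full, σ_add and the SHA-256 of
the reference mask at each dose (constant across doses by construction).
Reruns of the same configuration are bit-identical, including CSVs.

## Problem sizes

Defaults are chosen so a full study is desk-scale: the synthetic
dose-degradation study uses 20 phantoms × 6 dose levels (full, 75%, 50%,
25%, 10%, 5%), the noise-law checks use 20-slice flat phantoms at 128×128,
and metric oracles run on ≤ 16³ random masks where brute-force all-pairs
distances are exact and fast.
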