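# Methods

`mr2sct` re-creates, at desk scale and on synthetic data, a complete
MR-only radiotherapy verification workflow: translate T2-weighted-like
pelvic MR volumes into synthetic CT (sCT) with a 2.5D conditional GAN,
compare against a segmentation/bulk-HU baseline, compute dose on true
and synthetic CTs with a simplified arc engine, and quantify agreement
with the field's standard image- and dosimetry-similarity metrics.
This note documents the models, the parameters that matter, and the
design decisions taken where more than one reasonable choice existed.

## Synthetic phantom cohort

Clinical paired MR/CT pelvis scans are not distributable, so the study
conditions are emulated by a seeded phantom generator
(`mr2sct.phantoms`).  Each case is a single integer tissue-class map —
elliptical body with a subcutaneous fat ring, two lateral bone
structures with marrow cores, a posterior bone block, a bladder, a
treatment-target ellipsoid just posterior to it, and 0–3 bowel-gas
pockets — rendered twice: CT as per-class mean HU plus lightly smoothed
Gaussian noise (noise clipped at ±4 sd so class bands are strict), MR
likewise on an arbitrary intensity scale.  Both modalities derive from
the same class map, so every pair is perfectly aligned by construction.
The body outline tapers ~20 % toward the superior/inferior ends so that
translation along the slice axis is observable; a z-invariant phantom
would make z-registration ill-posed.

Default tissue values (HU / MR mean): air −1000 / 4, fat −90 / 70,
soft tissue 40 / 45, bladder 10 / 100, bone 700 / 10, marrow 150 / 60,
gas −950 / 5.  The contrast relations are T2-weighted-like (bright
bladder, dark cortical bone and gas).  Two properties are deliberate:

* **Non-invertibility.** Bone and gas overlap in MR intensity but sit at
  opposite ends of the HU scale, and fat/marrow/bladder break
  monotonicity, so no single global monotone MR→HU map can solve the
  task (the best isotonic fit leaves a body MAE of ~110 HU, several
  times the rendering-noise floor).  Spatial context is required — this
  is what makes a learned translator meaningful.
* **Inter-scan drift.** Each case's MR is perturbed by a random gain
  (0.7–1.4), offset (0–8), smooth multiplicative bias field (2–3
  low-order cosine modes, peak amplitude 0.05–0.2) and Gaussian noise
  (sd 1–3).  This reproduces the cross-scan histogram spread that
  intensity standardization exists to remove (cohort 99th-percentile
  coefficient of variation > 5 % before standardization).

The default study scale is 16 training + 4 test cases on 64×64×16 grids
with 2×2×3 mm voxels (a ~128 mm pelvic field of view), against the
clinical design of 40 + 10 cases at 512×512; cohort defaults in
`generate_cohort` remain 40/10.  What passing tests at this scale show
is that the pipeline's machinery and orderings behave as designed; they
do not certify clinical-magnitude accuracy, anatomical realism, organ
deformation, MR artefacts beyond smooth bias, or scanner physics.

## Preprocessing

**Nyul intensity standardization** (`preprocess`).  Foreground landmarks
at percentiles 1, 10, 20, …, 90, 99 are computed per training MR inside
its body mask, affinely mapped so (p1, p99) → (0, 100), and averaged
into a standard scale.  Applying the transform maps each image's own
landmarks exactly onto the standard ones, piecewise-linearly in
between, with linear continuation of the end segments beyond p1/p99.
The map is monotone and gain/offset-invariant; after standardization
the mean pairwise L1 distance between per-case landmark vectors drops
to ≲1 % of its original value.  CT volumes are never standardized —
HU is already a physical scale.  Landmarks use the body mask as
foreground; computing them over the whole image (including air) is the
main alternative and would dilute the landmarks with background noise.

**Body contours** are extracted by Otsu thresholding, keeping the
largest connected component, and filling holes slice-wise and in 3D
(so gas pockets stay inside the contour).

**Rigid harmonization.** Only translation is supported; the phantoms
are aligned by construction and deformable registration is out of
scope.  `rigid_resample` translates and trilinearly resamples onto the
fixed grid (background = median border value).  Shift estimation
resamples both volumes to a ~1 mm isotropic grid (cubic) and then runs
centre-of-mass initialization plus exhaustive NCC search (±5 mm, 1 mm
steps).  The isotropic step matters: evaluated on a native 3 mm slice
grid, linear-interpolation blur biases NCC toward integer-voxel
alignments by more than 1 mm.  Recovery accuracy is ≤1 mm per axis for
injected shifts up to 5 mm.

**Windowing.** Network tensors live in [−1, 1]: CT through the window
(−1000, 1500) HU, standardized MR through (0, 100) (the standard-scale
range), with clipping on the forward map and an exact affine inverse.

## Translation model

The generator (`gan.UNetGenerator`) is a U-Net over 2.5D inputs: each
axial slice enters as a 3-channel stack (slice below, slice, slice
above; edge slices replicate), and the network predicts the centre CT
slice, so a volume with S slices yields exactly S training samples and
each slice is predicted once at inference.  Architecture: a stem
convolution, 4 stride-2 downsampling blocks, 2 residual blocks in the
bottleneck, and a nearest-neighbour-upsampling decoder whose levels
concatenate the encoder features (skip connections); all blocks are
conv + instance norm + ReLU, with a final conv + tanh bounding the
output to [−1, 1].  Channel widths double from `base_channels=12` up
to `max_channels=64`.  These widths are sized for single-CPU training
(the engine below); an ablation with skip connections removed converges
to measurably worse validation MAE at equal budget.

The discriminator is five stride-2 convolution blocks with ReLU
activations, global average pooling and a sigmoid head — one
probability per (MR stack, CT slice) pair.  It is conditional
(pix2pix convention: it sees the MR stack concatenated with the real or
generated CT slice); an unconditional variant is available via
`DiscriminatorSpec(conditional=False)`.  The critic is deliberately
light (channels 2→16): with the 1:1 loss weighting, a wide critic's
gradient into the generator measures an order of magnitude above the
per-pixel L1 gradient and drowns the reconstruction signal — the same
imbalance that leads pix2pix-style systems to weight L1 by 100.  Here
the weights stay 1:1 and the balance is restored through critic
capacity instead.

Losses: generator = `lambda_l1 * mean|pred − target| + lambda_adv *
(−ln D(fake))`, discriminator = `−ln D(real) − ln(1 − D(fake))`, with
both weights defaulting to 1.  The adversarial type is non-saturating
binary cross-entropy; a least-squares (LSGAN) variant sits behind
`LossWeights(adv_mode="lsgan")`.

Training (`train.train`): Adam (lr 2e-4, betas (0.5, 0.999)), batch 3,
100 epochs by default (the scaled-down study uses 50), seeded
shuffling, discriminator updated first then the generator on the same
forward pass.  A fraction (default 0.1) of the training cases is held
out for per-epoch validation MAE/SSIM and never contributes gradients;
case IDs of both splits are recorded in the history.  Probabilities are
clipped to [1e−6, 1−1e−6] inside the loop so sigmoid saturation cannot
produce infinite losses; any non-finite loss aborts with the epoch and
batch named.  No learning-rate schedule or augmentation by default
(`lr_decay`, `augment_flip` flags exist).

### The numpy network engine

No GPU framework is assumed: `mr2sct.nnet` is a small CPU engine with
exactly the layers the two networks need.  Convolutions run
channels-last as one GEMM per kernel tap accumulated over taps, which
keeps memory access contiguous and hands the arithmetic to BLAS; the
backward pass scatter-adds through the same shifted views, and every
layer's gradients are verified against central finite differences in
the test suite.  Training the default study configuration takes a few
minutes per seed on one core.  Float32 throughout; training is
bit-reproducible for a fixed seed within one environment (exact values
can differ across BLAS builds, which is why tests assert orderings and
tolerances rather than frozen loss values).

## Baseline synthetic CT

`bulk_sct_baseline` stands in for commercial segmentation-based sCT:
inside the body, standardized MR below the lower threshold → bone bulk
HU (cortical bone is dark on T2), between thresholds → soft tissue,
above the upper threshold → fluid; outside → air
(−1000/700/40/10 HU).  `BulkHUBaseline.fit` places the thresholds at
the 6th/94th percentiles of the within-body training histogram (bone
and fluid occupy the tails).  The baseline intentionally reproduces
only the bulk-assignment character of such systems — the commercial
product's multi-echo (mDixon) decomposition is out of scope — and its
characteristic failures here are the same ones discussed clinically:
gas misassigned as bone, marrow and fat unrepresentable.

A second reference, used in tests, is the least-squares affine fit
HU ≈ a·MR + b on training body voxels: the best a global linear map can
do, and the floor any learned translator must beat.

## Dose engine

`dose.compute_dose` is a declared toy standing in for a Monte Carlo
treatment planning system: `n_angles` (default 36) coplanar
parallel-beam directions in a full arc; HU → physical density through a
piecewise-linear calibration curve ((−1000, 0.001), (−100, 0.93),
(0, 1.00), (60, 1.06), (1000, 1.55), (1500, 1.90) g/cc, clamped);
radiological depth accumulated along each ray with a midpoint rule at
steps of half the smallest voxel dimension; deposit per angle
`density · exp(−mu · depth)` with `mu_per_density = 0.005`/mm.  Each
beam is collimated to the target: a flat aperture covering the target's
lateral and longitudinal projection plus a 10 mm margin, with a 4 mm
Gaussian penumbra.  Collimation is what gives the dose its conformal
high-dose/low-dose structure — with open fields the phantom's in-body
dose is so flat that the 60 % cut-off selects the same voxels as the
10 % cut-off and the dual-cut-off analysis degenerates.  The angular
sum is rescaled so the mean dose over the target equals the
prescription (45 Gy) exactly; every dose grid (true or synthetic CT) is
normalized this way, so dose comparisons probe spatial distortion, not
global scale.  No scatter, no beam hardening, no aperture optimization;
single prescription level only.

## Verification metrics

* **MAE** (HU) and **SSIM** inside the body mask.  SSIM uses a 7×7
  Gaussian-weighted window (σ 1.5) per axial slice, constants
  C1 = (0.01·L)², C2 = (0.03·L)² with data range L = 2500 HU (the CT
  window width); the SSIM map is averaged over mask-covered voxels per
  slice, then across slices with coverage.  Boundary handling is
  edge-symmetric reflection.
* **DSC** of automatically extracted body contours, 2|A∩B|/(|A|+|B|),
  defined as 1 for two empty masks.
* **3D gamma index** at 1 %/1 mm: for each reference voxel above the
  dose cut-off, γ = min over displacements |δ| ≤ 3 mm (lattice pitch
  0.1 mm = DTA/10) of sqrt(|δ|²/DTA² + ΔD²(δ)/(1 % of prescription)²),
  with the evaluated dose trilinearly interpolated and global
  normalization to the prescription (local normalization behind a
  flag; a voxel-centre-only search mode exists).  The implementation
  visits displacements sorted by magnitude and stops a voxel's search
  once the distance term alone exceeds its running minimum — an exact
  early exit, verified voxel-for-voxel against an independent
  exhaustive brute-force search over the identical lattice (1e−9
  agreement on 100 seeded pairs).  γ values are stored unclipped.
* **GPR**: percentage of evaluated voxels with γ ≤ 1 (inclusive),
  reported at the 10 % (4.5 Gy) and 60 % (27 Gy) cut-offs of the
  prescription; the 60 % region is a subset of the 10 % region.
* **Paired t-test**, two-sided, on per-case paired metrics
  (t = mean(d)/(sd(d)/√n), sample sd, df = n−1).

## The experiment and what it shows

`workflow.run_experiment` chains everything: cohort → Nyul fit on
training cases → GAN training → GAN and bulk sCT for each test case →
arc dose on true and both synthetic CTs → three report tables (image
similarity of sCT vs true CT; GPR at both cut-offs; the
registration-independence check, SSIM and body-contour DSC between MR
and each sCT with no registration applied) plus paired t-tests per
metric.  Both sCT methods are always scored against the same true-CT
reference dose from the same engine and plan configuration.

At the default desk scale the reproducible findings are orderings, not
clinical magnitudes: the trained GAN beats the affine fit and the bulk
baseline in test MAE, its bone HU medians are far closer to truth than
any global map's, and its GPR at the 10 % cut-off exceeds the
baseline's.  At the 60 % cut-off the two methods are close on phantoms:
that region surrounds the soft-tissue/bladder target, where bulk
assignment happens to be nearly exact — the clinical high-dose
advantage of learned sCT rests on anatomy this phantom does not model.
Absolute GPR values are also lower than clinical reports, as expected
for a toy dose engine at 1 %/1 mm on coarse grids.

## Numerical choices and degenerate inputs

* Seeds: every stochastic component (phantom geometry, noise, scan
  variation, shuffling, initialization) is a pure function of an
  integer seed; per-case seeds are derived arithmetically and kept
  below 2³¹.
* Constant images are rejected by standardization and contour
  extraction with the offending image named; empty masks, empty dose
  cut-offs, non-binary masks, zero-variance t-test differences, and
  non-overlapping fields of view all raise informative errors.
* Gamma boundary rule: displacements leaving the evaluated grid are
  excluded from the search; the zero displacement is always available.
* Dose march grids use odd symmetric point counts so a mirrored
  phantom yields a bit-mirrored dose field to floating-point tolerance.
* Training validation with `val_fraction=0` falls back to scoring on
  (the first two) training cases, documented in `train`.

## Known limitations

Phantoms are piecewise-constant and rigid; no organ deformation,
bladder-filling differences, mDixon physics, or MR artefacts beyond a
smooth bias field.  The dose engine ignores scatter and optimization,
so its absolute GPRs are not clinically comparable.  The network
engine is single-CPU by design; large clinical matrices (512×512)
run but train slowly.  Deformable registration is explicitly out of
scope; only rigid translation is modelled.
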