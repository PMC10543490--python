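# Methods

`plexus-seg` implements an atlas-guided, patch-based 3-D U-Net pipeline for
segmenting the choroid plexus of the lateral ventricles from three anatomical
MRI contrasts (T1-, T2- and FLAIR-weighted), the evaluation statistics used
to validate such segmentations, and the regression analysis of plexus volume
across the adult lifespan.  Because clinical MRI cohorts cannot be shipped
with a software package, every stage is exercised on a synthetic phantom
cohort whose geometry and metadata follow the statistical structure of an
adult lifespan cohort; the phantom generator is a first-class, tested module.

## Segmentation model

The network is a 3-D U-Net variant operating on 64×64×64-voxel patches:

* **Encoder** — three blocks of two layers each; every layer is a 3×3×3
  convolution (stride 1, padding 1) → batch normalization → ReLU.  The first
  block has 64 filters, doubling per block (64, 128, 256).  Blocks are
  separated by 2×2×2 max pooling, so the third block is the bottleneck
  (64³ → 32³ → 16³).
* **Decoder** — mirrors the encoder with filters halved per block (128, 64);
  upsampling is a 2×2×2 transposed convolution with stride 2 and no padding,
  followed by concatenation skip connections from the matching encoder level
  and two conv→BN→ReLU layers.  Skip connections are standard for U-Nets and
  can be disabled (`skip_connections=False`) for ablation.
* **Head** — a 1×1×1 convolution followed by a hyperbolic tangent, so voxel
  scores live in (−1, 1).

Training minimizes the two-class **generalized Dice loss**.  Scores are
mapped to foreground probabilities p = (s + 1)/2 (the natural affine map
from the tanh range to [0, 1]); with reference labels r ∈ {0, 1} and class
weights w_ℓ = 1/(Σ_n r_ℓn + ε)², ε = 1e−6,

    GDL = 1 − 2 · (Σ_ℓ w_ℓ Σ_n r_ℓn p_ℓn) / (Σ_ℓ w_ℓ Σ_n (r_ℓn + p_ℓn)).

The ε guards patches where one class is empty.  Optimization uses Adam
(default learning rate 1e−4, batch size 4), early stopping on the validation
generalized Dice loss (patience 15, cap 100 epochs), and the returned model
is the checkpoint with the lowest validation loss.  Initialization is
Kaiming-style (seeded); training is deterministic end-to-end given the seed
(splits, patch centres, flips, initialization, batch order).

The network, loss, backward passes and Adam are implemented directly in
NumPy with numba kernels for the 3×3×3 convolutions.  Direct convolution was
chosen over im2col + GEMM after profiling: on a single CPU core the 27-fold
im2col inflation is memory-bandwidth-bound, while the direct loops keep
working rows in cache and reach ~26 GFLOP/s.  Gradients are verified against
finite differences in the test suite.

## Atlas-guided patching

All training happens in a shared **common space**.  A probabilistic atlas is
built as the voxelwise mean of the training subjects' truth masks; its
support (probability > 0), dilated by a configurable margin (default 8
voxels), defines a crop box around the structure.  Training patches are
centred on voxels drawn from the atlas **with probability proportional to
the atlas value** (41 patches per subject, sampled with replacement, fixed
per subject per fold).  The wording "random voxels from the atlas" admits a
uniform reading; probability weighting concentrates patches where the
structure actually occurs and is the package's design choice.  Patches are
augmented by random left–right mirroring (probability 0.5 per patch per
epoch) about the mid-sagittal axis.

At inference the crop box is tiled deterministically with stride = half the
patch size (guaranteeing full coverage; `atlas_random` tiling mirrors the
training-style sampling instead).  Overlapping patch scores are combined by
the **arithmetic mean of raw tanh scores**; voxels covered by no patch get
−1 (the tanh minimum); the mask keeps voxels with mean score strictly > 0,
equivalent to mean foreground probability > 0.5.  The binary mask is then
resampled to the subject's native grid using the inverse of the known rigid
transform with nearest-neighbour interpolation, which cannot invent label
values.

## Study design

Per contrast, a 5-fold cross-validation with 60/20/20 train/validation/test
fractions (30/10/10 subjects at n = 50); the test sets partition the cohort
so each subject is evaluated exactly once, and the identical seeded splits
are reused across the three contrast models so their predictions are
directly comparable.  Per-subject test metrics: Dice, 95% Hausdorff distance
(mm), voxelwise ROC AUC, and predicted/true volumes (cm³).

## Evaluation statistics

* **Dice** 2|A∩B|/(|A|+|B|); two empty masks score 1 (agreement on absence).
* **HD95** — surface voxels are set voxels with an unset face neighbour or
  on the grid boundary; the directed distance is the 95th percentile (linear
  interpolation) of Euclidean world-space (mm) nearest-surface distances,
  and the reported value is the maximum of the two directions.  The metric
  is undefined (an error) for empty masks.
* **AUC** — Mann–Whitney formulation (ties count ½), evaluated on the
  stitched score volume restricted to the atlas crop box: whole-volume AUC
  would be inflated by the vast amount of trivially-classified distant
  background.
* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measurement, from the standard ANOVA decomposition.  Absolute agreement is
  the right form for comparing volume *measurements* across methods, since
  a constant offset between methods should be penalized.
* **Bland–Altman** — bias ± 1.96·SD (sample SD, n−1) of paired differences.
* **Wilcoxon signed-rank** — two-sided, zero differences dropped (classical
  convention, flagged in the result); exact permutation null for n ≤ 25
  (dynamic program over doubled midranks, so ties are handled exactly),
  normal approximation with tie and continuity corrections above.
* **FDR** — Benjamini–Hochberg step-up; all p-values emitted by one analysis
  call share a single joint adjustment.

## Lifespan volumetry

Per contrast, plexus volume is regressed on age, sex (F = 0, M = 1, so the
male coefficient is the male–female offset) and total intracranial volume
with a Gaussian GLM (identity link; maximum likelihood = least squares).
Wald p-values are FDR-adjusted jointly across the three fits; significance
is declared at adjusted p < 0.05.  McFadden pseudo-R² = 1 − ℓ_model/ℓ_null
uses the profile (ML-variance) Gaussian log-likelihood, which makes it well
defined and monotone for nested Gaussian fits; note that for continuous
densities ℓ can be positive at very small residual scales, where McFadden's
measure loses its usual interpretation — at the cm³ volume scales used here
ℓ_null < 0 and the statistic behaves conventionally.  Percent change per
decade is 10·β_age/mean(volume)·100, i.e. evaluated at the cohort mean
volume (the natural baseline when none is stated).  Model-performance
metrics can likewise be regressed on lateral ventricular volume, one GLM per
metric, FDR-adjusted across metrics.

## Phantom cohort generator

Each subject is built deterministically from (parameters, age, sex, seed):

1. An ellipsoidal head (semi-axes 35×42×38 mm) scaled by a per-subject size
   factor ~ N(1, 0.03) — this makes TIV a non-degenerate covariate; TIV is
   the head-mask volume.
2. Two mirrored lateral-ventricle ellipsoids (base semi-axes 8×16×10 mm at
   age 21) whose semi-axes grow by 1% per year of age, emulating age-related
   ventricular enlargement; LVV is their voxel volume.
3. A target plexus volume drawn from V = β₀ + β_age·age + β_male·1[M] + ε,
   ε ~ N(0, σ²), truncated below at 0.5 cm³, with defaults
   (β₀, β_age, β_male, σ) = (0.62, 0.047, 0.30, 0.40) cm³ chosen so the
   cohort mean is ≈ 3.2 cm³ over ages 21–89 and the lifespan slope matches
   the ~0.047 cm³/yr reported for the adult lateral-ventricle choroid
   plexus, with males larger than females.
4. A curved tube hugging each ventricle's posterior-medial wall, rasterized
   at the radius (found by bisection on precomputed voxel-to-curve
   distances) that puts each side within 5% of half the target volume.  The
   tube is deliberately not a morphologically realistic frond — it is the
   simplest bilateral shape with an exactly tunable volume.
5. Intensities painted per contrast from a table (parenchyma/CSF/plexus:
   T1 0.60/0.15/0.45, T2 0.40/0.90/0.60, FLAIR 0.50/0.10/0.70) reproducing
   the qualitative contrast ordering of real MRI (CSF dark on T1/FLAIR,
   bright on T2; plexus brighter than CSF on FLAIR, with at least a 0.1
   intensity gap enforced), multiplied by a smooth low-order polynomial bias
   field (amplitude 0.1) and degraded with additive white Gaussian noise
   (σ = 0.03).  Rician noise was considered and rejected: at these SNRs the
   difference is immaterial to the test surface.
6. A rigid jitter (≤5° per axis, ≤3 mm translation) defines the subject's
   native space; contrasts are resampled there (optionally onto an
   anisotropic 0.57×0.57×4.0 mm FLAIR grid), while truth masks are kept in
   common space, mirroring a workflow in which manual labels live on the
   registered images.

Cohorts draw ages uniformly over [21, 89] and sexes Bernoulli(0.5).  A
metadata-only sampler (`sample_cohort_metadata`) draws the same statistical
model without rasterizing, for cohort-level statistical tests.

What the phantoms deliberately do **not** emulate: cortical anatomy, white
matter lesions, partial-volume effects at real acquisition resolution,
nonlinear inter-subject deformation (the known rigid transform stands in for
template registration), pathology-specific atrophy, and third/fourth
ventricle plexus (only the lateral-ventricle component is modelled).
Passing tests therefore demonstrate that the pipeline's machinery —
sampling, training, stitching, space mapping, metrics, statistics — is
correct and recovers planted effects; they do not certify segmentation
accuracy on clinical MRI.

## Problem sizes for the bundled checks

The default test suite and the acceptance script run a reduced configuration
chosen to keep the full study design intact at desk scale: a 20-subject
phantom cohort on a 64³ grid at 1.5 mm (same physical anatomy, coarser
sampling), base filters 8, 32³ patches, 8 patches per subject, batch 4,
learning rate 1e−2, 5 epochs.  The FLAIR-like contrast runs the full 5-fold
design; the T1/T2-like contrasts run the first two folds from the identical
splits, which yields 8 common test subjects for the cross-modality volume
ICC.  The lifespan analysis uses a 98-subject cohort at full 96³/1 mm
resolution with volumes read from rasterized truth masks plus 0.05 cm³
measurement noise (no training involved), and the null-slope false-positive
check runs 50 metadata-only replicates.

## Numerical choices and degenerate inputs

* Stitching threshold is *strictly* greater than 0: an exactly balanced
  overlap (mean score 0, probability 0.5) is excluded.
* Out-of-field voxels are filled with 0 for images and masks (background-
  equivalent, conservative for metrics); patch padding uses 0.
* Input volumes are z-normalized per volume before patch extraction, at both
  training and inference.
* Masks are stored as uint8 {0, 1}; any nonzero voxel on read is treated as
  1 (tolerant of 255-coded masks).
* Grid indexing is 0-based; the NIfTI affine maps voxel indices to world mm;
  rigid transforms are 4×4 row-major text files mapping common-space to
  native-space world coordinates.
* Batch normalization uses batch statistics during training and running
  statistics (momentum 0.1) in evaluation mode, so inference is
  deterministic and serialization round-trips bit-identically.
* Checkpoint selection never returns parameters from after the best
  validation epoch; training aborts with the epoch index if the loss goes
  non-finite.

## Known limitations

* Nonlinear template registration (e.g. ANTs to MNI) is out of scope; the
  phantoms carry known rigid transforms instead, so registration error is
  not part of the tested error budget.
* Single-channel, single-structure segmentation only; no multi-class heads,
  deep supervision or ensembling.
* CPU-oriented: the NumPy/numba implementation favours determinism and
  portability over throughput; it is not intended for large-cohort
  production inference.
* The Wilcoxon exact branch enumerates sign assignments implicitly via a
  subset-sum distribution; p-values for heavily tied tiny samples follow the
  midrank convention, which can differ from software that breaks ties
  differently.
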