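# Methods

## Problem

Adults with gliomas frequently also carry white matter hyperintensities
(WMH) from small vessel ischemic disease or chronic infarcts.  Both
processes produce bright T2/T2-FLAIR signal, so a tumor-segmentation model
that has never been told about WMH tends to mark distal WMH as tumor
(usually edema), which corrupts whole-tumor boundary-error metrics even
when overlap scores look fine.  `neuroseg` implements a multi-class 3D
U-Net that labels the glioma sub-regions — necrotic core (NCR, code 1),
peritumoral edema (ED, code 2), active/enhancing tumor (AT, code 4) — and
WMH (code 3) as distinct classes, in either a 4-class (no WMH) or 5-class
variant, together with the evaluation machinery used to compare the two.

## Segmentation model

The network is a standard encoder–decoder U-Net over 4-channel input
(T1, T1 post-contrast, T2, T2-FLAIR):

* per level, two nodes of [3×3×3 convolution, stride 1, zero padded →
  ReLU → batch normalization];
* `base_filters` channels (default 32) in the outermost level, doubling
  at each of `levels` levels (default 4): plan [32, 64, 128, 256];
* 2×2×2 max-pool downsampling; 2×2×2 stride-2 transposed-convolution
  upsampling; encoder outputs concatenated onto the matching decoder
  inputs; final 1×1×1 convolution to per-voxel class scores.

Training uses Xavier initialization, Adam (initial learning rate 1e-4),
a 2nd-order polynomial decay `lr(e) = lr0·(1 − e/E)²` over `E` epochs
(default 600), and unweighted voxelwise multi-class cross-entropy.  The
loss function is a design choice: the recipe we follow fixes "no voxelwise
weighting" but not the loss itself, and unweighted cross-entropy is the
minimal choice consistent with that.  Training patches (default 80³
voxels) are centred on a lesion voxel with probability 0.9 and on a brain
voxel otherwise, both uniform within their pool; a case with no lesion
falls back to brain-uniform sampling.  Optional augmentation applies a
fair-coin left-right flip followed by an affine warp with per-axis
rotation ≤ 45°, per-axis scale within ±25 %, shear coefficients within
±0.1 (trilinear for images, nearest-neighbour for labels).  Inference is
fully convolutional on the whole zero-padded volume; ensemble members'
softmax probabilities are averaged before the voxelwise argmax, with ties
broken toward the lowest class index.  Per-channel z-score normalization
over brain-mask voxels precedes both training and inference.

The layer stack (convolution via im2col + BLAS, batch norm, pooling,
transposed convolution, Adam) is implemented directly on numpy with
hand-derived reverse-mode gradients; a float64 finite-difference check of
the full network gradient is part of the test suite.

Numerical conventions pinned for reproducibility: all padding appended at
the high-index end of each axis (155 → 160 slices grows superiorly);
channel order fixed as (T1, T1PC, T2, FLAIR); axis order LPS; argmax ties
toward the lower class index; batch-norm running statistics frozen at
inference; each ensemble member trains from a seed derived from the
master seed.  Two validation modes exist side by side — k-fold
partitioning (`make_folds`, sizes differing by ≤ 1) and repeated
retraining on the full set (`train_ensemble`) — because both are
legitimate uses of the same training loop.

## Metrics

Dice = 2TP/(2TP + FP + FN) over a region mask.  Composite regions on
label codes: WT = {1,2,4}, TC = {1,4}, ET = {4}, WMH = {3}; WT
deliberately excludes WMH.  HD95 extracts each mask's surface (mask
voxels with ≥ 1 face-adjacent background neighbour, 6-connectivity;
array-border voxels count as surface), computes both directed
nearest-neighbour Euclidean distance sets in mm, and reports the maximum
of the two directed 95th percentiles (linear interpolation between order
statistics).  This max-of-directed form is the dominant
challenge-evaluation convention; the pooled-percentile variant is
available behind a flag and both are oracle-tested.  We use the
surface-distance definition of HD95 throughout, noting that prose
descriptions of the metric sometimes speak loosely of "distance between
centers" of segmentations.  Empty-mask policy: Dice(∅,∅) and HD95 with
any empty mask are undefined (NaN, excluded from aggregates, counts
reported); Dice(∅, nonempty) = 0; an option scores Dice(∅,∅) = 1
portal-style.

Cohort statistics: Pearson/Spearman volume correlation (two-sided p),
Bland–Altman bias with bias ± 1.96·sd(differences) limits (sample sd),
prevalence counts at the 100/1000/5000/10000 mm³ WMH thresholds
(inclusive ≥, matching "at least"), volume-stratified median Dice
(even-sized strata: mean of the central order statistics), volume–Dice
correlation with optional log10 volume transform (zero-volume cases
excluded and counted), and a paired two-tailed t-test implemented as a
one-sample t on per-case differences (zero-variance nonzero differences
flagged undefined; all-zero differences report t = 0, p = 1).

## Synthetic phantoms

The phantom generator produces the geometry and contrast relationships
this segmentation problem hinges on, at 1 mm isotropic spacing inside an
ellipsoidal "brain" with exact-zero background (so the brain mask is the
nonzero-voxel union, as for skull-stripped data):

* a tumor complex of three concentric jittered ellipsoids — NCR inside an
  AT rim inside an ED envelope — so NCR ⊂ core ⊂ WT holds by
  construction; default radii 4.0 / +2.5 / +3.5 mm at the test scale;
* a central ellipsoidal ventricle with CSF-like intensities, labelled
  background, providing a periventricular placement surface;
* 0–n WMH blobs (jittered ellipsoids) placed in deep white matter or
  along the ventricular surface, at a configurable minimum distance
  (default 6 mm) from the tumor complex, pairwise separated, clipped to
  brain and non-ventricle tissue.

Class mean intensities per channel (T1, T1PC, T2, FLAIR), arbitrary
units: brain (70, 70, 40, 45), ventricle (25, 25, 95, 20), NCR
(35, 25, 70, 55), ED (55, 60, 75, 80), WMH (50, 68, 75, 80), AT
(60, 95, 65, 65).  These encode the radiology the task depends on: AT is
the brightest class on T1PC (contrast enhancement), NCR is dark on T1PC,
ED and WMH are iso-intense to each other on T2 and FLAIR and both
brighter than brain, and WMH shows no enhancement (T1PC ≈ normal brain).
ED and WMH therefore differ only subtly (T1/T1PC, Euclidean profile gap
≈ 9 intensity units) and mainly by spatial context — edema wraps the
tumor, WMH sits distally — which is precisely the discrimination the
fifth class exists for.  An optional hard mode, `AMBIGUOUS_WMH_PROFILE`,
removes even that residual gap (WMH ≡ ED voxelwise), leaving spatial
context as the only cue.  Additive Gaussian noise (default sd 3, all
channels, brain voxels only) controls difficulty: at the default, a
per-voxel nearest-profile classifier still separates the classes well
except at the ED/WMH margin.

Cohort generation derives per-case seeds from a master seed and, when a
target total-WMH-volume range is set, spreads per-case targets evenly
(then shuffled) across the range, so the 100/1000/5000/10000 mm³ strata
of the volume-stratified analyses are all populated by construction.
Large targets are split across more blobs (per-blob volume capped near
1150 mm³) and radii are inflated ~8 % to offset voxelisation/clipping
losses.

What the phantoms do **not** model: anatomy beyond one ventricle, partial
volume and bias fields, k-space/MR physics, inter-subject anatomical
variability, multifocal tumors, and the ambiguous confluent
periventricular caps of real severe SVID.  Passing the phantom studies
demonstrates that the pipeline's machinery (sampling, optimization,
inference, metrics) is correct and that the architecture can exploit
multi-channel + spatial context; it does not certify clinical-grade
accuracy on real mpMRI.

## Scaled-down studies

Full-scale training (240×240×155 grids, 4 levels / 32 filters, 80³
patches, 600 epochs, 10-model ensembles) is a multi-GPU-hour workload.
The built-in studies in `neuroseg.experiments` keep every pipeline stage
but shrink the problem so each study runs in minutes on one CPU core:
64-cube phantoms, 2 levels / 8 base filters, Adam at 3e-3 (a higher
initial rate suited to the small network and short schedule; the
polynomial decay form is unchanged), and no augmentation (the phantom
cohort already spans the generator's variability, and the short schedule
is better spent on clean gradients).  The end-to-end study trains one
model on 32-voxel patches, 16 patches per epoch for 30 epochs; the
comparison study trains 2-member ensembles on 24-voxel patches, 24
patches per epoch for 28 epochs per member.

* `end_to_end_study`: 20-case cohort spanning 0–12000 mm³ of WMH, 15
  train / 5 held-out, 5-class model; reports held-out WT/WMH Dice, WT
  HD95 and the predicted-vs-true WT volume correlation.
* `class_comparison_study`: a 24-case WMH-rich cohort (every case ≥ 2
  distal blobs, 1500–9000 mm³ total).  The 5-class model and a 4-class
  model trained on the same cases with WMH relabelled to background (the
  label set the original tumor-only annotation provides) share one
  training protocol — 2-member ensembles with softmax averaging (the
  full-scale method's own validation-time device), 24-voxel patches, 28
  epochs per member — and held-out (10-case) whole-tumor HD95 medians are
  compared.  The expected direction is the 5-class median no worse than
  the 4-class median: residual 4-class errors at distal WMH are
  whole-tumor false positives far from the true surface, whereas a fully
  converged pair differs only by ±1-voxel surface jitter (a tie).
  Because single replicates are noisy at this scale, the check is a
  majority across three seeded replicates, and even so it remains a
  genuinely stochastic comparison: on these clean phantoms the 4-class
  model usually *does* learn to suppress WMH (exactly the behaviour the
  full-scale study reports on its validation split, where the HD95
  difference vanished), so the typical outcome is a tie decided at
  sub-voxel surface jitter, and occasional replicates fall on either
  side of it.

## Known limitations

* The numpy network trains small configurations only; the full-scale
  configuration is expressible but impractical on CPU.
* The exact polynomial-decay parameterization, the loss function, batch
  size (2) and patches-per-epoch (200 at full scale) are conventions
  where the original recipe is silent; all are configurable.
* Whether "maximum rotation 45°" is per-axis or in-plane is ambiguous;
  the augmenter draws per-axis angles, configurable via `AugmentSpec`.
* The 4-class/5-class comparison at phantom scale reproduces a direction,
  not effect sizes; a well-trained 4-class model can learn to ignore
  phantom WMH entirely (ties are the expected asymptote), mirroring the
  full-scale observation that the benefit concentrates where WMH burden
  is high and models are imperfect.
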