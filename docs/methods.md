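# Methods

## The subtraction model

The package detects focal interictal hypometabolism by comparing a
patient's clinical [18F]FDG-PET with a *pseudo-normal* PET predicted from
their own T1w MRI. The comparison is strictly within-subject:

1. **Preprocessing** (`io_prep`). Inputs are assumed co-registered on a
   common lattice in template space. The clinical PET is smoothed with a
   Gaussian kernel of 2 mm FWHM (the "2 mm filter" is read as FWHM, the
   neuroimaging convention; σ = FWHM/√(8 ln 2), per-axis in voxel units)
   and intensities are min-max scaled to [0, 1] over the whole volume.
   Order is smooth-then-scale by default and configurable, since the two
   operations do not commute through the affine rescale.
2. **Prediction** (`gan`). A 3D conditional adversarial network translates
   the T1w volume into a PET volume (below). Alternatively a predicted
   volume may be supplied directly; it then receives the same preprocessing
   as the clinical PET so the subtraction compares like with like (a
   network prediction is already produced in preprocessed space and is not
   re-smoothed).
3. **Mean-ratio scaling** (`core.scale_predicted`). The prediction is
   multiplied by mean(clinical)/mean(predicted), both means taken within
   the brain mask — background would otherwise dominate the ratio. After
   scaling the two in-mask means agree to 1e-9 relative.
4. **Standardization** (`core.difference_zmap`). D = clinical − predicted
   is converted to Z scores using the in-mask mean and *population*
   (n-denominator) SD, the usual convention when standardizing a full voxel
   population. By default the map is negated ("hypometabolism-positive")
   so that reduced clinical uptake produces positive Z and the one-tailed
   threshold below is operative for hypometabolism; a flag selects the
   other tail.
5. **Cluster detection** (`core.extract_clusters`). Voxels with Z > 2.33
   inside the brain mask eroded by 3 one-voxel iterations (border-artifact
   control; 6-connected structuring element by default) are grouped into
   connected components (26-connectivity default, 6/18 available).
   Components smaller than 1 mL are discarded; the minimum extent is
   expressed in mL and converted by the actual voxel volume, so "1000
   voxels" holds exactly at 1 mm³ voxels and generalizes elsewhere. Both
   peak and mean Z are reported per cluster, since either may be wanted as
   "the" cluster score.

Degenerate inputs fail loudly: constant volumes cannot be min-max scaled,
identical clinical/predicted pairs have σ_D = 0, erosion that empties a
mask is an error, and all cross-volume operations validate lattice
(shape + affine) agreement.

## The translation network

The generator is a 3D U-Net with residual units at each stage: encoder
channel widths (32, 64, 128, 256, 512), strided 3³ convolutions for
downsampling, transpose 2³ convolutions for upsampling, decoder widths
(512, 256, 128, 64, 32), skip concatenation at every resolution, PReLU
activations and batch normalization throughout, and a sigmoid head (data
live in [0, 1]). The patch edge must be divisible by 2^(depth−1). The
discriminator is a patch classifier on the concatenated (T1w, PET) pair:
strided convolutions of widths (64, 128, 256, 512) and a final 1-channel
score map (no normalization on its first stage).

Training alternates Adam updates (lr 2e-4 constant, β = (0.5, 0.999)) on
32³ patches whose centers are sampled uniformly inside the brain mask.
Losses follow the pix2pix convention:

- generator: ½ (λ·MSE(fake, real) + adv(D(T1w, fake), 1)), λ = 200;
- discriminator: ½ (adv(D(T1w, real), 1) + adv(D(T1w, fake), 0)),

with the adversarial term a binary cross-entropy on logits by default
(least-squares optional). Inference uses batch-norm running statistics
(eval mode). Whole-volume prediction is sliding-window: windows of the
training patch size tile the reflect-padded volume at 50% overlap, each
prediction is blended under a separable raised-cosine weight (offset by
0.01 so no voxel has zero weight), and the accumulated sum is normalized by
the accumulated weight — the effective weights sum to 1 everywhere, so a
generator that computes the identity reproduces its input exactly.

The network layer is implemented in-package as a small reverse-mode
autodiff on numpy float32 arrays (`sipcom.nn`): conv3d / conv_transpose3d
via explicit im2col/col2im written as k³ strided slice operations,
batch normalization with running buffers, PReLU, and the two losses.
Convolution gradients are exact adjoints (verified against finite
differences and a scipy correlation oracle in the tests). Computation is
single-threaded numpy; model building and training are pure functions of
the config seed, so runs are bit-reproducible on a given platform.

Checkpoints are a single zip archive holding the parameter arrays (npz),
the config and training metadata (JSON); save → load → predict is
bit-identical.

## Synthetic phantoms

`phantom` generates the paired data every downstream stage is tested on.
Anatomy is an ellipsoidal brain (default semi-axes 50/60/50 mm) with
concentric tissue shells — ventricular CSF core, white matter, a grey
matter shell, outer CSF — at normalized ellipsoidal radii 0.18/0.62/0.88/1.
Each tissue class has a mean intensity per modality (T1w: WM 0.85 > GM 0.50
> CSF 0.10; PET: GM 0.90 > WM 0.35 > CSF 0.05, i.e. cortical FDG uptake
brightest), so the PET is a deterministic function of the T1w tissue map in
the noiseless limit — exactly the structure a translation model must learn.
Gaussian voxel noise (sd 0.02 of the intensity range) is added *before*
Gaussian smoothing (FWHM 3 mm, a point-spread proxy), giving the spatially
correlated noise characteristic of reconstructed PET. The full study is a
pure function of the spec (seed included). An optional independent PET
noise seed yields a second PET realization of the same anatomy; such a pair
stands in for (prediction, truth) in oracle-predictor experiments, since a
perfect noiseless oracle would make the difference image degenerate
(σ_D = 0).

Hypometabolic lesions multiply PET uptake by a factor in (0, 1) inside a
sphere, with optional Gaussian edge feathering (support truncated at
radius + 3·softness so locality is exact); voxels outside the support are
returned bit-for-bit unchanged.

The toy atlas partitions the mask into 36 labels (18 sectors × 2
hemispheres) by geometric sectoring — hemisphere from the world x sign, six
azimuthal wedges × three ellipsoidal-radius bands — and maps each sector to
one of the 18 canonical cortical region codes. The assignment is arbitrary
but stable: the atlas exists to exercise label bookkeeping and
cluster/region overlap logic, not anatomy.

What the phantoms deliberately do not model: anatomical realism, partial
volume effects, scanner physics, registration error, inter-subject
anatomical variability. Passing phantom tests therefore demonstrates the
correctness of the pipeline's arithmetic and detection logic under
controlled truth, not clinical performance on real data.

## Image-quality metrics

Masked MAE, PSNR (10·log10(range²/MSE), +∞ sentinel for identical inputs)
and SSIM score predicted against true PET. SSIM uses the standard local
statistics with K1 = 0.01, K2 = 0.03 and a 7³ uniform window (unbiased
variance); by default both volumes are zeroed outside the mask and the SSIM
map is averaged over windows *centred* in-mask, so background cannot
inflate similarity — a whole-volume mode is provided since reporting
conventions differ. MAE/PSNR likewise offer mask-restricted means.

## Cohort evaluation

Detections are localized to 18 bilateral cortical regions (36 codes). The
packaged fixture is a 20-patient surgical cohort: per patient the SEEG
onset regions, the surgery (resection zone — "Idem" resolves to the SEEG
column), MRI status, Engel outcome class, and the region sets of the three
detection methods, written in a compact dialect ("AML + ATL R") where a
hemisphere letter distributes leftward over the codes since the previous
hemisphere letter. A patient is *concordant* for a method when the
method's set intersects the RZ. Rates are exact count/size fractions,
overall and in Engel-good (I–II)/poor (III–IV) and MRI-positive/negative
subgroups.

Region-level recall and precision are micro-averaged over patients:
recall = Σ|method ∩ RZ| / Σ|RZ|, precision = Σ|method ∩ RZ| / Σ|method|.
This is this package's definition, attached to the output; other
definitions (e.g. patient-averaged) give different numbers. Control
false-positive counts are summarized as mean ± sample (n−1) SD with range,
the convention for cohort "mean ± SD" reporting.

## Problem sizes and defaults used in shipped analyses

The shipped tests and the acceptance script use: 64³ phantoms at 1 mm for
lesion recovery (20 subjects, one 2 mL lesion at factor 0.7, oracle
predictor; lesion-free runs under the same seeds for FP counting), ≥100
random 16³–32³ Z-maps for the cluster-extraction oracle comparison, and a
toy translation-model training — 4 noiseless 48³ phantoms at 2 mm, encoder
widths (8, 16), 16³ patches, 50 epochs, batch 8, 16 patches/pair — chosen
as the smallest configuration on which the learning signal (held-out
masked SSIM and MAE against the untrained baseline) is unambiguous.
Full-scale defaults (32³ patches, widths to 512, 1000 epochs, batch 20)
remain the config defaults and are exercised structurally (shape, parameter
count, forward pass) rather than trained in the shipped analyses.

## Known limitations

- The numpy network layer is CPU-bound and single-threaded; it is meant
  for patch-scale models and phantom-scale studies, not full-resolution
  clinical training runs.
- Batch-norm inference uses running statistics; with very short toy
  trainings those statistics are still moving, which slightly degrades
  whole-volume predictions relative to training-mode statistics.
- Registration, bias correction and skull stripping are not provided;
  inputs must arrive co-registered with a mask.
- The toy atlas is geometric; region assignments on phantoms carry no
  anatomical meaning.
- Exact bit-reproducibility of training holds for a fixed platform/BLAS;
  across platforms, reproducibility is statistical rather than bitwise.
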