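# Methods

`damagemap` profiles DNA damage in thick 3D fluorescence histology volumes.
This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Problem setting

Input is a multi-channel confocal z-stack of a cleared, thick (~125 µm)
tumor tissue section — DAPI (all nuclei), γH2AX (phosphorylated H2AX,
marking DNA double-strand-break foci), CD8 (membrane marker of cytotoxic
T cells), optionally a pan-protein channel — together with a 3D *instance*
segmentation of nuclei produced by an external segmenter such as Cellpose.
The package never segments nuclei itself; the label volume is a first-class
input. All arrays are indexed `(z, y, x)`; physical scale is carried as a
`(z, y, x)` voxel-size triple in micrometers. The default lateral pitch is
0.32125 µm/px (fixed by the identity 32 px = 10.28 µm at 63× magnification);
the axial step defaults to the lateral pitch — an isotropic assumption that
makes radii quoted in pixels and in micrometers interchangeable — and is
configurable because acquisition z-steps differ between experiments.

## Marker-positive cell identification

γH2AX foreground is far brighter than autofluorescence background, so a
single global threshold (Otsu by default, or a fixed value) binarizes the
marker channel. The binary mask is then superimposed on the nuclei instance
segmentation: for each nucleus the overlap fraction
|instance ∩ mask| / |instance| is computed, and the cell is called positive
when the fraction reaches a threshold. Defaults:

| parameter | default | rationale |
|---|---|---|
| γH2AX overlap threshold | 0.5 | majority overlap is the natural reading of "significant overlap"; exposed for sensitivity analysis |
| CD8 overlap threshold | 0.2 | the CD8 marker is membranous; after dilation the signal can only occupy the outer shell of the dilated instance (~30–45 % of its volume for nuclear radii 4–10 voxels), so majority overlap is geometrically unreachable |
| CD8 instance dilation | 2 voxels (Euclidean ball) | the membrane ring sits just outside the nuclear surface; without dilation the overlap is exactly zero |

Dilation is implemented through the Euclidean distance transform: every
background voxel within the dilation radius joins its *nearest* original
instance, so instances can never merge and overlap fractions stay per-cell.
γH2AX positivity uses no dilation (the signal is intranuclear).

Each positive nucleus is cut into a 64×64 2D patch for the texture
branches: the central z-plane of its bounding box is taken from the γH2AX
channel, voxels outside the instance are zeroed (so neighboring nuclei do
not contaminate the texture; switchable via `mask_background`), the slice
is centered on the canvas — padded if smaller, isotropically rescaled if
larger — and min–max scaled to [0, 1]. A constant slice carries no texture
and maps to all zeros. Patches are 2D because the latent model consumes
64×64 images; 3D texture offsets are a possible extension, not implemented.

## GLCM texture features

For each patch a gray-level co-occurrence matrix is computed after uniform
quantization to 32 levels (a balance between intensity resolution and count
sparsity on 64×64 patches), at distance 1 for the four axis/diagonal
directions, symmetrized, normalized, and averaged over offsets. Four
Haralick-style features summarize the joint distribution p(i, j):

- energy `Σ p²` — uniformity,
- contrast `Σ (i−j)² p` — local variation,
- cluster prominence `Σ (i+j−μᵢ−μⱼ)⁴ p` — fourth moment about the marginal
  means; heavy, asymmetric co-occurrence mass scores high,
- correlation `Σ (i−μᵢ)(j−μⱼ) p / (σᵢσⱼ)`, defined as 1 when a marginal
  variance vanishes (a constant image is perfectly self-correlated).

Counting uses `skimage.feature.graycomatrix`; the feature reductions are
computed here and verified in the tests against an independent double-loop
summation oracle to 1e−10 relative precision. Background zeros participate
in counting as the lowest gray level by default (they carry the
nucleus/background geometry); excluding them is exposed as a flag.

## VAE-GAN latent representation

The second representation branch is a VAE-GAN trained on the γH2AX patches:
an encoder mapping a patch to a 16-dimensional diagonal Gaussian
(μ, log σ²), a generator decoding a latent vector to a [0, 1] image, and a
discriminator whose fourth-convolution feature maps provide a *learned
similarity metric* — reconstruction error is measured both pixel-wise and
in that feature space. Architecture: encoder = three 4×4 stride-2
convolutions (32/64/128 channels) with batch normalization + two dense
layers (256/128) + linear (μ, log σ²) heads; generator mirrors it with
three transposed convolutions; discriminator = five convolutions
(32/64/128/256/1), batch normalization on the middle layers, spatial mean
of the last map as the real/fake logit. Kernel sizes, strides, channel
widths, and the two-dense-layer head are free choices documented here.

Training alternates one discriminator update (non-saturating adversarial
loss on real vs reconstruction) and one joint encoder+generator update
minimizing

    w_kl·KL + w_pix·pixel-MSE + w_feat·feature-MSE + w_gan·adversarial,

each module under Adam at learning rate 1e−4; the reference schedule is
500 epochs (smoke runs use 20). The loss terms are *reported* as
per-element means; the default weights (w_kl = w_gan = 1,
w_pix = w_feat = 4096 = 64·64) restore the canonical per-sample
sum-over-dimensions scaling of the reconstruction terms relative to the
per-sample KL. This weighting matters: with unit weights on mean-scaled
terms the KL dominates and the posterior collapses onto the prior —
measured on the two-class synthetic bank, latent KMeans recovery falls
from ARI ≈ 0.9 to ≈ 0.02 after 20 epochs — while the sum-scaling keeps
ARI ≥ 0.9. Optional augmentation adds flips and 90° rotations, which
preserve texture statistics. Downstream analysis always uses the posterior
mean μ, never a sample, so encoding and everything after it is
deterministic.

The networks are implemented directly on numpy (im2col convolutions,
explicit backward passes, Adam), so training runs on any CPU-only host;
every backward pass is validated against finite differences in the test
suite. Batch statistics make training deterministic given the seed;
inference uses running statistics.

## Pseudo texture classes and neighborhood profiles

Per-cell feature vectors (the four GLCM features, or the 16-dim μ) are
standardized per column — without this the fourth-power prominence feature
dominates the Euclidean metric — and clustered with KMeans (k = 5 by
default, 10 restarts, seeded) into pseudo texture classes: surrogate
phenotype labels in the absence of expert annotation. A 2D PCA projection
is stored for inspection. Cluster indices are arbitrary; cross-run
comparisons should match labels via cluster-center distances.

Spatial profiling places a sphere of radius r (in lateral pixels; axial
displacements rescaled by the voxel anisotropy) around every labeled
γH2AX+ cell and counts neighbors per class, self excluded, a neighbor
counting iff 0 < d ≤ r between centroids. Aggregating the mean class-j
count over class-i centers gives a k×k co-occurrence heatmap per region
and, pooled, per condition; means rather than raw sums keep regions of
different cell density comparable (raw sums remain available). Classes with
no center in a region are flagged absent, never imputed. The same counting
applied around CD8+ cells at radii 32/64/128 px (10.28/20.56/41.13 µm)
quantifies immune-cell/DNA-damage colocalization. Counts are computed with
a KD-tree but are exactly equal to the quadratic scan (verified in tests).

Condition contrasts use a region-label permutation test: the region is the
exchangeable unit; condition labels are shuffled across regions (999
permutations by default, seeded, add-one correction, two-sided). With a
single region in a condition, differences are reported and p-values
suppressed. This inferential layer is an extension beyond visual heatmap
comparison; it is the minimal test consistent with the region-level design.

## Synthetic data

The generator exists so every stage is testable with known ground truth.
One region = non-overlapping axis-aligned ellipsoidal nuclei (radii
jittered in 4–10 voxels; disjointness enforced with a conservative
bounding-sphere test) in a (z, y, x) box; defaults mirror the targeted
acquisitions (302×302 px × 130 planes, ~700 nuclei; tests shrink both).
DAPI fills every nucleus; a configured fraction of nuclei is γH2AX+ and
rendered per texture class — bright Gaussian-ball foci and/or a diffuse
pan-nuclear fill; CD8+ cells get a 1–2-voxel membrane shell outside the
nuclear surface, which deliberately forces the dilation step to matter.
Additive Gaussian noise models background autofluorescence.

The two default texture classes (class 0: 10–16 foci of radius 1.5–2.5 on
a 0.5-level fill; class 1: no foci, 0.9-level diffuse fill) are built to
be unambiguous: both fills sit far enough above background that Otsu plus
majority overlap reproduces the planted positivity flags exactly, and the
classes separate in both GLCM and latent space. The generator does *not*
simulate optics (PSF, anisotropic blur, shot noise), nuclear shape
variation beyond ellipsoids, staining gradients, or segmentation errors —
so green tests demonstrate the correctness of the identification, texture,
and profiling logic, not robustness of thresholding or clustering on real
tissue.

The patch-bank generator renders single-nucleus 64×64 patches (elliptical
nuclei at 33–37 % of the canvas, textures per class, light noise) as
training fuel for the latent model and as the planted-truth input for
recovery tests.

## Problem sizes used in tests and in the acceptance script

Oracle equivalences run on 100 random matrices / 100 random cells
(seconds). Smoke training uses 200 patches, 20 epochs, batch 32, three
seeds. Planted-class recovery uses 50–100 patches per class. The
calibration study uses 16 exchangeable regions (24×96×96 voxels, 40
nuclei) with 100 relabelings of 999 permutations each; the power study
uses 10 regions per condition with the γH2AX+ fraction doubled (0.2 → 0.4)
in treated regions. Pipeline determinism runs the full chain twice on four
32×128×128 regions. These sizes are the package's own desk-scale choices;
all are parameters, not limits.

## Known limitations

- The VAE-GAN is CPU-oriented and desk-scale; no GPU path, no mixed
  precision, no FID-style synthesis metrics. Reproducibility is guaranteed
  per backend (BLAS) build, as with any floating-point training.
- GLCM and patches are 2D (central plane); fully 3D texture is future work.
- Positivity is a global-threshold call; per-cell adaptive thresholds are
  not implemented.
- KMeans pseudo-classes are surrogate labels: nothing ties a cluster index
  to a biological damage/repair state without annotation.
- The permutation test treats regions as exchangeable and ignores spatial
  autocorrelation between regions from the same sample.
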