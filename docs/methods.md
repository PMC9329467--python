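# Methods

`sketchct` implements sketch-conditioned synthesis of lung-tumor CT
images with a conditional GAN, together with the full pipeline around it:
phantom data generation, CT preprocessing, image-quality metrics, and a
data-augmentation evaluation harness.  This note records the models, the
parameter choices that matter, and the numerical decisions, in the order
the pipeline runs.

## Synthetic phantoms

The clinical data this kind of model is trained on (chest CT of
biopsy-confirmed lung tumors) cannot be distributed, so every experiment
in this package runs on seeded synthetic phantoms.  A phantom is a 3-D HU
volume containing:

* an air-density lung background (−880 HU healthy; −700 HU plus patchy
  +150 HU blobs for the "pneumonia-like" degraded variant),
* a lobulated ellipsoidal tumor of prescribed long diameter (soft-tissue
  density, ~+30 HU) whose long semi-axis is aligned with x,
* optional random-walk tubular vessels (−30 HU) and a chest-wall slab
  (+40 HU) on one face,
* additive Gaussian HU noise (default sd 12 HU, a typical lung-CT noise
  level).

Lobulation carves smooth inward lobes (von-Mises-like angular bumps) with
amplitude up to 35 % of the local radius; the two long-axis poles are
excluded from carving so the annotated long diameter stays exact.  Because
the lobe directions are drawn before any size-dependent state, tumor
volume is monotone in the requested diameter at a fixed seed.

Three surrogate histology classes (`ADC_like`, `SCC_like`, `SCLC_like`)
differ in lobulation range, aspect ratio of the short semi-axes, rim
sharpness, and internal heterogeneity.  The shape components are
deliberately strong: the augmentation mechanism transfers class
information through sketches, so class signal must be visible in tumor
contours, not only in texture.  Default sampling ranges (diameters
8–30 mm, 70 % chest-wall contact, 25 % pneumonia-like backgrounds) emulate
a hospital case mix of small nodules through large masses.

What the phantoms do *not* model: real pulmonary anatomy, scanner
reconstruction kernels, DICOM metadata, partial-volume effects, or real
histology texture.  Passing tests therefore demonstrate that the
*pipeline and models* behave as specified, not that the generator
produces clinically realistic images.

## Preprocessing

Each annotated volume is cropped to a cube of physical side twice the
tumor's long diameter (out-of-volume voxels padded with −1000 HU air),
then resampled trilinearly onto an exactly cubic isotropic grid at
0.625 mm.  Test volumes contribute the single central axial slice;
training volumes contribute oblique planes through the cube center at
every pair of tilts from {−30°,…,+30°} in 10° steps about the two
in-plane axes — the full 7×7 grid — each emitted unmirrored and
left–right mirrored: 98 slices per volume, so 127 training volumes give
12,446 images and 20 test volumes give 20.  Rotations compose about the
image axes with trilinear interpolation and nearest-border padding.

Slices are resized bilinearly to the model resolution (128×128), rendered
through the lung window (level −600 HU, width 1600 HU) with half-up
rounding to 8 bits (so the window center maps to 128 exactly), and saved
as 24-bit RGB PNGs with three equal channels; sketches/edges are 8-bit
binary PNGs.

Edges stand in for hand-drawn sketches and are produced by a Canny
implementation written for 8-bit thresholds: 5×5 Gaussian smoothing
(sigma 1.1 via the usual kernel-size convention), 3×3 Sobel gradients,
four-sector non-maximum suppression (strict comparison on one side so a
symmetric step edge keeps exactly one pixel), and hysteresis at raw-Sobel
thresholds 128/200 with 8-connected linking.  Tests cross-check it
against scikit-image's Canny (thresholds mapped by the factor 4·255 that
separates the two Sobel normalizations); agreement is ≥ 99 % of pixels on
phantom renders, with differences confined to borders and threshold-edge
ties.  `make_hand_sketch` emulates a doctor's free-form drawing from an
edge image: a detail level in [0, 1] interpolates between lesion-only and
everything, plus stroke jitter, thickness variation, and partial erasure.

## Models

Both generators share a U-Net: seven stride-2 4×4 convolutions
(channels 64→128→256→512→512→512→512 at the default width, instance norm
except on the first and bottleneck layers, leaky-ReLU 0.2), mirrored by
seven decoder stages with skip concatenation (ReLU, tanh output in
[−1, 1]).  For a 128×128 input the bottleneck is 1×1.  Decoder stages use
nearest-neighbor upsampling followed by a 3×3 convolution
("resize-convolution") rather than a transposed convolution; the
up-convolution kernel is not prescribed by the design being followed, and
this choice makes the baseline and style decoders identical except for
modulation (and avoids checkerboard artifacts).

The style generator replaces each decoder convolution with a style
block: a shared mapping network (four 512→512 fully connected layers,
leaky-ReLU) turns a standard-normal latent into a style vector, and a
per-block head of four fully connected layers turns that vector into one
scale per input channel.  The 3×3 kernel is multiplied per input channel
by these scales and then demodulated (each output channel's effective
kernel rescaled to unit L2 norm, eps 1e−8).  Demodulation is on by
default and config-switchable.  Implementation note: scaling the kernel
per input channel is algebraically identical to scaling the input
channels before a shared-kernel convolution, with demodulation a
per-(sample, output-channel) rescale; the code uses this form so one BLAS
convolution serves the whole batch.  The style heads initialise their
output bias at 1 with small weights, so training starts near the
unmodulated operator.

The patch discriminator (shared by both models) scores the channel
concatenation of sketch and image through four stride-2 convolutions
(64/128/256/512, instance norm after the first) and a 3×3 sigmoid head,
yielding an 8×8 probability grid at 128×128.

All networks run on a small tape-based reverse-mode autodiff layer
written on NumPy (`sketchct._nn`): im2col convolutions, the modulated
convolution above, instance norm, the pointwise ops, and Adam/SGD.  Every
operator's gradient, and the composed generator gradient, is verified
against central finite differences in the test suite.  Computation is
float32 end to end; float64 is used for gradient checks.

## Objectives and training

The discriminator minimizes −[E log D(x|y) + E log(1 − D(G(z|y)))]; at
the uniform D = 0.5 equilibrium this equals 2 log 2.  The generator uses
the non-saturating adversarial term −E log D(G(z|y)) (standard practice;
the minimax form alone does not determine this choice) plus an L1
reconstruction penalty λ·E|x − G(z|y)| with λ = 100, the canonical
pix2pix weight.  Sigmoid outputs are clamped to [1e−7, 1 − 1e−7] before
logs.  Training alternates one discriminator and one generator Adam step
(β₁ = 0.9, β₂ = 0.999) per batch; the style model draws a fresh latent
per sample per step so the mapping network trains through the generator
loss.  Production defaults are learning rate 1e−5, batch 5, 400 epochs
for the baseline and 200 for the style model; the desk-scale runs in the
tests use 32×32 images, narrower networks (8 base channels), a 2e−3
learning rate and tens of epochs, chosen once as the package's scaled
study conditions.  Runs are reproducible from the config seed; NaN losses
abort with a diagnostic.

A numerical caveat: with near-constant inputs (a blank sketch region is
constant) instance-norm variances approach zero and the normalisation
1/√(var + eps) makes the loss surface extremely stiff, so single-step
descent is only observable at very small plain-gradient steps; the
gradient itself is exact (finite-difference-verified), and multi-epoch
Adam training descends reliably.

## Metrics

PSNR and the global-statistics SSIM follow their closed forms on 8-bit
images; SSIM uses the printed constants C₁ = 0.01·255², C₂ = 0.03·255²
and image-wide moments (a sliding-window mode is available behind a
flag).  Identical images report PSNR as a documented 99 dB sentinel so
aggregate means stay finite.  FID fits a Gaussian to per-image deep
features of each group and evaluates
‖μ_F − μ_G‖² + Tr(Σ_F + Σ_G − 2(Σ_F Σ_G)^½); the matrix square root is
computed from the symmetric product Σ_F^½ Σ_G Σ_F^½ by eigendecomposition
with numerically tiny negative eigenvalues clipped to zero (a relative
1e−8 tolerance; anything larger raises).  LPIPS channel-unit-normalizes
each layer's feature maps, squares the (optionally per-channel weighted)
difference, averages spatially and sums over layers; weights default to
ones.

Feature extractors are pluggable behind a two-method interface
(`feature_maps`, `features`).  The default is a small deterministic
randomly initialised three-stage CNN (fixed seed), which makes FID and
LPIPS fast, dependency-free and exactly reproducible at desk scale; an
ImageNet-pretrained Inception-v3 / AlexNet backbone can be dropped in to
recover the conventional large-scale definitions.  Report semantics
follow the evaluation tables: PSNR/SSIM/LPIPS are averaged over
index-aligned pairs, FID is computed once over the two groups (hence
requires at least two images per group).

## Augmentation study

The harness asks whether pretraining a classifier on generated images
helps a scarce real-data task.  Three disjoint phantom cohorts are drawn:
45 tumors to train the style model, 15 (five per class — augmentation
targets the data-scarce regime) for classification with one
representative axial image each, and 12 whose oblique-slice edge sets
(every 7th of the 98 training slices) drive generation with five fresh
latents per edge (280 images per class).  The GAN trains on
oblique-augmented pairs of the generation-training cohort.  A compact
AlexNet-like CNN (three stride-2 convolutions, two fully connected
layers) is pretrained on the generated images (all layers, SGD), then
only its fully connected layers are fine-tuned on the real training
folds — the convolutional weights are hash-verified unchanged.  Accuracy
is mean ± sd over three repeats of stratified three-fold
cross-validation, stratified by tumor so no slice of a held-out tumor
appears in its training folds.  The no-pretraining baseline trains all
layers on the same real training folds.

The expected direction (augmented ≥ baseline) holds with a mean margin
of a few accuracy points under the default conditions; because one study
is a single draw of three small cohorts, individual reruns at unusual
seeds can invert the ordering, which is the same cohort-level variance a
small clinical study would show.  Production-protocol defaults
(26 tumors per class, 100-epoch phases, learning rates 1e−5/1e−4) remain
the config defaults; `pretrain_epochs = 0` is allowed as the documented
fine-tune-only limit.

## Scale of the shipped experiments

The test suite and the acceptance script exercise the complete method at
sizes a single CPU handles comfortably: counting checks run the full
127-tumor slice pipeline and the full 980/4900-per-class generation at
128×128 with a narrow untrained generator (2 base channels); training
and augmentation checks run at 32×32.  Nothing in the method depends on
these sizes; they are the package's chosen desk-scale study conditions.

## Known limitations

* Phantom realism is deliberately minimal; results quantify pipeline
  correctness and the augmentation mechanism on synthetic contrasts only.
* The default FID/LPIPS extractor is not ImageNet-trained, so absolute
  metric values are not comparable to published table values; only
  relative comparisons within a run are meaningful.
* The left–right/head–tail tilt pair is composed about image axes;
  composing about patient axes would differ by interpolation details.
* No learning-rate schedules, EMA, or multi-device training.
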