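# Methods

## Pipeline

`histovae` compares three experimental arms on one shared
train/test/validation split:

1. **baseline** — train the CNN classifier on the original patches and
   evaluate on the original test partition;
2. **cvae** — train the convolutional VAE unsupervised on the training
   partition, reconstruct all three partitions, train the CNN on the
   reconstructed training set and evaluate it on the reconstructed test
   set;
3. **dvae** — identical, with the denoising VAE (noise factor 0.2).

Evaluating the VAE arms on *reconstructed* test images is the default
because the classifier is fitted to the reconstruction distribution; a
config flag (`eval_on_reconstructed=False`) evaluates on the original test
images instead for the domain-shift comparison.

## Model and loss

The VAE assumes a 5-dimensional diagonal-Gaussian posterior
q(z|x) = N(μ(x), σ²(x)) with standard-normal prior. The training loss is
the negative evidence lower bound with a Bernoulli likelihood per pixel:
pixelwise binary cross-entropy summed over the 4,096 pixels and averaged
over the batch, plus the closed-form KL term −½Σ(1+log σ²−μ²−σ²). The
sum scale (not a per-pixel mean) is the default so the reconstruction and
KL terms have their natural relative weight; `loss_scale="mean"` is
available, which effectively multiplies the KL weight by 4,096 and drives
the posterior to the prior at small scale.

The denoising variant corrupts the encoder input with additive Gaussian
noise scaled by the noise factor (0.2) and clipped back to [0,1], drawn
fresh each batch from a dedicated RNG stream; the loss always targets the
clean image. Because corruption, latent sampling and shuffling use
independent child streams of the seed, setting the noise factor to zero
reproduces the plain VAE's loss trajectory bit-for-bit — a property the
tests assert exactly.

Reconstruction at inference samples the stochastic latent z by default
(seeded); `use_mean=True` decodes μ for a deterministic, slightly
smoother reconstruction.

The classifier head is Dense(2) with per-unit sigmoids trained under
categorical cross-entropy; scores are renormalised to sum to one inside
the loss (the convention of mainstream frameworks), so both units receive
gradient and the closed forms hold: ln 2 per sample at uniform (0.5, 0.5)
scores, → 0 on a saturated correct prediction. A softmax head is available
by flag. The two MaxPool layers have pool size (1,1) and are exact
identities, kept so the 10-layer enumeration of the architecture is
preserved; all spatial downsampling comes from the stride-2 convolutions
(64→32→16→8), making the flattened width 8·8·256 = 16,384. Convolutions
use "same" padding — required for those sizes — and Glorot-uniform
initialisation.

Both networks are implemented on a small numpy engine with manual
backpropagation (`histovae._nn`): convolution via im2col/col2im, the
transposed convolution as the exact adjoint of the strided convolution,
and Adam with framework-default moments. Numeric finite-difference tests
check every layer's gradients. Single-threaded numpy makes training
deterministic given (seed, platform).

## Parameters that matter

| parameter | default | why |
|---|---|---|
| latent dimension | 5 | the compression bottleneck of the method |
| noise factor | 0.2 (dvae), 0 (cvae) | corruption scale of the denoising arm |
| VAE learning rate | 10⁻³ | Adam default; decays ×0.5 after 2 stalled epochs (reduce-on-plateau on validation loss) |
| CNN learning rate | 5·10⁻⁴ | fixed Adam rate of the classifier |
| dropout rate | 0.2 | regularisation of the classifier |
| batch size | 64 | throughput/stability compromise on one CPU |
| VAE / CNN epochs | 30 / 20 (config defaults); 10 / 5 in the desk-scale preset | see problem sizes below |
| split fractions | 0.56 / 0.20 / 0.24 | the train/test/validation ratio of the full-scale 28,000/10,000/12,000 split |

Splitting draws one seeded permutation and takes contiguous slices in
train/test/validation order; a stratified variant (per-class quotas) is
available by flag. Balanced subsampling and file enumeration are
lexicographically ordered before seeding so results depend only on the
seed, never on filesystem order.

## Synthetic data: what it does and does not show

The generator emulates only the *statistical* structure needed to test the
pipeline: 64×64 grayscale patches in [0,1] with a pale background
(level 0.82), class-dependent darkest-wins blob composition — class 0 has
3–6 large faint blobs (radius 5–9 px, level ≈0.62), class 1 has 25–40
small dark "nuclei" (radius 2–4 px, level ≈0.25) — plus additive Gaussian
pixel noise (sd 0.05) and clipping. Per-image RNGs derive from
(seed, label, index), so datasets are stable prefixes of larger ones.
The classes are separable by construction (class 1 is darker and more
textured), which is what makes the end-to-end smoke test sharp: a CNN that
fails to exceed 0.80 test accuracy here is broken, not unlucky.

What passing these tests does **not** show: performance on real stained
tissue. There is no staining variability, no tissue architecture, no label
noise, and the class signal (mean intensity) is far stronger than in real
IDC patches. Synthetic results validate the machinery, not the clinical
claim.

## Problem sizes and the desk-scale preset

The preset runs 300 patches per class (336/120/144 after the split), 10
VAE epochs and 5 CNN epochs — the full three-arm experiment takes about
two minutes on one CPU, and is the configuration both the end-to-end test
and the acceptance script use. At this scale the baseline arm is perfect,
while the VAE arms collapse to a near-constant predictor: the
reconstructions do retain class signal (the per-image mean intensity of
reconstructed test patches separates the classes with AUC ≈ 0.89), but
they are low-contrast, and five CNN epochs on 336 images are ~30 Adam
steps — too few to exploit a weak-contrast signal. This is a scale
limitation of the preset, not a wiring defect: the pipeline-consistency
test substitutes an identity-behaving reconstruction stage and recovers
the baseline metrics exactly, and the degenerate column the collapsed arms
produce (κ ≈ 0, AUC ≈ ½, weighted precision ≈ prevalence²) matches the
closed-form constant-predictor analytics that the metrics module
reproduces exactly on a 10,000-sample fixture. Full-scale runs (50,000
patches, tens of epochs) are supported by the same code paths but not
exercised in tests.

## Numerical choices and degenerate inputs

* Grayscale uses ITU-R BT.601 luma (0.299/0.587/0.114), rounded to
  integer; equal-channel inputs pass through exactly.
* Resizing is bilinear with half-pixel-centre sampling and edge clamping,
  implemented directly so the interpolation convention is fixed; a
  per-pixel brute-force oracle checks it. 1-pixel dimensions are rejected.
* Probabilities are clipped to [10⁻⁷, 1−10⁻⁷] inside the cross-entropy
  losses; the decoder's sigmoid keeps reconstructions strictly inside
  (0,1).
* Per-class metrics with a zero denominator (e.g. precision of a class
  never predicted) are taken as 0, logged; Cohen's κ returns 0 with a
  warning when chance agreement Pe = 1. Prediction ties break to the lower
  class index.
* ROC AUC uses midranks, so tied scores contribute half — identical scores
  give exactly 0.5.
* Weighted averaging (class support / total) is the default metric
  convention; macro averaging is available. The weighted convention is the
  one under which a constant predictor on a 5,002/4,998 truth yields
  precision 0.2502 and recall 0.5002 exactly.

## Known limitations

* The numpy engine is single-threaded and desk-scale; GPU-scale training
  of 50,000-patch datasets, while supported functionally, is slow.
* Only binary classification; no multi-class generalisation.
* The DVAE noise model is additive Gaussian with clipping; no
  structured/occlusion noise.
* No stain normalisation or whole-slide handling — the package consumes
  pre-extracted patches.
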