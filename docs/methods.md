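# Methods

## Problem and model

`fusegan` addresses two-class diagnosis (an early- vs late-impairment
contrast, labels 0/1) from two co-registered 3-D imaging modalities when
the second modality ("PET") is missing for part of the cohort.  The
method is a three-stage hybrid of synthesis and classification:

1. **Pretraining.** A dual-branch residual CNN consumes (MRI, PET) whole
   volumes, one branch per modality, concatenates branch feature maps
   along channels and fuses them in a residual trunk; a final affine head
   maps the flattened fused features to two class scores.  Everything
   except the head is the *fusion feature extractor* F.  Training
   minimises softmax cross-entropy plus an L2 penalty on all parameters.
2. **Feature-fusion GAN.** A 3-D U-Net generator G maps MRI patches to
   PET patches; a stride-2 convolutional discriminator D scores patches
   as real/synthetic.  The generator objective is

        L(G) = L_GAN(G, D) + λ1 · E‖y − G(x)‖₁ + λ2 · E‖F(x, y) − F(x, G(x))‖₁

   with λ1 = λ2 = 100 and F *frozen*.  The third term is the package's
   core mechanism: it penalises the generator in the classifier's fused
   feature space, steering synthesis toward the regions that matter for
   diagnosis rather than toward average photometric fidelity alone.
   Training alternates 5 discriminator steps with 1 generator step, each
   iteration consuming every patch of one subject pair (54 at full
   scale: 27 MRI + 27 PET).
3. **Fine-tuning.** Training-set PET volumes are treated as missing,
   re-synthesised by the frozen generator, and the classifier is resumed
   at a lower learning rate on real-MRI + synthetic-PET pairs so it
   adapts to synthesis artifacts.  Stages 2 and 3 can be cycled; the
   model with the best validation accuracy (ties broken by AUC) is kept.

Norms in the L1 and fusion terms are per-element means, not sums, so the
weights 100/100 keep their meaning across patch and feature sizes.

## Networks

* Generator: encoder of stride-2 3³ convolutions with leaky-rectifier
  (slope 0.2) activations, decoder of stride-2 transposed convolutions
  with rectifier activations and channel-concatenation skips, sigmoid
  output so synthesized intensities live in the normalized [0, 1] range.
  Full-scale channels 64–128–256–512–1024–1024 / 1024–512–256–128–64–1;
  every spec carries a `width_scale` and an explicit channel list so
  faithful miniatures exist.
* Discriminator: stride-2 3³ convolutions (32–64–…–1024 at full scale),
  leaky rectifier, flatten + single-unit affine head squashed to (0, 1).
  The training loop evaluates the identical objective from the head's
  logit through softplus, which keeps the generator's adversarial
  gradient bounded when the discriminator saturates; the probability
  form is the module's reference definition and what the tests check.
* Fusion classifier: residual blocks of 4 convolutions (first stride 2)
  with 2 shortcuts — a strided 1³ projection across the downsampling
  pair, an identity across the stride-1 pair — each convolution followed
  by batch normalisation then a rectifier, and 50% dropout after each
  block.  Two branch blocks per modality and one trunk block at desk
  scale (three and two at full scale).

The generator's adversarial term defaults to the non-saturating form
−E log D(G(x)); the literal minimax form is available behind a flag.
Both share the GAN fixed point.

## Synthetic cohorts

Real cohorts of this kind are access-restricted, so the package ships a
generator that reproduces the *statistical structure* the method needs:

* background anatomy: a radial gradient blended with Gaussian-smoothed
  white noise (smoothness 2 voxels), per subject;
* cross-modal relation: PET_clean = gain · g(MRI) + offset with
  g the smoothstep t²(3−2t) — smooth, monotone, learnable by a small
  U-Net, and switchable to the identity for oracle tests;
* class signal: label-1 subjects receive an additive intensity shift of
  0.4 inside two spherical lesion regions on PET and 25% of that on MRI
  (so MRI alone carries some class information, as a usable MRI-only
  classifier requires);
* noise: additive Gaussian, σ = 0.05; the noiseless PET is retained
  in memory as a ground-truth oracle;
* a configurable MRI-only subset (default balanced per class; an
  imbalanced 27:76 option mirrors realistic missingness patterns).

What the generator does *not* emulate: scanner physics, partial-volume
effects, registration error, anatomical variability beyond smooth random
texture, or any spatial correlation between lesions and anatomy.
Passing tests therefore demonstrate that the pipeline's machinery —
losses, freezing, scheduling, synthesis, evaluation — behaves as
specified on data with the assumed structure; they say nothing about
clinical performance.

## Study conditions at desk scale

All tests and the acceptance script run the shipped desk profile:
16³ volumes, 8 paired + 4 MRI-only subjects per class, 4 stratified
folds (one fold is the validation split; MRI-only subjects are the test
split), whole-volume patches (patch 16, stride 8), generator channels
[4, 8]/[8, 1], discriminator [2, 4, 8], fusion base width 4.  Stochastic
properties aggregate five seeds.

Optimisation constants differ from the full-scale settings because Adam
step counts shrink by orders of magnitude at this size: stage 1 runs
30 epochs at lr 5e-3, stage 2 runs 40 epochs at lr 5e-3 for G and
2.5e-4 for D, stage 3 runs 20 epochs at lr 1e-3.  Two desk-specific
choices deserve note:

* **Discriminator learning rate.**  With one patch per subject and the
  5:1 alternating schedule, a shared learning rate lets D's weights —
  and therefore the magnitude of its input gradients — grow without
  bound, and the adversarial term swamps the L1 term on some seeds.
  Training D twenty times slower restores the intended balance; the
  full-scale profile keeps the shared setting.
* **Flip augmentation** is implemented (paired, per-axis, probability
  0.5 by default) but not enabled in the desk profile: with
  deterministic planted lesion locations and very small training sets it
  only injects label-irrelevant variance.

## Evaluation conventions

* Positive class for sensitivity is class 1 (the late-impairment-like
  class); this is fixed and documented because it is otherwise ambiguous.
* AUC uses the rank (Mann–Whitney) formulation with ties counted ½ —
  exact at small n and invariant under monotone transforms.
* MSE is the voxelwise mean square; PSNR = 10·log₁₀(1/MSE) with peak 1
  (volumes are min-max normalized), reported as +∞ when MSE = 0.  SSIM
  uses K1 = 0.01, K2 = 0.03, a 7-voxel uniform window, data range 1.
  Published MSE/PSNR pairs for methods of this family are not always
  mutually consistent under any single peak convention, so the package
  fixes its own convention rather than matching any specific table.
* Grad-CAM: channel weights are spatial means of the target-class score
  gradient at the last branch block; the rectified weighted activation
  sum is trilinearly upsampled and max-normalized.  All-zero gradients
  yield a flagged zero map.  At desk scale the target layer is only 4³,
  so saliency maps are coarse; lesion localization is demonstrated with
  an analytic stub model, not asserted statistically for trained
  miniatures.

## Numerical and design choices

* Probabilities are clamped at 1e-7 before logarithms; no loss returns
  NaN/Inf on clamped input.
* Min-max normalization of a constant volume is an error, never a
  silent zero volume; patch geometries that do not tile the volume are
  errors, never silent truncation.
* Patch reassembly averages all covering patches per voxel (uniform
  weights), making extract→reassemble exactly the identity.
* Stage-3 fine-tunes on reassembled whole volumes, matching the input
  scale stages 1 and 3 share.
* Across cycles, stage 2 resumes the generator and stage 3 fine-tunes
  the current classifier (a re-initialisation flag exists); validation
  inputs are always real MRI + real PET, test inputs real MRI +
  synthesized PET.
* L2 regularisation applies to all classifier parameters.
* All computation is float64 on NumPy; identical seeds give bit-identical
  artifacts, which the determinism contracts test byte-for-byte.

## Known limitations

* The NumPy engine is single-threaded-ish and desk-sized; the full-scale
  (128³) profile is a faithful description, not a practical CPU run.
* Accuracy on 8-subject test splits is quantised in 12.5% steps; ordering
  claims are therefore made on medians over five seeds.
* GAN training at batch-of-one-patch scale remains noisy; individual
  seeds can deviate from the median ordering.
* The synthetic lesion contrast is spatially fixed; real anatomical and
  acquisition variability is far richer.
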