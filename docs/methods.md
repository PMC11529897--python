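# Methods

## Problem and pipeline

Bark-beetle outbreaks kill conifers over a progression of crown phases
(green → yellow → red → gray). The package stages individual tree crowns into
three classes — 0 healthy, 1 affected/declining, 2 dead — from 5-band
multispectral drone orthomosaics (blue 475 nm, green 560 nm, red 668 nm,
red-edge 717 nm, NIR 842 nm), in five steps:

1. **dataset** — cut a 64×64×5 reflectance window around each surveyed
   crown, label it from field symptom scores, balance classes by seeded
   downsampling to the minority count, and split 8:2 stratified by class.
2. **preprocess** — reduce each crop to a 64×64×3 stack of normalized
   difference indices (NDIs).
3. **models** — a DCGAN-style generator with channel attention and a
   five-convolution discriminator with two heads: real/fake (sigmoid) and
   class (log-softmax). The trained discriminator *is* the classifier.
4. **training** — staged unconditional→conditional adversarial training.
5. **evaluation** — confusion matrix, accuracy, macro precision/recall,
   Cohen's kappa, macro F1/F2.

A synthetic crown simulator (**synthdata**) makes the whole pipeline testable
without any field data, and supplies an independent closed-form oracle.

## Labeling rule

Field surveys grade crown color (0–5), defoliation (0–4), reduced crown size
(0–1), resin flow (0–2) and bark damage (0–2). The total is

    total = 1.5·(crown_color + defoliation) + crown_size + resin_flow + bark_damage

with the crown symptoms up-weighted because a nadir image sees the crown.
`total ≤ 2` is healthy, otherwise declining; crowns flagged visually dead
(reddish/brown/gray in RGB) are dead regardless of the total. The dead flag
is taken from the input table as a human annotation — no image-based dead
detection is attempted. Crowns whose window would cross the raster edge are
skipped, not padded: padded reflectance would be fabricated data.

## NDI representation

For reflectances ρ₁, ρ₂, `NDI(ρ₁, ρ₂) = (ρ₁ − ρ₂)/(ρ₁ + ρ₂)`. Three index
images form the classifier input, in fixed channel order:

| channel | index | sensitivity |
|---|---|---|
| 0 | NDI(red-edge, red) | chlorophyll loss at the red edge |
| 1 | NDI(red, NIR) | canopy structure/vigor (−NDVI) |
| 2 | NDI(red, green) | discoloration toward red/brown |

Numerical choices: 0/0 pixels map to 0 (neutral) rather than NaN, which
would poison training; outputs are clipped to [−1, 1]. No further
normalization is applied — NDIs already live in the tanh codomain of the
generator, so real and generated images share a domain.

## Architecture

Defaults: latent size nz = 100, base widths ngf = ndf = 128, nc = 3
channels, 3 classes.

**Generator** (1×1 → 64×64): a transposed-convolution stem
(nz+3 → ngf·8, k4 s1 p0) then three upsampling blocks (k4 s2 p1) with the
monotone channel progression ngf·8 → ngf·4 → ngf·2 → ngf, a tanh output
block (ngf → 3, k4 s2 p1), batch-norm + ReLU in every block, and
squeeze-excite channel attention (pool → C/r bottleneck → ReLU → expand →
sigmoid gate) after the 8×8 and 16×16 blocks, reduction r = 16 (the
conventional squeeze-excite default). The one-hot class vector is scaled by
the transition weight λ_t and concatenated to the noise; labels reach the
generator through no other path.

**Discriminator/classifier** (64×64 → heads): five convolutions, kernel 4,
strides 2,2,2,2,1, widths 3 → ndf → ndf·2 → ndf·4 → ndf·8 → ndf·2,
batch-norm on the middle three blocks, leaky-ReLU slope 0.2 throughout, and
dropout 0.5 after the second convolution. The flattened ndf·2 vector feeds
two linear heads: `disc_linear` (sigmoid realness) and `aux_linear`
(log-softmax class posterior). The discriminator never receives labels as
input; class information acts only through the auxiliary loss. Class
prediction is the posterior argmax, ties broken toward the smaller label.

Initialization is the DCGAN convention: conv weights N(0, 0.02²), batch-norm
scale N(1, 0.02²), biases 0.

## Staged transition training

Small datasets make a conditional GAN collapse to one output per class.
Training therefore runs in three stages controlled by

    λ_t = min(max((t − T_s)/(T_e − T_s), 0), 1)

unconditional before epoch T_s, linear transition until T_e, fully
conditional after. The losses are

    L_D = BCE(D(x_real), 1) + BCE(D(G(z)), 0) + λ_t · NLL(aux(x_real), y)
    L_G = BCE(D(G(z)), 1) + λ_t · NLL(aux(G(z)), y_requested)

Per batch the discriminator is updated on the real batch and on a generated
batch (generated images do not backpropagate into the generator during the
discriminator step), then a fresh batch is generated and the generator
updated — the non-saturating objective.

Three deliberate interpretations, each where the procedure was underspecified:

* **Class loss on real images only** in L_D. Teaching the auxiliary head on
  early low-quality fakes would corrupt the classifier it is supposed to
  become; generated images enter L_D only through the adversarial term.
* **Supervised warm-up**: during the first `pretrain_epochs` the auxiliary
  head is fitted on real labels with weight 1 regardless of λ_t. This gives
  the classifier head a head start while the GAN is still unconditional.
* **Decay factor 0.5** at each scheduled learning-rate milestone
  (60, 120, 240, 620, 800, 1200). A factor of 0.1 over six milestones would
  collapse the learning rate by 10⁻⁶.

Published defaults: lr_D = 0.001, lr_G = 0.01, weight decay 0.0005,
pretrain = 50, T_s = 500, T_e = 600, T_m = 1250. Adam moments are (0.5,
0.999), the usual GAN-stability setting; batch size 32; noise is standard
normal. One master seed drives initialization, batch order, noise, dropout
and augmentation, so runs are bit-reproducible.

**Model selection.** The epoch with the best held-out accuracy is
checkpointed alongside the final epoch. The best checkpoint is the
*classifier* a practitioner would deploy — it often falls in the warm-up
phase where the classifier peaks but the generator is still unconditional.
Generation diagnostics therefore always use the final-epoch generator, the
only one trained to λ = 1.

**Baselines.** `train_baseline` trains the same discriminator network with
the NLL term alone (no adversarial terms) — without augmentation ("WA") or
with label-preserving flips and 90° rotations on the fly ("A").

## The numpy engine

No tensor/autodiff library is part of the dependency footprint; `nn.py`
implements the required layers with explicit backward passes in float32.
Activations use a (C, N, H, W) layout internally so that im2col/col2im are
pure slice arithmetic and each convolution — forward, input gradient and
weight gradient — is a single large BLAS matmul; this is what makes CPU
training tractable (~60 GFLOP/s effective on one core). Sigmoid outputs are
clipped to [1e−7, 1−1e−7] so realness is strictly inside (0, 1) and the
binary cross-entropy (computed in float64) stays finite. Correctness is
pinned by adjointness and scipy cross-checks plus numerical-gradient tests.

## Synthetic crowns and the independent oracle

Each synthetic image is a centered disk crown (radius ~ U(18, 28) px) over a
dim soil/shadow background (0.05), with per-class mean reflectances

| class | blue | green | red | red-edge | NIR |
|---|---|---|---|---|---|
| healthy | 0.04 | 0.10 | 0.05 | 0.30 | 0.55 |
| declining | 0.05 | 0.10 | 0.12 | 0.28 | 0.40 |
| dead | 0.10 | 0.12 | 0.22 | 0.24 | 0.25 |

±10% per-tree brightness jitter and σ = 0.02 per-pixel Gaussian noise,
clipped to [0, 1]. The values echo known vegetation spectral behavior
(healthy: strong NIR, low red; dead: flat brown/gray); they are design
parameters, not measurements. Brightness jitter cancels exactly in the NDIs
— deliberate, since real illumination varies.

The **NDI-threshold oracle** classifies an image by the mean of channel 1
over a central disk, against the two midpoints between the closed-form class
values (−0.833, −0.538, −0.064 for the defaults). It never sees the learned
models, so it can referee both the classifier and the conditional generator.

What the simulator does *not* emulate: crown texture and self-shadowing,
mixed boundary pixels, neighboring-crown overlap, registration error,
within-class spectral diversity beyond brightness, and any green-attack
subtlety — on real data the declining class is much harder than here.
Passing tests on synthetic data therefore demonstrate that the machinery
(labeling, indices, architecture, staged training, metrics) is correct and
that conditioning is learned without mode collapse; they do not certify
field accuracy.

## Desk-scale experiment sizes

The published configuration (1250 epochs, width 128, 342 crops) is an
hours-long GPU-scale run. The package's own experiment defaults keep the
study's structure at desk scale: 100 crowns/class, width ngf = ndf = 32,
batch 32, with the stage proportions preserved (transition from 30% to 45%
of training, warm-up for the first quarter — matching 500/600/1250 and
50/1250 proportionally). Classifier-accuracy replicates run 30 epochs; the
run whose generator is used for generation diagnostics runs 60 epochs, so
that a substantial fraction of training happens at λ = 1. A run takes a few
minutes on one CPU core. The scarce-data baseline comparison uses 30
crowns/class and 40 epochs. `scripts/acceptance.py` reruns all of it from
scratch.

**Generation diagnostics.** Class-conditional sample quality is judged by
the independent oracle (fraction of samples assigned to the requested
class) and sample diversity by the across-sample standard deviation of
channel 1 at each central-disk pixel, averaged over the disk, per class.
Diversity is deliberately *not* measured on the disk-averaged statistic: a
~500-pixel mean has near-zero within-class spread even for ideal data, so
it cannot distinguish a healthy generator from a collapsed one, whereas
per-pixel across-sample spread goes to zero exactly when the generator
emits near-identical images.

## Known limitations

* Pixel coordinates or simple north-up geotransforms only; rotated/sheared
  rasters are out of scope.
* The engine is single-device, float32, CPU-oriented; width-128 runs at
  1250 epochs are possible but slow (hours).
* Kappa is reported in [0, 1] internally and ×100 for presentation.
* Metrics macro-average over classes; for the balanced test sets produced
  by the pipeline, macro and weighted averages coincide.
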