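# beetlegan

Staging bark-beetle damage of individual tree crowns — healthy, declining,
dead — from 5-band multispectral drone imagery, using an
auxiliary-classifier GAN whose discriminator doubles as the classifier.

Bark-beetle outbreaks kill conifers at landscape scale, and the early
("green") infestation stage shows no visible crown discoloration, so
field-scale deep learning runs into a hard constraint: labeled crown images
are scarce. This package targets exactly that regime. Instead of training a
CNN classifier directly on a few hundred crowns, it trains a generative
adversarial network in which the discriminator carries an auxiliary class
head; the generator's synthetic crowns act as augmentation, and the
discriminator that emerges is the deployed classifier. It is intended for
remote-sensing and forest-health researchers working with drone
multispectral orthomosaics (here: blue 475, green 560, red 668, red-edge
717, NIR 842 nm) and per-tree field symptom surveys.

## Method

Each surveyed crown becomes a 64×64×5 reflectance crop, labeled from field
scores (crown color and defoliation weighted 1.5; total ≤ 2 ⇒ healthy;
visually dead crowns ⇒ dead), balanced to equal class counts and split 8:2.
Crops are reduced to three normalized difference indices,
NDI(ρ₁,ρ₂) = (ρ₁−ρ₂)/(ρ₁+ρ₂): NDI(red-edge, red), NDI(red, NIR),
NDI(red, green) — a 64×64×3 stack in [−1, 1].

Conditional GANs mode-collapse on small datasets, so training is staged by a
transition weight

    λ_t = min(max((t − T_s)/(T_e − T_s), 0), 1)

that phases class-conditioning in linearly between epochs T_s and T_e:

    L_D = BCE(D(x), 1) + BCE(D(G(z)), 0) + λ_t · NLL(aux(x), y)
    L_G = BCE(D(G(z)), 1) + λ_t · NLL(aux(G(z)), y)

The generator is a DCGAN-style transposed-convolution stack with
squeeze-excite channel attention; the discriminator has five convolutions
and two linear heads (realness sigmoid, class log-softmax). Evaluation
reports the confusion matrix, accuracy, macro precision/recall, Cohen's
kappa, and macro F1/F2. A seeded synthetic crown simulator with
class-dependent spectra makes everything runnable and testable without any
download; see `docs/methods.md` for details and design choices.

Everything runs on plain numpy (float32, im2col + BLAS convolutions with
hand-written backward passes) — no GPU or tensor library required.

## Worked example

Simulate a small labeled dataset, train at reduced scale, evaluate, and
sample the conditional generator:

```sh
beetlegan --seed 1 --out sim simulate --n-per-class 100
beetlegan --seed 1 --out run --config configs/desk.yaml train --data sim
beetlegan --out run evaluate --checkpoint run/best.npz --data sim --report run/metrics.json
beetlegan --seed 1 --out samples generate --checkpoint run/final.npz --label 2 --n 8
```

with `configs/desk.yaml` holding the desk-scale setup (width 32, 30 epochs,
transition epochs 9→14, supervised warm-up 8):

```yaml
gan: {ngf: 32, ndf: 32}
optim: {pretrain_epochs: 8, seed: 1}
schedule: {T_s: 9, T_e: 14, T_m: 30}
```

The evaluate step prints one JSON line with the held-out metrics (×100):

```
{"accuracy": 100.0, "precision_macro": 100.0, "recall_macro": 100.0, "kappa": 100.0, "f1_macro": 100.0, "f2_macro": 100.0}
```

a perfect 60-crop confusion matrix on the synthetic test split. The
simulated classes are far better separated than field data, so treat this
as a check of the machinery, not a field-accuracy estimate; real surveys
use the full-scale configuration (width 128, 1250 epochs) and land well
below 100%. `samples/` receives eight 64×64×3 NDI images of dead crowns in
[−1, 1] as TIFFs.

To run on real data instead, `beetlegan prepare --raster ortho.tif --trees
trees.csv` expects a 5-band GeoTIFF plus a CSV with columns `tree_id`,
`x`, `y` (0-based pixel; or `lon`/`lat` with a north-up geotransform),
`crown_color`, `defoliation`, `crown_size`, `resin_flow`, `bark_damage`,
`dead_flag`.

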