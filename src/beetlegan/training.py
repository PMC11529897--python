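"""Three-stage transition training for the auxiliary-classifier GAN.

With few training images a conditional GAN collapses: the generator emits one
image per class. Training therefore starts unconditionally (the generator
ignores labels, the discriminator only separates real from fake), then a
transition weight

    lambda_t = clip((t - T_s) / (T_e - T_s), 0, 1)

linearly phases the class-conditional loss terms in between epochs T_s and
T_e, after which training is fully conditional:

    L_G = L_G_uncond + lambda_t * L_G_cond
    L_D = L_D_uncond + lambda_t * L_D_cond

The unconditional parts are binary cross-entropy on the real/fake head; the
conditional parts are negative log-likelihood on the auxiliary class head.
The same lambda_t scales the one-hot label vector fed to the generator, so
labels reach the generator only once conditioning is switched on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .models import (Discriminator, DiscriminatorOutput, GANConfig, Generator,
                     make_generator_input, predict_class)
from .nn import F32
from .preprocess import NDIImage, to_ndi_stack, to_training_array

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransitionSchedule:
    """Epochs bracketing the unconditional->conditional transition."""

    T_s: int = 500    # transition start
    T_e: int = 600    # transition end
    T_m: int = 1250   # total training epochs

    def __post_init__(self):
        if not 0 <= self.T_s < self.T_e <= self.T_m:
            raise ValueError(
                f"need 0 <= T_s < T_e <= T_m, got {self.T_s}, {self.T_e}, "
                f"{self.T_m}")


@dataclass(frozen=True)
class OptimConfig:
    """Optimization hyperparameters (published defaults)."""

    lr_D: float = 0.001
    lr_G: float = 0.01
    weight_decay: float = 0.0005
    decay_epochs: tuple = (60, 120, 240, 620, 800, 1200)
    decay_factor: float = 0.5
    pretrain_epochs: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.lr_D <= 0 or self.lr_G <= 0:
            raise ValueError("learning rates must be positive")
        if list(self.decay_epochs) != sorted(set(self.decay_epochs)):
            raise ValueError("decay_epochs must be strictly increasing")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


def transition_lambda(t: int, schedule: TransitionSchedule) -> float:
    """Piecewise-linear transition weight, clamped to [0, 1]."""
    if t < 0:
        raise ValueError(f"epoch must be >= 0, got {t}")
    if schedule.T_e == schedule.T_s:
        raise ValueError("degenerate schedule: T_e == T_s")
    lam = (t - schedule.T_s) / (schedule.T_e - schedule.T_s)
    return float(min(max(lam, 0.0), 1.0))


def apply_lr_decay(epoch: int, optim: OptimConfig,
                   current_lrs: dict[str, float]) -> dict[str, float]:
    """Multiply both learning rates by decay_factor at each milestone epoch."""
    if epoch in optim.decay_epochs:
        return {k: v * optim.decay_factor for k, v in current_lrs.items()}
    return dict(current_lrs)


# ---------------------------------------------------------------------------
# losses (scalar forms; the training loop reuses the same primitives with
# their gradients)
# ---------------------------------------------------------------------------

def discriminator_loss(real_out: DiscriminatorOutput,
                       fake_out: DiscriminatorOutput,
                       labels: np.ndarray, lam: float) -> float:
    """L_D = [BCE(real, 1) + BCE(fake, 0)] + lam * NLL(real class head)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    l_real, _ = nn.bce_loss(real_out.realness, 1.0)
    l_fake, _ = nn.bce_loss(fake_out.realness, 0.0)
    l_cls, _ = nn.nll_loss(real_out.class_logprobs, np.asarray(labels))
    loss = l_real + l_fake + lam * l_cls
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite discriminator loss {loss}")
    return float(loss)


def generator_loss(fake_out: DiscriminatorOutput, labels: np.ndarray,
                   lam: float) -> float:
    """L_G = BCE(fake, 1) + lam * NLL(fake class head) (non-saturating)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    l_adv, _ = nn.bce_loss(fake_out.realness, 1.0)
    l_cls, _ = nn.nll_loss(fake_out.class_logprobs, np.asarray(labels))
    loss = l_adv + lam * l_cls
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite generator loss {loss}")
    return float(loss)


# ---------------------------------------------------------------------------
# history
# ---------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    rows: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.rows.append(kwargs)

    def column(self, name: str) -> list:
        return [r[name] for r in self.rows]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.rows:
                fh.write(json.dumps(r) + "\n")

    def __len__(self) -> int:
        return len(self.rows)


def _check_classes(y: np.ndarray, nb_label: int) -> None:
    present = set(int(v) for v in np.unique(y))
    missing = sorted(set(range(nb_label)) - present)
    if missing:
        raise ValueError(f"training set has no samples of class(es) {missing}")


def _accuracy(disc: Discriminator, x: np.ndarray, y: np.ndarray,
              batch: int = 64) -> float:
    hits = 0
    for i in range(0, len(x), batch):
        hits += int((predict_class(disc, x[i:i + batch]) == y[i:i + batch]).sum())
    return hits / len(x)


@dataclass
class TrainResult:
    generator: Generator
    discriminator: Discriminator
    history: TrainingHistory
    best_epoch: int | None = None
    best_accuracy: float | None = None
    best_state: tuple | None = None      # (gen arrays, disc arrays)

    def restore_best(self) -> None:
        if self.best_state is None:
            raise ValueError("no held-out set was provided; no best state kept")
        g_arrays, d_arrays = self.best_state
        self.generator.load_state_arrays([a.copy() for a in g_arrays])
        self.discriminator.load_state_arrays([a.copy() for a in d_arrays])


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        return data
    return to_training_array(list(data))


# ---------------------------------------------------------------------------
# GAN training
# ---------------------------------------------------------------------------

def train_gan(train_set: list[NDIImage] | tuple[np.ndarray, np.ndarray],
              config: GANConfig,
              optim: OptimConfig,
              schedule: TransitionSchedule,
              test_set=None,
              log_path: str | Path | None = None) -> TrainResult:
    """Run the staged unconditional->conditional training loop.

    Per batch: (1) the discriminator is updated on a real batch (adversarial
    BCE plus the lambda-weighted class NLL on real images) and on a generated
    batch (adversarial BCE; the generated images do not propagate into the
    generator here); (2) a fresh batch is generated and the generator is
    updated with the lambda-weighted generator loss. During the first
    ``pretrain_epochs`` the auxiliary class head is fitted on real labels
    with weight 1 regardless of lambda (supervised warm-up).

    Returns the trained networks plus a per-epoch history; when ``test_set``
    is given, held-out accuracy is tracked and the best-epoch parameters are
    retained alongside the final ones.
    """
    x, y = _as_arrays(train_set)
    if len(x) == 0:
        raise ValueError("training set is empty")
    _check_classes(y, config.nb_label)
    x_test = y_test = None
    if test_set is not None:
        x_test, y_test = _as_arrays(test_set)

    root = np.random.SeedSequence(optim.seed)
    ss_init_g, ss_init_d, ss_loop = root.spawn(3)
    gen = Generator(config, np.random.default_rng(ss_init_g))
    disc = Discriminator(config, np.random.default_rng(ss_init_d))
    rng = np.random.default_rng(ss_loop)
    disc.set_dropout_rng(rng)             # dropout shares the loop stream

    opt_g = nn.Adam(gen.params(), optim.lr_G, optim.weight_decay)
    opt_d = nn.Adam(disc.params(), optim.lr_D, optim.weight_decay)
    lrs = {"lr_D": optim.lr_D, "lr_G": optim.lr_G}
    history = TrainingHistory()
    best: tuple | None = None
    best_acc, best_epoch = -1.0, None

    for epoch in range(schedule.T_m):
        lam = transition_lambda(epoch, schedule)
        aux_w = 1.0 if epoch < optim.pretrain_epochs else lam
        lrs = apply_lr_decay(epoch, optim, lrs)
        opt_d.lr, opt_g.lr = lrs["lr_D"], lrs["lr_G"]

        order = rng.permutation(len(x))
        sums = {"d_uncond": 0.0, "d_cond": 0.0, "g_uncond": 0.0, "g_cond": 0.0}
        n_batches = 0
        for start in range(0, len(x), optim.batch_size):
            idx = order[start:start + optim.batch_size]
            xb, yb = x[idx], y[idx]
            b = len(idx)

            # --- discriminator update -------------------------------------
            disc.zero_grad()
            out_r = disc.forward(xb, training=True)
            l_real, g_real = nn.bce_loss(out_r.realness, 1.0)
            l_cls, g_cls = nn.nll_loss(out_r.class_logprobs, yb)
            d_img = disc.backward_heads(
                g_real, aux_w * g_cls if aux_w > 0 else None)
            del d_img

            noise = rng.standard_normal((b, config.nz)).astype(F32)
            fl = rng.integers(0, config.nb_label, b)
            fake = gen.forward(
                make_generator_input(noise, fl, config.nb_label, lam),
                training=True)
            out_f = disc.forward(fake, training=True)
            l_fake, g_fake = nn.bce_loss(out_f.realness, 0.0)
            disc.backward_heads(g_fake, None)
            opt_d.step()

            # --- generator update -----------------------------------------
            gen.zero_grad()
            disc.zero_grad()
            noise = rng.standard_normal((b, config.nz)).astype(F32)
            fl = rng.integers(0, config.nb_label, b)
            fake = gen.forward(
                make_generator_input(noise, fl, config.nb_label, lam),
                training=True)
            out_g = disc.forward(fake, training=True)
            l_adv, g_adv = nn.bce_loss(out_g.realness, 1.0)
            l_gcls, g_gcls = nn.nll_loss(out_g.class_logprobs, fl)
            d_img = disc.backward_heads(
                g_adv, lam * g_gcls if lam > 0 else None)
            gen.backward(d_img)
            opt_g.step()

            batch_losses = (l_real + l_fake, aux_w * l_cls, l_adv,
                            lam * l_gcls)
            if not all(np.isfinite(v) for v in batch_losses):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: D_uncond="
                    f"{l_real + l_fake:.4g} D_cond={aux_w * l_cls:.4g} "
                    f"G_uncond={l_adv:.4g} G_cond={lam * l_gcls:.4g}")
            for k, v in zip(sums, batch_losses):
                sums[k] += v
            n_batches += 1

        acc = None
        if x_test is not None:
            acc = _accuracy(disc, x_test, y_test)
            if acc > best_acc:
                best_acc, best_epoch = acc, epoch
                best = ([a.copy() for a in gen.state_arrays()],
                        [a.copy() for a in disc.state_arrays()])
        history.append(
            epoch=epoch, lam=lam, aux_weight=aux_w,
            lr_D=lrs["lr_D"], lr_G=lrs["lr_G"],
            loss_D_uncond=sums["d_uncond"] / n_batches,
            loss_D_cond=sums["d_cond"] / n_batches,
            loss_G_uncond=sums["g_uncond"] / n_batches,
            loss_G_cond=sums["g_cond"] / n_batches,
            test_accuracy=acc)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(history.rows[-1]) + "\n")

    return TrainResult(gen, disc, history, best_epoch,
                       None if best is None else best_acc, best)


# ---------------------------------------------------------------------------
# desk-scale synthetic experiment (shared by the test suite and the
# acceptance script)
# ---------------------------------------------------------------------------

def run_synthetic_experiment(seed: int, n_per_class: int = 100,
                             base_width: int = 32, epochs: int = 30,
                             t_s: int | None = None, t_e: int | None = None,
                             pretrain: int | None = None) -> dict:
    """End-to-end staged-GAN run on the bundled synthetic crowns.

    Generates 3*n_per_class crowns, converts them to NDI stacks, splits 8:2
    stratified, trains the reduced-width GAN and returns the trained result
    plus held-out accuracy (at the best-accuracy epoch, which is the
    checkpoint a practitioner would deploy, and at the final epoch).

    The default 30-epoch schedule keeps the published stage proportions
    (transition beginning at 30% and ending at ~45% of training, supervised
    warm-up for the first quarter); problem sizes are chosen so a run
    completes in minutes on one CPU core.
    """
    from .dataset import split_dataset
    from .synthdata import make_dataset

    if t_s is None:
        t_s = max(1, round(0.30 * epochs))
    if t_e is None:
        t_e = max(t_s + 1, round(0.45 * epochs))
    if pretrain is None:
        pretrain = round(0.25 * epochs)
    crops = make_dataset(n_per_class, seed=seed)
    train_c, test_c = split_dataset(crops, 0.2, seed=seed)
    train = to_training_array([to_ndi_stack(c) for c in train_c])
    test = to_training_array([to_ndi_stack(c) for c in test_c])
    config = GANConfig(ngf=base_width, ndf=base_width)
    optim = OptimConfig(seed=seed, pretrain_epochs=pretrain)
    schedule = TransitionSchedule(t_s, t_e, epochs)
    result = train_gan(train, config, optim, schedule, test_set=test)
    return {
        "result": result,
        "config": config,
        "schedule": schedule,
        "train": train,
        "test": test,
        "best_accuracy": result.best_accuracy,
        "final_accuracy": result.history.rows[-1]["test_accuracy"],
    }


# ---------------------------------------------------------------------------
# baseline classifier (no adversarial training)
# ---------------------------------------------------------------------------

def _augment_batch(xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Label-preserving geometric augmentation: flips and 90-degree turns."""
    out = xb.copy()
    for i in range(len(out)):
        k = int(rng.integers(0, 4))
        if k:
            out[i] = np.rot90(out[i], k, axes=(1, 2))
        if rng.random() < 0.5:
            out[i] = out[i][:, :, ::-1]
        if rng.random() < 0.5:
            out[i] = out[i][:, ::-1, :]
    return np.ascontiguousarray(out)


def train_baseline(train_set, config: GANConfig, optim: OptimConfig,
                   augment: bool, epochs: int = 100,
                   test_set=None) -> tuple[Discriminator, TrainingHistory]:
    """Train the discriminator's class head alone (plain NLL classifier).

    The same network as the GAN discriminator, but without adversarial terms
    — the comparison baseline "WA" (augment=False) / "A" (augment=True, on
    the fly flips and 90-degree rotations).
    """
    x, y = _as_arrays(train_set)
    if len(x) == 0:
        raise ValueError("training set is empty")
    _check_classes(y, config.nb_label)
    x_test = y_test = None
    if test_set is not None:
        x_test, y_test = _as_arrays(test_set)

    root = np.random.SeedSequence(optim.seed)
    ss_init, ss_loop = root.spawn(2)
    disc = Discriminator(config, np.random.default_rng(ss_init))
    rng = np.random.default_rng(ss_loop)
    disc.set_dropout_rng(rng)
    opt = nn.Adam(disc.params(), optim.lr_D, optim.weight_decay)
    lrs = {"lr_D": optim.lr_D, "lr_G": optim.lr_G}
    history = TrainingHistory()

    for epoch in range(epochs):
        lrs = apply_lr_decay(epoch, optim, lrs)
        opt.lr = lrs["lr_D"]
        order = rng.permutation(len(x))
        total, n_batches = 0.0, 0
        for start in range(0, len(x), optim.batch_size):
            idx = order[start:start + optim.batch_size]
            xb, yb = x[idx], y[idx]
            if augment:
                xb = _augment_batch(xb, rng)
            disc.zero_grad()
            out = disc.forward(xb, training=True)
            loss, grad = nn.nll_loss(out.class_logprobs, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite classifier loss at epoch {epoch}")
            disc.backward_heads(None, grad)
            opt.step()
            total += loss
            n_batches += 1
        acc = None if x_test is None else _accuracy(disc, x_test, y_test)
        history.append(epoch=epoch, lam=0.0, aux_weight=1.0,
                       lr_D=lrs["lr_D"], lr_G=lrs["lr_G"],
                       loss_D_uncond=0.0, loss_D_cond=total / n_batches,
                       loss_G_uncond=0.0, loss_G_cond=0.0,
                       test_accuracy=acc)
    return disc, history
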