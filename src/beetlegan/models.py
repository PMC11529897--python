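"""Generator and discriminator/classifier for 64x64 3-channel NDI images.

The generator is a DCGAN-style stack of transposed convolutions with
squeeze-excite channel attention after the 8x8 and 16x16 blocks; the
discriminator carries two heads, a real/fake sigmoid (``disc_linear``) and an
auxiliary 3-class log-softmax (``aux_linear``), so that after adversarial
training the discriminator itself is the damage-stage classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import F32

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class GANConfig:
    """Architecture hyperparameters.

    Defaults follow the published configuration: nz=100 latent dims,
    base widths ngf=ndf=128, nc=3 image channels, nb_label=3 classes.
    """

    nz: int = 100
    ngf: int = 128
    ndf: int = 128
    nc: int = 3
    nb_label: int = 3
    attention_reduction: int = 16
    leaky_slope: float = 0.2
    dropout_rate: float = 0.5

    def __post_init__(self):
        for name in ("nz", "ngf", "ndf", "nc", "nb_label"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for c in (4 * self.ngf, 2 * self.ngf):
            if c % self.attention_reduction != 0:
                raise ValueError(
                    f"attention_reduction {self.attention_reduction} does not "
                    f"divide attended channel count {c}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class DiscriminatorOutput:
    """realness: P(real) per image, strictly inside (0,1);
    class_logprobs: log-softmax over the 3 damage stages."""

    realness: np.ndarray          # (N,)
    class_logprobs: np.ndarray    # (N, nb_label)


def make_generator_input(noise: np.ndarray, labels: np.ndarray,
                         nb_label: int, lam: float) -> np.ndarray:
    """Concatenate latent noise with a one-hot label vector scaled by the
    transition weight lambda; shape (N, nz + nb_label, 1, 1)."""
    n = noise.shape[0]
    onehot = np.zeros((n, nb_label), dtype=F32)
    onehot[np.arange(n), labels] = F32(lam)
    vec = np.concatenate([noise.astype(F32), onehot], axis=1)
    return vec[:, :, None, None]


class Generator(nn.Module):
    """noise+label vector -> nc x 64 x 64 image in [-1, 1] (tanh head).

    Channel progression ngf*8 -> ngf*4 -> ngf*2 -> ngf -> nc over spatial
    sizes 4 -> 8 -> 16 -> 32 -> 64.
    """

    def __init__(self, config: GANConfig, rng: np.random.Generator):
        self.config = config
        g, r = config.ngf, config.attention_reduction
        self.net = nn.Sequential(
            # 1x1 -> 4x4
            nn.ConvTranspose2d(config.nz + config.nb_label, g * 8, 4, 1, 0, rng),
            nn.BatchNorm2d(g * 8, rng), nn.ReLU(),
            # 4x4 -> 8x8
            nn.ConvTranspose2d(g * 8, g * 4, 4, 2, 1, rng),
            nn.BatchNorm2d(g * 4, rng), nn.ReLU(),
            nn.ChannelAttention(g * 4, r, rng),
            # 8x8 -> 16x16
            nn.ConvTranspose2d(g * 4, g * 2, 4, 2, 1, rng),
            nn.BatchNorm2d(g * 2, rng), nn.ReLU(),
            nn.ChannelAttention(g * 2, r, rng),
            # 16x16 -> 32x32
            nn.ConvTranspose2d(g * 2, g, 4, 2, 1, rng),
            nn.BatchNorm2d(g, rng), nn.ReLU(),
            # 32x32 -> 64x64
            nn.ConvTranspose2d(g, config.nc, 4, 2, 1, rng),
            nn.Tanh(),
        )

    def forward(self, x, training=False):
        expected = self.config.nz + self.config.nb_label
        if x.ndim != 4 or x.shape[1] != expected:
            raise ValueError(
                f"generator input must be (N, {expected}, 1, 1), got {x.shape}")
        return nn.to_nchw(self.net.forward(nn.to_cnhw(x), training))

    def backward(self, dy):
        return nn.to_nchw(self.net.backward(nn.to_cnhw(dy)))

    def sample(self, n: int, label: int, lam: float,
               rng: np.random.Generator) -> np.ndarray:
        """Draw n class-conditional images in evaluation mode."""
        noise = rng.standard_normal((n, self.config.nz)).astype(F32)
        labels = np.full(n, label, dtype=np.int64)
        x = make_generator_input(noise, labels, self.config.nb_label, lam)
        return self.forward(x, training=False)

    def summary(self) -> list[str]:
        return _summarize(self.net, "generator")


class Discriminator(nn.Module):
    """64x64 image -> (realness, class log-probabilities).

    Five convolutions (64->32->16->8->4->1 spatial), widths
    nc -> ndf -> ndf*2 -> ndf*4 -> ndf*8 -> ndf*2, then two linear heads on
    the flattened ndf*2 vector. Dropout follows the second convolution.
    """

    def __init__(self, config: GANConfig, rng: np.random.Generator):
        self.config = config
        d, s = config.ndf, config.leaky_slope
        self.features = nn.Sequential(
            nn.Conv2d(config.nc, d, 4, 2, 1, rng), nn.LeakyReLU(s),
            nn.Conv2d(d, d * 2, 4, 2, 1, rng),
            nn.BatchNorm2d(d * 2, rng), nn.LeakyReLU(s),
            nn.Dropout(config.dropout_rate, rng),
            nn.Conv2d(d * 2, d * 4, 4, 2, 1, rng),
            nn.BatchNorm2d(d * 4, rng), nn.LeakyReLU(s),
            nn.Conv2d(d * 4, d * 8, 4, 2, 1, rng),
            nn.BatchNorm2d(d * 8, rng), nn.LeakyReLU(s),
            nn.Conv2d(d * 8, d * 2, 4, 1, 0, rng), nn.LeakyReLU(s),
        )
        self.disc_linear = nn.Linear(d * 2, 1, rng)
        self.aux_linear = nn.Linear(d * 2, config.nb_label, rng)
        self._cache = None

    def forward(self, x, training=False) -> DiscriminatorOutput:
        if x.ndim != 4 or x.shape[1:] != (self.config.nc, 64, 64):
            raise ValueError(
                f"discriminator input must be (N, {self.config.nc}, 64, 64), "
                f"got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("discriminator input contains non-finite values")
        feat = self.features.forward(nn.to_cnhw(x), training)
        flat = np.ascontiguousarray(feat.reshape(feat.shape[0], -1).T)  # (N, C)
        s_logit = self.disc_linear(flat)[:, 0]
        c_logit = self.aux_linear(flat)
        logp = nn.log_softmax(c_logit)
        realness = nn.sigmoid(s_logit)
        self._cache = (flat.shape, realness, logp)
        return DiscriminatorOutput(realness, logp)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        """Point the dropout layer at a caller-owned random stream."""
        for layer in self.features.layers:
            if isinstance(layer, nn.Dropout):
                layer.rng = rng

    def backward_heads(self, d_realness: np.ndarray | None,
                       d_logprobs: np.ndarray | None) -> np.ndarray:
        """Backprop from head-output gradients down to the input image.

        d_realness is dL/d(realness); d_logprobs is dL/d(log p). Either may
        be None when that head does not contribute to the loss.
        """
        flat_shape, r, logp = self._cache
        dflat = np.zeros(flat_shape, dtype=F32)
        if d_realness is not None:
            # realness = sigmoid(s_logit): chain through the sigmoid
            ds_logit = (d_realness * r * (1.0 - r)).astype(F32)
            dflat += self.disc_linear.backward(ds_logit[:, None])
        if d_logprobs is not None:
            # log-softmax jacobian: dlogit = dlogp - softmax * sum(dlogp)
            p = np.exp(logp)
            dc_logit = d_logprobs - p * d_logprobs.sum(axis=1, keepdims=True)
            dflat += self.aux_linear.backward(dc_logit.astype(F32))
        dfeat = np.ascontiguousarray(dflat.T) \
            .reshape(self.config.ndf * 2, flat_shape[0], 1, 1)
        return nn.to_nchw(self.features.backward(dfeat))

    def summary(self) -> list[str]:
        lines = _summarize(self.features, "discriminator.features")
        lines.append(f"discriminator.disc_linear: ({self.config.ndf * 2} -> 1)")
        lines.append(
            f"discriminator.aux_linear: ({self.config.ndf * 2} -> "
            f"{self.config.nb_label})")
        return lines


def predict_class(disc: Discriminator, images: np.ndarray) -> np.ndarray:
    """Argmax class per image (ties toward the smaller label index)."""
    out = disc.forward(images, training=False)
    return np.argmax(out.class_logprobs, axis=1)


def _summarize(seq: nn.Sequential, prefix: str) -> list[str]:
    lines = []
    for i, layer in enumerate(seq.layers):
        desc = type(layer).__name__
        if isinstance(layer, (nn.Conv2d, nn.ConvTranspose2d)):
            desc += (f"({layer.cin} -> {layer.cout}, k={layer.k}, "
                     f"s={layer.stride}, p={layer.pad})")
        elif isinstance(layer, nn.BatchNorm2d):
            desc += f"({layer.c})"
        elif isinstance(layer, nn.ChannelAttention):
            desc += f"({layer.c}, r={layer.reduction})"
        lines.append(f"{prefix}[{i}]: {desc}")
    return lines


def parameter_count(module: nn.Module) -> int:
    return sum(p.value.size for p in module.params())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, gen: Generator, disc: Discriminator,
                    extra: dict | None = None) -> None:
    """Serialize both networks plus their GANConfig to an .npz file."""
    arrays = {}
    for i, a in enumerate(gen.state_arrays()):
        arrays[f"g{i}"] = a
    for i, a in enumerate(disc.state_arrays()):
        arrays[f"d{i}"] = a
    meta = {"schema": CHECKPOINT_SCHEMA, "config": asdict(gen.config),
            "extra": extra or {}}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path,
                    config: GANConfig | None = None
                    ) -> tuple[Generator, Discriminator, dict]:
    """Rebuild generator+discriminator from a checkpoint.

    Refuses to load when the stored config disagrees with an explicitly
    requested one.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        stored = GANConfig(**meta["config"])
        if config is not None and config != stored:
            raise ValueError("checkpoint config does not match requested config")
        rng = np.random.default_rng(0)  # overwritten by loaded state
        gen = Generator(stored, rng)
        disc = Discriminator(stored, rng)
        gen.load_state_arrays(
            [data[f"g{i}"] for i in range(len(gen.state_arrays()))])
        disc.load_state_arrays(
            [data[f"d{i}"] for i in range(len(disc.state_arrays()))])
    return gen, disc, meta.get("extra", {})
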