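"""Normalized-difference-index representation of crown crops.

The classifier does not see raw reflectances: each 64x64x5 crop is reduced to
three normalized difference indices, NDI(a,b) = (a - b) / (a + b), computed
pixel by pixel between band pairs known to separate damage stages:

    channel 0: NDI(red-edge, red)
    channel 1: NDI(red, NIR)      (the negative of NDVI)
    channel 2: NDI(red, green)

NDIs are dimensionless, invariant to overall brightness, and live in [-1, 1]
— the same codomain as the generator's tanh head, so real and generated
images share a domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ClassLabel, MultispectralCrop

#: (numerator band index, subtrahend band index) per output channel,
#: bands ordered blue, green, red, red-edge, NIR
NDI_CHANNEL_BANDS = ((3, 2), (2, 4), (2, 1))
NDI_CHANNEL_NAMES = ("ndi_rededge_red", "ndi_red_nir", "ndi_red_green")


@dataclass
class NDIImage:
    """64x64x3 stack of the three selected NDIs, values in [-1, 1]."""

    pixels: np.ndarray
    label: ClassLabel

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"NDI stack must be (H, W, 3), got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("NDI stack contains non-finite values")
        if p.min() < -1.0 or p.max() > 1.0:
            raise ValueError("NDI values must lie in [-1, 1]")
        self.pixels = p


def ndi(band_a: np.ndarray, band_b: np.ndarray) -> np.ndarray:
    """Elementwise (a - b) / (a + b); 0/0 pixels map to 0 (neutral)."""
    a = np.asarray(band_a, dtype=np.float64)
    b = np.asarray(band_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"band shapes differ: {a.shape} vs {b.shape}")
    num, den = a - b, a + b
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den != 0)
    return out


def to_ndi_stack(crop: MultispectralCrop) -> NDIImage:
    """5-band crop -> 3-channel NDI image, clipped to [-1, 1]."""
    p = crop.pixels
    channels = [ndi(p[:, :, i], p[:, :, j]) for i, j in NDI_CHANNEL_BANDS]
    stack = np.clip(np.stack(channels, axis=2), -1.0, 1.0)
    return NDIImage(stack.astype(np.float32), crop.label)


def to_training_array(images: list[NDIImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack NDI images into (N, 3, 64, 64) float32 plus (N,) int labels."""
    x = np.stack([im.pixels.transpose(2, 0, 1) for im in images]).astype(np.float32)
    y = np.array([im.label.value for im in images], dtype=np.int64)
    return x, y
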