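"""Synthetic 5-band crown images with class-dependent spectra.

Emulates the spectral behavior that separates damage stages in real imagery:
healthy conifer crowns reflect strongly in the NIR and little in the red;
declining crowns lose NIR reflectance and gain red; dead crowns flatten out
into a brown/gray spectrum. Each image is a circular crown of seeded random
radius over a dim soil/shadow background, with per-tree brightness jitter
and per-pixel Gaussian noise.

Also provides an NDI-threshold oracle classifier derived in closed form from
the generating profiles — an independent reference the learned classifier and
the generator can be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ClassLabel, MultispectralCrop
from .preprocess import NDIImage, ndi

#: per-class mean reflectance, bands blue, green, red, red-edge, NIR
_DEFAULT_MEANS = (
    (0.04, 0.10, 0.05, 0.30, 0.55),   # healthy: high NIR, low red
    (0.05, 0.10, 0.12, 0.28, 0.40),   # declining: NIR down, red up
    (0.10, 0.12, 0.22, 0.24, 0.25),   # dead: flat brown/gray
)


@dataclass(frozen=True)
class SpectralProfile:
    """Design parameters of the simulator (reflectances unitless, [0, 1])."""

    class_means: tuple = _DEFAULT_MEANS
    noise_sigma: float = 0.02          # per-pixel Gaussian noise
    radius_range: tuple = (18.0, 28.0)  # crown radius in pixels
    background: float = 0.05           # dim soil/shadow, all bands
    jitter: float = 0.10               # per-tree brightness jitter, +-10%
    size: int = 64

    def __post_init__(self):
        if len(self.class_means) != 3 or any(len(m) != 5 for m in self.class_means):
            raise ValueError("class_means must be 3 classes x 5 bands")
        flat = [v for m in self.class_means for v in m]
        if min(flat) < 0.0 or max(flat) > 1.0:
            raise ValueError("reflectances must lie in [0, 1]")
        lo, hi = self.radius_range
        if not (0.0 < lo <= hi < self.size / 2):
            raise ValueError(
                f"radius_range must lie within (0, {self.size / 2})")

    def crown_ndi_red_nir(self, label: int) -> float:
        """Closed-form crown value of NDI(red, NIR) for one class."""
        _b, _g, r, _re, nir = self.class_means[label]
        return float(ndi(np.array(r), np.array(nir)))


def make_crown(label: ClassLabel, profile: SpectralProfile,
               seed: int) -> MultispectralCrop:
    """One synthetic 64x64x5 crop: disk crown over background, clipped [0,1]."""
    rng = np.random.default_rng(seed)
    s = profile.size
    radius = rng.uniform(*profile.radius_range)
    jit = 1.0 + rng.uniform(-profile.jitter, profile.jitter)
    yy, xx = np.mgrid[0:s, 0:s]
    c = (s - 1) / 2.0
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
    means = np.array(profile.class_means[label.value])
    img = np.full((s, s, 5), profile.background, dtype=np.float64)
    img[mask] = means * jit
    if profile.noise_sigma > 0:
        img += rng.normal(0.0, profile.noise_sigma, img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return MultispectralCrop(img, f"synth-{label.value}-{seed}", label)


def make_dataset(n_per_class: int, profile: SpectralProfile | None = None,
                 seed: int = 0) -> list[MultispectralCrop]:
    """3 * n_per_class crops, exactly balanced, deterministically seeded."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    profile = profile or SpectralProfile()
    # one independent child seed per crop so noise realizations are disjoint
    children = np.random.SeedSequence(seed).spawn(3 * n_per_class)
    crops = []
    for i, child in enumerate(children):
        label = ClassLabel(i % 3)
        crop_seed = int(child.generate_state(1)[0] % (2 ** 31))
        crops.append(make_crown(label, profile, crop_seed))
    return crops


# ---------------------------------------------------------------------------
# independent NDI-threshold oracle
# ---------------------------------------------------------------------------

def _oracle_thresholds(profile: SpectralProfile) -> tuple[float, float]:
    v = sorted(profile.crown_ndi_red_nir(k) for k in range(3))
    return (v[0] + v[1]) / 2.0, (v[1] + v[2]) / 2.0


def crown_mean_channel1(ndi_pixels: np.ndarray,
                        profile: SpectralProfile | None = None) -> float:
    """Mean of channel 1 (NDI red,NIR) over a central disk safely inside the
    smallest simulated crown."""
    profile = profile or SpectralProfile()
    s = ndi_pixels.shape[0]
    c = (s - 1) / 2.0
    yy, xx = np.mgrid[0:s, 0:s]
    r = 0.75 * profile.radius_range[0]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= r ** 2
    return float(ndi_pixels[:, :, 1][mask].mean())


def ndi_threshold_oracle(image: NDIImage,
                         profile: SpectralProfile | None = None) -> ClassLabel:
    """Classify by the crown-mean of channel 1 (NDI red,NIR) against the two
    midpoint thresholds of the generating profiles.

    Healthy crowns sit far negative (NIR >> red), dead crowns near zero.
    This rule never sees the learned models — it is the independent
    reference for tests.
    """
    profile = profile or SpectralProfile()
    m = crown_mean_channel1(image.pixels, profile)
    t01, t12 = _oracle_thresholds(profile)
    by_value = {profile.crown_ndi_red_nir(k): k for k in range(3)}
    ordered = [by_value[v] for v in sorted(by_value)]
    if m < t01:
        return ClassLabel(ordered[0])
    if m < t12:
        return ClassLabel(ordered[1])
    return ClassLabel(ordered[2])


def conditional_sample_stats(generator, n_per_class: int = 100, seed: int = 0,
                             profile: SpectralProfile | None = None) -> dict:
    """Mode-collapse diagnostics for a trained class-conditional generator.

    Draws n_per_class samples per requested class and reports, via the
    independent NDI-threshold oracle: the fraction assigned to the requested
    class; the per-class mean of the crown-mean NDI(red,NIR) statistic and
    the mean gap between adjacent class means (half the healthy-to-dead
    spread for 3 classes); and per-class sample diversity, measured as the
    across-sample standard deviation of channel 1 at each central-disk pixel,
    averaged over the disk. A collapsed generator emits near-identical
    images, driving that diversity to zero; averaging the statistic over the
    disk first would not discriminate, because a ~500-pixel mean has tiny
    within-class spread even for ideal data.
    """
    profile = profile or SpectralProfile()
    rng = np.random.default_rng(seed)
    side = profile.size
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    r = 0.75 * profile.radius_range[0]
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= r ** 2
    agree, stats = 0, {}
    for label in range(3):
        imgs = generator.sample(n_per_class, label, lam=1.0, rng=rng)
        ch1 = np.clip(imgs[:, 1], -1.0, 1.0)          # (n, H, W)
        vals = ch1[:, disk].mean(axis=1)              # crown-mean per sample
        for img in imgs:
            pix = np.clip(img.transpose(1, 2, 0), -1.0, 1.0)
            pred = ndi_threshold_oracle(NDIImage(pix, ClassLabel(label)),
                                        profile)
            agree += int(pred.value == label)
        stats[label] = {
            "mean": float(vals.mean()),
            "crown_mean_std": float(vals.std()),
            "pixel_std": float(ch1[:, disk].std(axis=0).mean()),
        }
    means = sorted(s["mean"] for s in stats.values())
    gap = (means[-1] - means[0]) / 2.0
    return {
        "oracle_agreement": agree / (3 * n_per_class),
        "per_class": stats,
        "mean_gap": gap,
        "min_pixel_std": min(s["pixel_std"] for s in stats.values()),
    }
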