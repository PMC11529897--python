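"""Crown-crop dataset construction from multispectral orthomosaics.

A 5-band orthomosaic (blue 475, green 560, red 668, red-edge 717, NIR 842 nm)
plus a CSV of surveyed trees — pixel coordinates, field symptom scores and a
visual dead-crown flag — is turned into 64x64x5 crops with 3-class damage
labels (0 healthy, 1 declining, 2 dead), balanced to equal class counts and
split 8:2 stratified by class.

Labeling rule: crown discoloration and defoliation scores are weighted 1.5
(crown symptoms are what a nadir image can see), all five scores are summed,
and a total of two or less is healthy; visually dead crowns are labeled dead
regardless of scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

BAND_CENTERS_NM = (475, 560, 668, 717, 842)
BAND_NAMES = ("blue", "green", "red", "red_edge", "nir")
CLASS_NAMES = ("healthy", "declining", "dead")

_SCORE_RANGES = {
    "crown_color": (0, 5),
    "defoliation": (0, 4),
    "crown_size": (0, 1),
    "resin_flow": (0, 2),
    "bark_damage": (0, 2),
}


class WindowOutOfBoundsError(ValueError):
    """Crop window extends beyond the raster; the tree should be skipped."""


@dataclass(frozen=True)
class FieldScores:
    """Field-surveyed symptom scores, each on its own ordinal scale."""

    crown_color: int    # leaf color, 0 healthy green .. 5 gray
    defoliation: int    # needle loss bins, 0 (0-10%) .. 4 (75-100%)
    crown_size: int     # 1 if vertical crown size clearly reduced
    resin_flow: int     # fresh resin flows on the trunk, 0-2
    bark_damage: int    # structural bark damage, 0-2

    def __post_init__(self):
        for name, (lo, hi) in _SCORE_RANGES.items():
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and lo <= v <= hi):
                raise ValueError(
                    f"score '{name}'={v!r} outside its range [{lo}, {hi}]")


@dataclass(frozen=True)
class ClassLabel:
    """Damage stage: 0 healthy, 1 affected/declining, 2 dead."""

    value: int

    def __post_init__(self):
        if self.value not in (0, 1, 2):
            raise ValueError(f"class label must be 0, 1 or 2, got {self.value}")


@dataclass(frozen=True)
class TreeRecord:
    tree_id: str
    x_px: int           # column of the crown center in the orthomosaic
    y_px: int           # row of the crown center
    scores: FieldScores
    dead_flag: bool


@dataclass
class MultispectralCrop:
    """64x64x5 reflectance patch around one crown (bands blue..NIR)."""

    pixels: np.ndarray                       # (size, size, 5), float
    tree_id: str
    label: ClassLabel
    band_centers: tuple = BAND_CENTERS_NM

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 5:
            raise ValueError(f"crop must be (H, W, 5), got {p.shape}")
        if p.shape[0] != p.shape[1]:
            raise ValueError(f"crop must be square, got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("crop contains non-finite values")
        self.pixels = p


def score_to_class(scores: FieldScores, dead_flag: bool) -> ClassLabel:
    """Weighted symptom total -> 3-class stage.

    total = 1.5*(crown_color + defoliation) + crown_size + resin_flow +
    bark_damage; total <= 2 is healthy, otherwise declining. A visually dead
    crown is dead regardless of the total.
    """
    if dead_flag:
        return ClassLabel(2)
    total = 1.5 * (scores.crown_color + scores.defoliation) \
        + scores.crown_size + scores.resin_flow + scores.bark_damage
    return ClassLabel(0 if total <= 2 else 1)


def crop_crown(raster: np.ndarray, record: TreeRecord,
               size: int = 64) -> MultispectralCrop:
    """Cut the size x size window centered at the record's pixel coordinates.

    The raster is (H, W, 5), bands in file order blue..NIR. A window that
    would extend beyond the raster raises WindowOutOfBoundsError (no padding:
    padded pixels would fabricate reflectance).
    """
    raster = np.asarray(raster)
    if raster.ndim != 3 or raster.shape[2] != 5:
        raise ValueError(f"raster must be (H, W, 5), got {raster.shape}")
    if size <= 0 or size % 2:
        raise ValueError(f"size must be even and positive, got {size}")
    h, w = raster.shape[:2]
    half = size // 2
    r0, c0 = record.y_px - half, record.x_px - half
    if r0 < 0 or c0 < 0 or r0 + size > h or c0 + size > w:
        raise WindowOutOfBoundsError(
            f"tree {record.tree_id}: window [{r0}:{r0 + size}, "
            f"{c0}:{c0 + size}] outside raster {h}x{w}")
    window = raster[r0:r0 + size, c0:c0 + size, :].copy()
    return MultispectralCrop(window, record.tree_id,
                             score_to_class(record.scores, record.dead_flag))


def extract_crops(raster: np.ndarray, records: list[TreeRecord],
                  size: int = 64) -> list[MultispectralCrop]:
    """crop_crown over a manifest; out-of-bounds trees are logged and skipped."""
    crops = []
    for rec in records:
        try:
            crops.append(crop_crown(raster, rec, size))
        except WindowOutOfBoundsError as exc:
            log.warning("skipping tree: %s", exc)
    return crops


def balance_classes(crops: list[MultispectralCrop],
                    seed: int) -> list[MultispectralCrop]:
    """Downsample every class to the minority count (seeded, without
    replacement) and shuffle the result deterministically."""
    by_class = {0: [], 1: [], 2: []}
    for c in crops:
        by_class[c.label.value].append(c)
    missing = [k for k, v in by_class.items() if not v]
    if missing:
        raise ValueError(
            "cannot balance: no crops for class(es) "
            + ", ".join(f"{m} ({CLASS_NAMES[m]})" for m in missing))
    rng = np.random.default_rng(seed)
    n_min = min(len(v) for v in by_class.values())
    kept: list[MultispectralCrop] = []
    for k in (0, 1, 2):
        idx = rng.choice(len(by_class[k]), size=n_min, replace=False)
        kept.extend(by_class[k][i] for i in sorted(idx))
    order = rng.permutation(len(kept))
    return [kept[i] for i in order]


def split_dataset(crops: list[MultispectralCrop], test_fraction: float = 0.2,
                  seed: int = 42
                  ) -> tuple[list[MultispectralCrop], list[MultispectralCrop]]:
    """Stratified train/test partition; per-class test count =
    round(test_fraction * class count)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    by_class: dict[int, list[int]] = {}
    for i, c in enumerate(crops):
        by_class.setdefault(c.label.value, []).append(i)
    for k, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(
                f"class {k} ({CLASS_NAMES[k]}) has {len(idx)} member(s); "
                "need at least 2 to split")
    rng = np.random.default_rng(seed)
    test_idx: set[int] = set()
    for k in sorted(by_class):
        idx = by_class[k]
        n_test = int(round(test_fraction * len(idx)))
        chosen = rng.choice(len(idx), size=n_test, replace=False)
        test_idx.update(idx[i] for i in chosen)
    train = [c for i, c in enumerate(crops) if i not in test_idx]
    test = [c for i, c in enumerate(crops) if i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# I/O: orthomosaics, tree tables, crop files, manifests
# ---------------------------------------------------------------------------

def load_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a 5-band GeoTIFF as (H, W, 5) float plus geo metadata.

    Returns (array, geo) where geo may hold 'pixel_scale' and 'tiepoint'
    from the GeoTIFF tags (used for lon/lat -> pixel conversion).
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        geo = {}
        for tag_name, key in (("ModelPixelScaleTag", "pixel_scale"),
                              ("ModelTiepointTag", "tiepoint")):
            tag = page.tags.get(tag_name)
            if tag is not None:
                geo[key] = tuple(float(v) for v in tag.value)
    if arr.ndim == 3 and arr.shape[0] == 5 and arr.shape[2] != 5:
        arr = np.moveaxis(arr, 0, 2)     # planar (5, H, W) -> (H, W, 5)
    if arr.ndim != 3 or arr.shape[2] != 5:
        raise ValueError(
            f"{path}: expected a 5-band raster, got shape {arr.shape}")
    return arr.astype(np.float64), geo


def geo_to_pixel(lon: float, lat: float, geo: dict) -> tuple[int, int]:
    """Map geographic coordinates to (x_px, y_px) via the raster's
    pixel-scale/tiepoint geotransform (north-up rasters)."""
    if "pixel_scale" not in geo or "tiepoint" not in geo:
        raise ValueError("raster carries no geotransform; "
                         "provide pixel coordinates instead")
    sx, sy = geo["pixel_scale"][0], geo["pixel_scale"][1]
    i, j, _k, gx, gy, _gz = geo["tiepoint"][:6]
    x = i + (lon - gx) / sx
    y = j + (gy - lat) / sy
    return int(round(x)), int(round(y))


def read_tree_table(path: str | Path, geo: dict | None = None) -> list[TreeRecord]:
    """Parse the tree CSV into TreeRecords.

    Required columns: tree_id, the five score columns, dead_flag, and either
    x/y (0-based pixel, x=column) or lon/lat (converted via the raster's
    geotransform).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: tree table is empty")
    score_cols = list(_SCORE_RANGES)
    needed = ["tree_id", *score_cols, "dead_flag"]
    missing = [c for c in needed if c not in df.columns]
    has_px = {"x", "y"}.issubset(df.columns)
    has_geo = {"lon", "lat"}.issubset(df.columns)
    if not has_px and not has_geo:
        missing.append("x/y (or lon/lat)")
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    if df["tree_id"].duplicated().any():
        dupes = df.loc[df["tree_id"].duplicated(), "tree_id"].tolist()
        raise ValueError(f"{path}: duplicate tree_id(s): {dupes}")
    records = []
    for row in df.itertuples(index=False):
        if has_px:
            x_px, y_px = int(row.x), int(row.y)
        else:
            x_px, y_px = geo_to_pixel(float(row.lon), float(row.lat), geo or {})
        scores = FieldScores(**{c: int(getattr(row, c)) for c in score_cols})
        records.append(TreeRecord(str(row.tree_id), x_px, y_px, scores,
                                  bool(row.dead_flag)))
    return records


def write_crop(path: str | Path, crop: MultispectralCrop) -> None:
    """Write one crop as a 5-band TIFF (bit-exact round trip)."""
    tifffile.imwrite(str(path), crop.pixels, photometric="minisblack")


def read_crop(path: str | Path, tree_id: str, label: ClassLabel
              ) -> MultispectralCrop:
    return MultispectralCrop(tifffile.imread(str(path)), tree_id, label)


def write_manifest(path: str | Path, rows: list[dict]) -> None:
    """CSV manifest: tree_id, file, label, split."""
    pd.DataFrame(rows, columns=["tree_id", "file", "label", "split"]) \
        .to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"tree_id", "file", "label", "split"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: manifest missing columns "
                         f"{sorted(needed - set(df.columns))}")
    return df


def load_split(manifest_path: str | Path, split: str) -> list[MultispectralCrop]:
    """Load all crops of one split ('train'/'test') from a manifest."""
    df = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    out = []
    for row in df[df["split"] == split].itertuples(index=False):
        out.append(read_crop(base / row.file, str(row.tree_id),
                             ClassLabel(int(row.label))))
    return out
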