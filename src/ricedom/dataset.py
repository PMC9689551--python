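"""Dataset assembly: stratified 6:2:2 splits and the training-set
augmentation recipe.

Augmentation: center crop to 224×224 (padding smaller crops with the
background shade), independent 30% random draws for horizontal and
vertical flips, a random rotation in [35°, 135°] for every training
image, then per-channel standardization with statistics computed on the
training split only (no leakage into validation/test, which receive only
the crop and standardization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LabeledImage",
    "SplitRatios",
    "Splits",
    "ChannelStats",
    "AugmentConfig",
    "split",
    "center_crop",
    "augment_training_set",
    "channel_stats",
    "standardize",
    "save_manifest",
    "load_manifest",
]


@dataclass
class LabeledImage:
    """One image with its grade label and provenance id."""

    image: np.ndarray  # H×W×3 uint8
    label: int
    source_id: str = ""


@dataclass(frozen=True)
class SplitRatios:
    train: float = 0.6
    val: float = 0.2
    test: float = 0.2

    def __post_init__(self):
        vals = (self.train, self.val, self.test)
        if any(v <= 0 for v in vals):
            raise ValueError("ratios must be positive")
        if not np.isclose(sum(vals), 1.0):
            raise ValueError(f"ratios must sum to 1, got {sum(vals)}")


@dataclass
class Splits:
    train: list[LabeledImage]
    val: list[LabeledImage]
    test: list[LabeledImage]


@dataclass
class ChannelStats:
    """Per-channel mean/std on [0, 1] intensities, training split only."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if (self.std <= 0).any():
            raise ValueError("channel std must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"mean": self.mean.tolist(), "std": self.std.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "ChannelStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["mean"]), np.array(d["std"]))


@dataclass
class AugmentConfig:
    crop_size: int = 224
    flip_fraction: float = 0.3
    rot_min: float = 35.0
    rot_max: float = 135.0
    fill: int = 15  # background shade used for padding/rotation fill

    def __post_init__(self):
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError("flip_fraction must be in [0, 1]")
        if self.rot_min > self.rot_max:
            raise ValueError("rot_min must not exceed rot_max")


def split(pool: list[LabeledImage], ratios: SplitRatios = SplitRatios(),
          seed: int = 0) -> Splits:
    """Stratified split: per class, val/test get floor(ratio·n) items and
    the remainder goes to train. Shuffling is seed-deterministic; a class
    with fewer than 3 items errors."""
    if not pool:
        raise ValueError("empty pool")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[LabeledImage]] = {}
    for item in pool:
        by_class.setdefault(item.label, []).append(item)
    out = Splits([], [], [])
    for label in sorted(by_class):
        items = by_class[label]
        n = len(items)
        if n < 3:
            raise ValueError(f"class {label} has only {n} image(s); need >= 3")
        order = rng.permutation(n)
        n_val = int(np.floor(ratios.val * n))
        n_test = int(np.floor(ratios.test * n))
        n_train = n - n_val - n_test
        shuffled = [items[i] for i in order]
        out.train.extend(shuffled[:n_train])
        out.val.extend(shuffled[n_train: n_train + n_val])
        out.test.extend(shuffled[n_train + n_val:])
    return out


def center_crop(img: np.ndarray, size: int = 224, fill: int = 15) -> np.ndarray:
    """Center crop to size×size; inputs smaller than `size` along an axis
    are first padded with the fill shade, original content centered."""
    h, w = img.shape[:2]
    pad_h = max(0, size - h)
    pad_w = max(0, size - w)
    if pad_h or pad_w:
        pads = ((pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2))
        if img.ndim == 3:
            pads = pads + ((0, 0),)
        img = np.pad(img, pads, constant_values=fill)
        h, w = img.shape[:2]
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return img[r0: r0 + size, c0: c0 + size]


def _rotate(img: np.ndarray, angle: float, fill: int) -> np.ndarray:
    out = ndimage.rotate(img.astype(np.float32), angle, reshape=False, order=1,
                         cval=fill, axes=(0, 1))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment_training_set(train: list[LabeledImage], cfg: AugmentConfig,
                         rng: np.random.Generator,
                         expand: bool = False) -> list[LabeledImage]:
    """Apply the flip/rotate recipe to a training split.

    Exactly round(flip_fraction·n) images are horizontally flipped and an
    independently drawn round(flip_fraction·n) vertically flipped (both
    selections without replacement; an image may receive both); then every
    image is rotated by an angle drawn uniformly from [rot_min, rot_max].
    By default the transformed images replace the originals (set size
    preserved); with `expand=True` they are appended instead."""
    n = len(train)
    k = int(round(cfg.flip_fraction * n))
    h_idx = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    v_idx = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    out = []
    for i, item in enumerate(train):
        img = item.image
        if i in h_idx:
            img = img[:, ::-1]
        if i in v_idx:
            img = img[::-1, :]
        angle = float(rng.uniform(cfg.rot_min, cfg.rot_max))
        img = _rotate(np.ascontiguousarray(img), angle, cfg.fill)
        out.append(LabeledImage(img, item.label, item.source_id))
    if expand:
        return list(train) + out
    return out


def channel_stats(train: list[LabeledImage]) -> ChannelStats:
    """Mean and population std per color channel over all pixels of all
    training images, on intensities scaled to [0, 1]."""
    if not train:
        raise ValueError("empty training set")
    total = np.zeros(3)
    total_sq = np.zeros(3)
    count = 0
    for item in train:
        x = item.image.reshape(-1, 3).astype(np.float64) / 255.0
        total += x.sum(axis=0)
        total_sq += (x * x).sum(axis=0)
        count += x.shape[0]
    mean = total / count
    var = total_sq / count - mean**2
    var = np.maximum(var, 0.0)
    if (var <= 0).any():
        raise ValueError("zero-variance color channel; cannot standardize")
    return ChannelStats(mean, np.sqrt(var))


def standardize(img: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Per channel: (intensity/255 − mean)/std, float32."""
    x = img.astype(np.float32) / 255.0
    return ((x - stats.mean.astype(np.float32)) / stats.std.astype(np.float32))


def save_manifest(splits: Splits, path) -> None:
    """CSV manifest with path (source id), label, split columns."""
    import pandas as pd

    rows = []
    for name in ("train", "val", "test"):
        for item in getattr(splits, name):
            rows.append({"path": item.source_id, "label": item.label, "split": name})
    pd.DataFrame(rows, columns=["path", "label", "split"]).to_csv(path, index=False)


def load_manifest(path):
    import pandas as pd

    return pd.read_csv(path)
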