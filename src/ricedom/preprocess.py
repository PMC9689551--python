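"""Scan preprocessing: grayscale, median smoothing, fixed-threshold
binarization, morphological cleanup.

Grains are bright on a near-black scanner plate, so a fixed global
threshold separates foreground without splitting endosperm from bran the
way adaptive methods tend to. The pipeline is
grayscale -> median filter -> threshold -> open/close.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessConfig",
    "to_grayscale",
    "median_smooth",
    "binarize_fixed",
    "refine_mask",
    "preprocess_scan",
]

#: ITU-R BT.601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class PreprocessConfig:
    """Knobs for the mask-extraction pipeline.

    median_kernel, open_kernel, close_kernel are odd window sides in pixels;
    threshold is the fixed grayscale cut (foreground strictly above it).
    """

    median_kernel: int = 3
    threshold: int = 100
    open_kernel: int = 3
    close_kernel: int = 3

    def __post_init__(self) -> None:
        for name in ("median_kernel", "open_kernel", "close_kernel"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be a positive odd integer, got {k}")
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must be in 0..255, got {self.threshold}")

    @classmethod
    def from_yaml(cls, path) -> "PreprocessConfig":
        """Load from YAML; accepts flat keys or a `preprocess:` block."""
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        cfg = cfg.get("preprocess", cfg)
        known = {k: v for k, v in cfg.items()
                 if k in ("median_kernel", "threshold", "open_kernel", "close_kernel")}
        return cls(**known)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luminance: round(0.299 R + 0.587 G + 0.114 B), uint8."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 color image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("empty image")
    gray = img.astype(np.float64) @ _LUMA
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def median_smooth(img: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with a kernel×kernel window; borders replicate edges."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("median_smooth expects a grayscale image")
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError(f"kernel must be odd, got {kernel}")
    if kernel > min(img.shape):
        raise ValueError("kernel larger than image")
    return ndimage.median_filter(img, size=kernel, mode="nearest")


def binarize_fixed(img: np.ndarray, threshold: int) -> np.ndarray:
    """Fixed global threshold: 1 where intensity > threshold, else 0."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in 0..255, got {threshold}")
    img = np.asarray(img)
    return (img > threshold).astype(np.uint8)


def refine_mask(mask: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Morphological opening (removes specks) then closing (fills holes
    smaller than the structuring element), square elements."""
    mask = np.asarray(mask).astype(bool)
    if cfg.open_kernel > 1:
        mask = ndimage.binary_opening(mask, structure=np.ones((cfg.open_kernel,) * 2))
    if cfg.close_kernel > 1:
        mask = ndimage.binary_closing(mask, structure=np.ones((cfg.close_kernel,) * 2))
    return mask.astype(np.uint8)


def preprocess_scan(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full pipeline from a color scan to a clean binary foreground mask."""
    cfg = cfg or PreprocessConfig()
    gray = to_grayscale(img)
    gray = median_smooth(gray, cfg.median_kernel)
    mask = binarize_fixed(gray, cfg.threshold)
    return refine_mask(mask, cfg)
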