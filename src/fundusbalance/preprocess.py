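"""Image standardization and stochastic training-time augmentation.

Every image is stretched to a square target size and standardized with
the fixed per-channel ImageNet-1K statistics.  During training a fixed
sequence of stochastic transforms is applied, each gated by its own
probability: rotation, horizontal/vertical flips, brightness/contrast
jitter, and cutout occlusion.  Augmentation is never applied at
validation or test time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["PreprocessConfig", "AugmentationConfig", "resize_normalize", "augment"]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class PreprocessConfig:
    target_size: int = 224
    mean: tuple[float, float, float] = IMAGENET_MEAN
    std: tuple[float, float, float] = IMAGENET_STD

    def __post_init__(self) -> None:
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if any(s <= 0 for s in self.std):
            raise ValueError("std components must be positive")


@dataclass
class AugmentationConfig:
    """Training-time transform probabilities and ranges."""

    rotate_prob: float = 0.8
    rotate_limit_deg: float = 90.0
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    brightness_contrast_prob: float = 0.5
    brightness_limit: float = 0.1
    contrast_limit: float = 0.15
    cutout_prob: float = 0.5
    cutout_holes: int = 20
    cutout_max_h: int = 11
    cutout_max_w: int = 11
    #: image side for which the cutout hole sizes are specified; holes are
    #: scaled proportionally when augmenting images of other sizes, so the
    #: occluded fraction stays constant across resolutions.
    reference_size: int = 224

    def __post_init__(self) -> None:
        for name in ("rotate_prob", "hflip_prob", "vflip_prob",
                     "brightness_contrast_prob", "cutout_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.cutout_max_h < 1 or self.cutout_max_w < 1:
            raise ValueError("cutout hole dimensions must be >= 1")
        if self.rotate_limit_deg < 0:
            raise ValueError("rotate_limit_deg must be >= 0")

    @classmethod
    def disabled(cls) -> "AugmentationConfig":
        return cls(rotate_prob=0.0, hflip_prob=0.0, vflip_prob=0.0,
                   brightness_contrast_prob=0.0, cutout_prob=0.0)


def resize_normalize(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Stretch to target_size x target_size and standardize per channel.

    Channels are scaled to [0, 1] then mapped to (x - mean) / std.  The
    operation involves no randomness.  Returns float32 HxWx3.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError(f"expected a nonempty HxWx3 RGB image, got shape {image.shape}")
    t = cfg.target_size
    if image.shape[:2] != (t, t):
        pil = Image.fromarray(image.astype(np.uint8))
        image = np.asarray(pil.resize((t, t), Image.BILINEAR))
    x = image.astype(np.float32) / 255.0
    mean = np.asarray(cfg.mean, dtype=np.float32)
    std = np.asarray(cfg.std, dtype=np.float32)
    return (x - mean) / std


def augment(
    image: np.ndarray,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
    return_applied: bool = False,
) -> np.ndarray | tuple[np.ndarray, dict[str, bool]]:
    """Apply the stochastic transform stack to a uint8 RGB image.

    Order is fixed: rotate -> hflip -> vflip -> brightness/contrast ->
    cutout.  Each transform fires independently with its configured
    probability; with ``return_applied`` the per-transform decisions are
    reported alongside the image.  Deterministic under a fixed rng.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    applied = {}

    applied["rotate"] = rng.random() < cfg.rotate_prob
    if applied["rotate"]:
        angle = rng.uniform(-cfg.rotate_limit_deg, cfg.rotate_limit_deg)
        img = ndimage.rotate(
            img.astype(np.float32), angle, axes=(1, 0), reshape=False,
            order=1, mode="constant", cval=0.0, prefilter=False,
        )
        img = np.clip(img, 0, 255).astype(np.uint8)

    applied["hflip"] = rng.random() < cfg.hflip_prob
    if applied["hflip"]:
        img = img[:, ::-1]

    applied["vflip"] = rng.random() < cfg.vflip_prob
    if applied["vflip"]:
        img = img[::-1]

    applied["brightness_contrast"] = rng.random() < cfg.brightness_contrast_prob
    if applied["brightness_contrast"]:
        b = rng.uniform(-cfg.brightness_limit, cfg.brightness_limit)
        c = rng.uniform(-cfg.contrast_limit, cfg.contrast_limit)
        out = img.astype(np.float32) * (1.0 + c) + b * 255.0
        img = np.clip(out, 0, 255).astype(np.uint8)

    applied["cutout"] = rng.random() < cfg.cutout_prob
    if applied["cutout"]:
        img = img.copy()
        h, w = img.shape[:2]
        scale = min(h, w) / cfg.reference_size
        max_h = max(1, int(round(cfg.cutout_max_h * scale)))
        max_w = max(1, int(round(cfg.cutout_max_w * scale)))
        for _ in range(cfg.cutout_holes):
            hh = int(rng.integers(1, max_h + 1))
            ww = int(rng.integers(1, max_w + 1))
            cy = int(rng.integers(0, h))
            cx = int(rng.integers(0, w))
            y0, y1 = max(cy - hh // 2, 0), min(cy - hh // 2 + hh, h)
            x0, x1 = max(cx - ww // 2, 0), min(cx - ww // 2 + ww, w)
            img[y0:y1, x0:x1] = 0

    img = np.ascontiguousarray(img)
    return (img, applied) if return_applied else img
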