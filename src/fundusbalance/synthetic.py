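"""Synthetic fundus-like image corpus with class-conditional structure.

Renders small RGB images that carry the visual motifs a fundus grader
uses for the four classes: a circular bright retina field on a dark
background, an optic disc with an inner cup (enlarged cup-to-disc ratio
for glaucoma), scattered bright exudate-like blobs plus dark
hemorrhage-like dots for diabetic retinopathy, and a cluster of yellowish
drusen-like deposits near the macula for AMD.  Acquisition artifacts of a
heterogeneous multi-camera corpus are emulated with per-image exposure
perturbation, additive pixel noise and a fraction of images rendered at a
different resolution.

Geometry is rendered analytically, so every image comes with ground-truth
feature metadata (disc/cup areas, lesion coordinates) usable as oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image

from .corpus import CorpusManifest, ImageRecord, ManifestError
from .labels import AMD, CLASSES, DR, GLAUCOMA, NORMAL, check_label

__all__ = [
    "SynthesisParams",
    "generate_image",
    "generate_corpus",
    "paper_ratio_counts",
]

#: Class totals of the merged 22-dataset corpus (Normal, Glaucoma, AMD, DR).
MERGED_CORPUS_TOTALS: dict[str, int] = {
    NORMAL: 86_415,
    GLAUCOMA: 3_787,
    AMD: 632,
    DR: 34_379,
}


def paper_ratio_counts(scale: float = 0.01) -> dict[str, int]:
    """Class counts proportional to the merged public corpus, scaled and rounded."""
    return {c: round(n * scale) for c, n in MERGED_CORPUS_TOTALS.items()}


@dataclass
class SynthesisParams:
    """Tunable knobs of the synthetic fundus renderer.

    Intensity values are on the 8-bit 0-255 scale.  Cup-to-disc ratios
    are *area* ratios; the default glaucoma range is disjoint from (and
    above) the normal range so the discriminative signal is unambiguous.
    Setting the class-specific ranges equal (see :meth:`null_signal`)
    collapses the classes to indistinguishable renderings, which is the
    null condition for signal-detection tests.
    """

    image_size: int = 64
    field_radius_fraction: float = 0.92
    cup_ratio_normal: tuple[float, float] = (0.10, 0.30)
    cup_ratio_glaucoma: tuple[float, float] = (0.55, 0.80)
    dr_bright_count: tuple[int, int] = (4, 9)
    dr_dark_count: tuple[int, int] = (4, 9)
    amd_blob_count: tuple[int, int] = (5, 9)
    lesion_intensity: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "dr_bright": (220.0, 255.0),
            "dr_dark": (5.0, 40.0),
            "amd": (190.0, 240.0),
        }
    )
    exposure_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 6.0
    alt_resolution_fraction: float = 0.10
    alt_resolution_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 0.0 < self.field_radius_fraction <= 1.0:
            raise ValueError("field_radius_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for lo, hi in (self.cup_ratio_normal, self.cup_ratio_glaucoma):
            if not 0.0 < lo <= hi < 1.0:
                raise ValueError("cup ratio ranges must satisfy 0 < lo <= hi < 1")
        for lo, hi in (self.dr_bright_count, self.dr_dark_count, self.amd_blob_count):
            if lo < 0 or hi < lo:
                raise ValueError("lesion count ranges must satisfy 0 <= lo <= hi")

    @classmethod
    def null_signal(cls, **kwargs) -> "SynthesisParams":
        """Parameters under which all four classes render identically."""
        return cls(
            cup_ratio_glaucoma=(0.10, 0.30),
            dr_bright_count=(0, 0),
            dr_dark_count=(0, 0),
            amd_blob_count=(0, 0),
            **kwargs,
        )


def _disk_mask(shape, cy, cx, ry, rx):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _paint_blob(img, cy, cx, radius, color):
    mask = _disk_mask(img.shape[:2], cy, cx, radius, radius)
    img[mask] = color


def _render(label: str, params: SynthesisParams, rng: np.random.Generator, size: int):
    """Render one image; returns (float image HxWx3, ground-truth metadata)."""
    s = size
    img = np.full((s, s, 3), 8.0)
    c = (s - 1) / 2.0
    R = params.field_radius_fraction * s / 2.0

    yy, xx = np.ogrid[:s, :s]
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    in_field = r2 <= R**2
    falloff = 1.0 - 0.35 * np.clip(r2 / R**2, 0, 1)
    base = np.array([195.0, 95.0, 42.0])
    img[in_field] = base * falloff[in_field][:, None]

    # macula: slightly darker central region (all classes)
    macula = _disk_mask((s, s), c, c, 0.22 * R, 0.22 * R)
    img[macula] *= 0.82

    # optic disc + cup; disc sits temporally, left or right at random
    side = 1 if rng.random() < 0.5 else -1
    disc_cx = c + side * 0.45 * R
    disc_cy = c + rng.uniform(-0.08, 0.08) * R
    disc_ry, disc_rx = 0.30 * R, 0.25 * R
    disc = _disk_mask((s, s), disc_cy, disc_cx, disc_ry, disc_rx)
    img[disc] = (235.0, 195.0, 115.0)

    cup_range = params.cup_ratio_glaucoma if label == GLAUCOMA else params.cup_ratio_normal
    cup_ratio = rng.uniform(*cup_range)  # area ratio cup/disc
    k = math.sqrt(cup_ratio)
    cup = _disk_mask((s, s), disc_cy, disc_cx, k * disc_ry, k * disc_rx)
    img[cup] = (252.0, 232.0, 170.0)

    # vessels: dark random walks leaving the disc
    n_vessels = 5
    vessel_color = np.array([95.0, 28.0, 18.0])
    for v in range(n_vessels):
        ang = rng.uniform(0, 2 * math.pi)
        y, x = disc_cy, disc_cx
        dy, dx = math.sin(ang), math.cos(ang)
        for _ in range(int(1.6 * R)):
            y += dy + rng.normal(0, 0.35)
            x += dx + rng.normal(0, 0.35)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < s and 0 <= ix < s):
                break
            if (iy - c) ** 2 + (ix - c) ** 2 > R**2:
                break
            img[max(iy - 1, 0) : iy + 1, max(ix - 1, 0) : ix + 1] = vessel_color

    meta = {
        "label": label,
        "disc_area": float(disc.sum()),
        "cup_area": float(cup.sum()),
        "cup_disc_area_ratio": float(cup.sum() / max(disc.sum(), 1)),
        "bright_lesions": [],
        "dark_lesions": [],
        "amd_deposits": [],
    }

    def _scatter_site(radius, placed):
        # keep lesions off the disc and apart so each stays a distinct
        # connected component (exudates spare the disc in real fundi too)
        for _ in range(60):
            ang, rad = rng.uniform(0, 2 * math.pi), rng.uniform(0.15, 0.8) * R
            ly, lx = c + rad * math.sin(ang), c + rad * math.cos(ang)
            on_disc = (((ly - disc_cy) / disc_ry) ** 2
                       + ((lx - disc_cx) / disc_rx) ** 2) <= 1.6
            clear = all(math.hypot(ly - py, lx - px) > radius + pr + 2.0
                        for py, px, pr in placed)
            if not on_disc and clear:
                return ly, lx
        return ly, lx

    if label == DR:
        k_bright = int(rng.integers(params.dr_bright_count[0], params.dr_bright_count[1] + 1))
        m_dark = int(rng.integers(params.dr_dark_count[0], params.dr_dark_count[1] + 1))
        placed: list[tuple[float, float, float]] = []
        lo, hi = params.lesion_intensity["dr_bright"]
        for _ in range(k_bright):
            radius = rng.uniform(0.040, 0.070) * s
            ly, lx = _scatter_site(radius, placed)
            inten = rng.uniform(lo, hi)
            _paint_blob(img, ly, lx, radius, (inten, inten, inten * 0.82))
            placed.append((ly, lx, radius))
            meta["bright_lesions"].append((ly, lx))
        lo, hi = params.lesion_intensity["dr_dark"]
        for _ in range(m_dark):
            radius = rng.uniform(0.028, 0.050) * s
            ly, lx = _scatter_site(radius, placed)
            inten = rng.uniform(lo, hi)
            _paint_blob(img, ly, lx, radius, (inten * 1.4, inten, inten))
            placed.append((ly, lx, radius))
            meta["dark_lesions"].append((ly, lx))
    elif label == AMD:
        n_blobs = int(rng.integers(params.amd_blob_count[0], params.amd_blob_count[1] + 1))
        lo, hi = params.lesion_intensity["amd"]
        for _ in range(n_blobs):
            ang, rad = rng.uniform(0, 2 * math.pi), rng.uniform(0.0, 0.25) * R
            ly, lx = c + rad * math.sin(ang), c + rad * math.cos(ang)
            inten = rng.uniform(lo, hi)
            _paint_blob(img, ly, lx, rng.uniform(0.040, 0.075) * s, (inten, inten * 0.92, inten * 0.42))
            meta["amd_deposits"].append((ly, lx))

    exposure = rng.uniform(*params.exposure_range)
    img *= exposure
    meta["exposure"] = float(exposure)
    if params.noise_sd > 0:
        img += rng.normal(0, params.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), meta


def generate_image(
    label: str,
    params: SynthesisParams,
    rng: np.random.Generator | int | None = None,
    index: int = 0,
    with_meta: bool = False,
):
    """Generate one labeled fundus-like image as an in-memory :class:`ImageRecord`.

    A fraction of images (``alt_resolution_fraction``) is rendered at a
    larger resolution to emulate multi-camera size heterogeneity; the
    preprocessing stage is responsible for standardizing sizes.
    """
    check_label(label)
    if rng is None or not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(params.seed if rng is None else rng)
    size = params.image_size
    if rng.random() < params.alt_resolution_fraction:
        size = int(round(size * params.alt_resolution_scale))
    pixels, meta = _render(label, params, rng, size)
    record = ImageRecord(
        id=f"{label.lower()}_{index:06d}",
        path=None,
        label=label,
        source="synthetic",
        width=size,
        height=size,
        pixels=pixels,
    )
    return (record, meta) if with_meta else record


def generate_corpus(
    counts: Mapping[str, int],
    params: SynthesisParams,
    seed: int,
    out_dir: str | Path | None = None,
) -> CorpusManifest:
    """Generate a labeled corpus with exactly the requested per-class counts.

    Images stay in memory on the records; when ``out_dir`` is given they
    are additionally written as PNG files next to a ``manifest.csv``.
    Identical (counts, params, seed) produce byte-identical corpora.
    """
    total = sum(int(counts.get(c, 0)) for c in CLASSES)
    if total < 1:
        raise ManifestError("generate_corpus requires at least one image (all counts zero)")
    for c in counts:
        check_label(c)
    rng = np.random.default_rng(seed)
    records: list[ImageRecord] = []
    for label in CLASSES:
        for i in range(int(counts.get(label, 0))):
            records.append(generate_image(label, params, rng, index=i))
    manifest = CorpusManifest(records)

    if out_dir is not None:
        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        for r in manifest:
            rel = f"images/{r.id}.png"
            Image.fromarray(r.pixels).save(out_dir / rel)
            r.path = rel
        manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def load_pixels(record: ImageRecord, root: str | Path | None = None) -> np.ndarray:
    """Return the uint8 RGB array of a record, decoding from disk if needed."""
    if record.pixels is not None:
        return record.pixels
    if record.path is None:
        raise ManifestError(f"record {record.id!r} has neither pixels nor a path")
    path = Path(root) / record.path if root is not None else Path(record.path)
    return np.asarray(Image.open(path).convert("RGB"))
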