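"""Seeded generator of panoramic-style grayscale scenes with exact masks.

Scenes are wide (aspect >= 1) images of two dental arches of elliptical
teeth.  Per tooth, four restoration classes are drawn independently:

* ``filling``   — irregular bright blob inside the crown half of the tooth,
* ``crown``     — cap covering the occlusal part of the tooth,
* ``root_canal``— thin tapered triangle on the root axis (small, infrequent),
* ``implant``   — threaded rectangle replacing the tooth (bright, rare).

Restorations render radiopaque (bright) over darker anatomy.  Mask channels
record the exact rendered geometry *before* blur/noise, and channels are not
mutually exclusive — e.g. a root-canal filling extends under its crown, so
overlapping pixels carry both labels.  Class size ranges and per-tooth
probabilities are configured so that root-canal objects are far smaller and
rarer than crowns/implants, matching the structure the tiling experiment is
sensitive to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import draw as skdraw

from tileseg.channels import CLASS_NAMES, MASK_SUFFIXES, N_CLASSES

__all__ = [
    "GenConfig",
    "LabeledImage",
    "generate_image",
    "generate_dataset",
    "load_dataset",
    "class_frequency_report",
]

# render intensities (8-bit scale)
_BG = 42.0
_BONE = 72.0
_TOOTH = 125.0
_INTENSITY = {"filling": 205.0, "crown": 220.0, "root_canal": 245.0, "implant": 235.0}

_REF_AREA = 256 * 512  # canvas at which default size ranges are stated


def _scaled(lo: float, hi: float, k: float) -> tuple[float, float]:
    return (lo * k, hi * k)


@dataclass(frozen=True)
class GenConfig:
    """Scene parameters; size ranges are pixel areas (min, max)."""

    height: int = 256
    width: int = 512
    n_teeth: int = 24
    p_filling: float = 0.45
    p_crown: float = 0.25
    p_root_canal: float = 0.15
    p_implant: float = 0.05
    filling_area: tuple = (60.0, 200.0)
    crown_area: tuple = (350.0, 700.0)
    root_canal_area: tuple = (25.0, 90.0)
    implant_area: tuple = (300.0, 600.0)
    background_noise_sd: float = 6.0
    blur_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.width < self.height:
            raise ValueError("panoramic aspect requires width >= height")
        if self.n_teeth < 1:
            raise ValueError("n_teeth must be >= 1")
        for name in ("p_filling", "p_crown", "p_root_canal", "p_implant"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("filling_area", "crown_area", "root_canal_area", "implant_area"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        if self.root_canal_area[1] >= self.crown_area[0]:
            raise ValueError("root_canal size range must lie strictly below crown's")
        if self.root_canal_area[1] >= self.implant_area[0]:
            raise ValueError("root_canal size range must lie strictly below implant's")

    @classmethod
    def scaled_default(cls, height: int, width: int, **overrides) -> "GenConfig":
        """Defaults with size ranges scaled to a different canvas area."""
        k = (height * width) / _REF_AREA
        base = cls()
        fields = dict(
            height=height,
            width=width,
            filling_area=_scaled(*base.filling_area, k),
            crown_area=_scaled(*base.crown_area, k),
            root_canal_area=_scaled(*base.root_canal_area, k),
            implant_area=_scaled(*base.implant_area, k),
        )
        fields.update(overrides)
        return cls(**fields)

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("filling_area", "crown_area", "root_canal_area", "implant_area"):
            d[name] = list(d[name])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenConfig":
        d = dict(d)
        for name in ("filling_area", "crown_area", "root_canal_area", "implant_area"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


@dataclass
class LabeledImage:
    """A grayscale scene, its 4-channel boolean mask, and object records."""

    image: np.ndarray  # (H, W) uint8
    mask: np.ndarray  # (4, H, W) bool
    metadata: list = field(default_factory=list)  # {class, bbox, area, tooth}
    id: str = ""

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape[1:]:
            raise ValueError("image and mask extents differ")
        if self.mask.shape[0] != N_CLASSES:
            raise ValueError(f"mask must have {N_CLASSES} channels")


def _paint(canvas: np.ndarray, mask: np.ndarray, channel: int, rr, cc,
           value: float, metadata: list, tooth: int, cls: str) -> None:
    """Render coords into canvas (max blend) and mask; record the object."""
    h, w = canvas.shape
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rr, cc = rr[keep], cc[keep]
    if rr.size == 0:
        return
    new = ~mask[channel, rr, cc]
    canvas[rr, cc] = np.maximum(canvas[rr, cc], value)
    mask[channel, rr, cc] = True
    metadata.append(
        {
            "class": cls,
            "tooth": tooth,
            "bbox": [int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1],
            "area": int(new.sum()),
        }
    )


def _tooth_positions(config: GenConfig, rng: np.random.Generator):
    """Tooth centers along the two arch curves; 'occlusal' sign points at the gap."""
    h, w = config.height, config.width
    n_upper = (config.n_teeth + 1) // 2
    n_lower = config.n_teeth - n_upper
    out = []
    for n_arch, (base, amp, occl) in (
        (n_upper, (0.30 * h, 0.10 * h, +1)),
        (n_lower, (0.70 * h, -0.10 * h, -1)),
    ):
        if n_arch == 0:
            continue
        xs = np.linspace(0.10 * w, 0.90 * w, n_arch)
        x0 = w / 2.0
        for x in xs:
            arch = 1.0 - ((x - x0) / (0.45 * w)) ** 2
            cy = base + amp * arch + rng.normal(0, 0.01 * h)
            cx = x + rng.normal(0, 0.005 * w)
            out.append((cy, cx, occl))
    return out


def generate_image(config: GenConfig, rng: np.random.Generator) -> LabeledImage:
    """Render one scene; mask channels are exact pre-noise geometry."""
    h, w = config.height, config.width
    canvas = np.full((h, w), _BG, dtype=np.float64)
    # soft bone band between the arches
    rows = np.arange(h)[:, None]
    band = np.exp(-(((rows - 0.5 * h) / (0.22 * h)) ** 2))
    canvas += (_BONE - _BG) * band
    mask = np.zeros((N_CLASSES, h, w), dtype=bool)
    metadata: list = []

    tooth_a = 0.085 * h  # vertical semi-axis
    tooth_b = 0.32 * (0.8 * w / max(config.n_teeth / 2.0, 1.0))

    for tooth_idx, (cy, cx, occl) in enumerate(_tooth_positions(config, rng)):
        a = tooth_a * rng.uniform(0.85, 1.15)
        b = tooth_b * rng.uniform(0.8, 1.2)
        has_implant = rng.random() < config.p_implant
        has_filling = rng.random() < config.p_filling
        has_crown = rng.random() < config.p_crown
        has_canal = rng.random() < config.p_root_canal

        if has_implant:
            area = rng.uniform(*config.implant_area)
            length = 2.0 * a
            width_i = max(area / length, 2.0)
            r0, r1 = int(cy - a), int(cy + a)
            c0, c1 = int(cx - width_i / 2), int(np.ceil(cx + width_i / 2))
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            rr, cc = rr.ravel(), cc.ravel()
            # thread ridges sticking out sideways
            ridge_rows = np.linspace(r0 + 2, r1 - 2, 4).astype(int)
            ridges_r, ridges_c = [], []
            for rrow in ridge_rows:
                ridges_r.append(np.full(2, rrow))
                ridges_c.append(np.array([c0 - 1, c1]))
            rr = np.concatenate([rr] + ridges_r)
            cc = np.concatenate([cc] + ridges_c)
            _paint(canvas, mask, CLASS_NAMES.index("implant"), rr, cc,
                   _INTENSITY["implant"], metadata, tooth_idx, "implant")

        # the tooth itself (anatomy, not a mask channel); an implant replaces
        # the natural tooth, but other restoration draws stay independent
        trr, tcc = skdraw.ellipse(cy, cx, a, b, shape=(h, w))
        if not has_implant:
            canvas[trr, tcc] = np.maximum(canvas[trr, tcc], _TOOTH * rng.uniform(0.9, 1.1))

        if has_crown and trr.size:
            area = int(min(rng.uniform(*config.crown_area), 0.7 * trr.size))
            # the `area` occlusal-most pixels of the tooth form the cap
            order = np.argsort(occl * trr, kind="stable")[::-1][:area]
            _paint(canvas, mask, CLASS_NAMES.index("crown"), trr[order], tcc[order],
                   _INTENSITY["crown"], metadata, tooth_idx, "crown")

        if has_filling:
            area = rng.uniform(*config.filling_area)
            ratio = rng.uniform(0.5, 2.0)
            fa = np.sqrt(area / np.pi * ratio)
            fb = np.sqrt(area / np.pi / ratio)
            fcy = cy + occl * a * rng.uniform(0.2, 0.6)
            fcx = cx + rng.uniform(-0.4, 0.4) * b
            frr, fcc = skdraw.ellipse(fcy, fcx, max(fa, 1.0), max(fb, 1.0),
                                      shape=(h, w), rotation=rng.uniform(-1.5, 1.5))
            _paint(canvas, mask, CLASS_NAMES.index("filling"), frr, fcc,
                   _INTENSITY["filling"], metadata, tooth_idx, "filling")

        if has_canal:
            area = rng.uniform(*config.root_canal_area)
            # cone width stays 3-8 px at any canvas: thinner would vanish
            # from even native-resolution tiles, wider would stop being
            # "thin" relative to desk-scale teeth
            base_w = rng.uniform(3.0, 8.0)
            length = np.clip(2.0 * area / base_w, 3.0, 1.4 * a)
            tip_r = cy - occl * a  # root tip
            base_r = tip_r + occl * length  # extends past center into the crown half
            jitter = rng.uniform(-0.15, 0.15) * b
            poly_r = np.array([tip_r, base_r, base_r])
            poly_c = np.array([cx + jitter, cx - base_w / 2, cx + base_w / 2])
            prr, pcc = skdraw.polygon(poly_r, poly_c, shape=(h, w))
            _paint(canvas, mask, CLASS_NAMES.index("root_canal"), prr, pcc,
                   _INTENSITY["root_canal"], metadata, tooth_idx, "root_canal")

    # photometric degradation on the image only; masks stay pre-noise geometry
    if config.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        canvas = gaussian_filter(canvas, sigma=config.blur_sigma)
    if config.background_noise_sd > 0:
        canvas = canvas + rng.normal(0.0, config.background_noise_sd, size=canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return LabeledImage(image=image, mask=mask, metadata=metadata)


def _image_rng(base_seed: int, index: int) -> np.random.Generator:
    # mixing rule: SeedSequence([base_seed, index]) — extending a dataset
    # never reshuffles earlier images
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), int(index)]))


def generate_dataset(
    config: GenConfig,
    n_images: int,
    seed: int | None = None,
    out_dir=None,
):
    """Generate ``n_images`` independent scenes; optionally write them out.

    Returns ``(images, manifest)``.  With ``out_dir`` set, writes 8-bit
    grayscale image PNGs, four binary {0,255} mask PNGs per image, and a
    ``manifest.json`` array of records.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    base_seed = config.seed if seed is None else seed

    images, manifest = [], []
    for i in range(n_images):
        item = generate_image(config, _image_rng(base_seed, i))
        item.id = f"img_{i:05d}"
        images.append(item)
        record = {
            "id": item.id,
            "image_path": f"images/{item.id}.png",
            "mask_paths": [f"masks/{item.id}{sfx}.png" for sfx in MASK_SUFFIXES],
            "height": config.height,
            "width": config.width,
            "seed": int(base_seed),
        }
        manifest.append(record)

    if out_dir is not None:
        out = Path(out_dir)
        try:
            (out / "images").mkdir(parents=True, exist_ok=True)
            (out / "masks").mkdir(parents=True, exist_ok=True)
            for item, record in zip(images, manifest):
                Image.fromarray(item.image).save(out / record["image_path"])
                for c, path in enumerate(record["mask_paths"]):
                    Image.fromarray(item.mask[c].astype(np.uint8) * 255).save(out / path)
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
            with open(out / "genconfig.json", "w") as fh:
                json.dump(config.to_dict(), fh, indent=1)
        except OSError as exc:
            raise OSError(f"cannot write dataset to {out}: {exc}") from exc
    return images, manifest


def load_dataset(in_dir) -> list[LabeledImage]:
    """Read a dataset written by :func:`generate_dataset` (metadata not kept)."""
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    images = []
    for record in manifest:
        img = np.asarray(Image.open(in_dir / record["image_path"]))
        mask = np.stack(
            [np.asarray(Image.open(in_dir / p)) > 127 for p in record["mask_paths"]]
        )
        images.append(LabeledImage(image=img, mask=mask, id=record["id"]))
    return images


def class_frequency_report(dataset) -> pd.DataFrame:
    """Per-channel object count, mean object area and pixel prevalence.

    Prevalence = set pixels / total pixels over the whole dataset.  Object
    statistics come from generator metadata (objects that contributed no new
    pixels are ignored).
    """
    if not dataset:
        raise ValueError("dataset is empty")
    total_px = sum(item.image.size for item in dataset)
    rows = []
    for c, name in enumerate(CLASS_NAMES):
        areas = [
            obj["area"]
            for item in dataset
            for obj in item.metadata
            if obj["class"] == name and obj["area"] > 0
        ]
        set_px = sum(int(item.mask[c].sum()) for item in dataset)
        rows.append(
            {
                "channel": name,
                "object_count": len(areas),
                "mean_object_area": float(np.mean(areas)) if areas else 0.0,
                "pixel_prevalence": set_px / total_px,
            }
        )
    return pd.DataFrame(rows).set_index("channel")
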