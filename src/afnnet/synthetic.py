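"""Synthetic nucleus-image generator.

Produces microscopy-like RGB tiles containing elliptical nucleus-shaped
blobs over a textured background, together with exact binary masks and
per-nucleus instance masks, in the Data Science Bowl 2018 stage-1 on-disk
layout (``<id>/images/<id>.png`` + ``<id>/masks/<k>.png``).  The generator
covers the regimes that make nucleus segmentation hard: small objects
(radii down to ~2 px), eccentric/rotated shapes, touching or overlapping
instances, low foreground/background contrast, and sensor noise.

Randomness is counter-based: sample ``index`` under a spec ``seed`` is an
independent stream, so any subset of a dataset can be regenerated
bit-identically in any order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError, ContractViolation

__all__ = ["SyntheticSpec", "SyntheticSample", "generate_sample", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the nucleus-image generator.

    Defaults emulate a 64×64 crop of a fluorescence-like nucleus image:
    a handful of bright elliptical nuclei (radius 2–10 px, possibly
    touching) on a dim textured background with mild Gaussian noise.
    """

    height: int = 64
    width: int = 64
    n_range: tuple = (1, 6)
    radius_range: tuple = (2.0, 10.0)
    axis_ratio_range: tuple = (0.5, 1.0)
    allow_overlap: bool = True
    fg_intensity_range: tuple = (0.55, 0.95)
    bg_intensity_range: tuple = (0.05, 0.25)
    noise_sd: float = 0.03
    texture_amplitude: float = 0.05
    seed: int = 0
    max_place_tries: int = 200

    def __post_init__(self):
        n_min, n_max = self.n_range
        if not (0 <= n_min <= n_max):
            raise ConfigurationError(f"need 0 <= n_min <= n_max, got {self.n_range}")
        if self.radius_range[0] < 1.0:
            raise ConfigurationError(f"radii must be >= 1 px, got {self.radius_range}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise sd must be >= 0, got {self.noise_sd}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("n_range", "radius_range", "axis_ratio_range",
                  "fg_intensity_range", "bg_intensity_range"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        for k in ("n_range", "radius_range", "axis_ratio_range",
                  "fg_intensity_range", "bg_intensity_range"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SyntheticSample:
    """One generated tile: image in [0,1], exact mask, instance masks."""

    image: np.ndarray            # (3, H, W) float in [0, 1]
    mask: np.ndarray             # (1, H, W) uint8 in {0, 1}
    nucleus_masks: list = field(default_factory=list)   # each (H, W) uint8
    metadata: list = field(default_factory=list)        # per-nucleus geometry dicts


def _rasterize_ellipse(H: int, W: int, cy: float, cx: float, a: float, b: float,
                       theta: float) -> np.ndarray:
    """Pixel-center inclusion test for a rotated ellipse."""
    rr, cc = np.mgrid[0:H, 0:W]
    dy, dx = rr - cy, cc - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    return (u * u + v * v <= 1.0).astype(np.uint8)


def _background(rng: np.random.Generator, H: int, W: int, spec: SyntheticSpec) -> np.ndarray:
    lo, hi = spec.bg_intensity_range
    base = rng.uniform(lo, hi)
    bg = np.full((H, W), base)
    if spec.texture_amplitude > 0:
        ch, cw = max(H // 8, 2), max(W // 8, 2)
        coarse = rng.standard_normal((ch, cw))
        tex = ndimage.zoom(coarse, (H / ch, W / cw), order=1, grid_mode=True,
                           mode="nearest")
        bg = bg + spec.texture_amplitude * tex
    return bg


def generate_sample(spec: SyntheticSpec, index: int) -> SyntheticSample:
    """Generate one tile deterministically from ``(spec.seed, index)``."""
    rng = np.random.default_rng([spec.seed, int(index)])
    H, W = spec.height, spec.width
    n = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))

    nucleus_masks, metadata = [], []
    occupied = np.zeros((H, W), dtype=bool)
    for _ in range(n):
        placed = False
        for _try in range(spec.max_place_tries):
            r = rng.uniform(*spec.radius_range)
            ratio = rng.uniform(*spec.axis_ratio_range)
            a, b = r, max(r * ratio, 1.0)
            theta = rng.uniform(0.0, np.pi)
            cy = rng.uniform(0.0, H - 1.0)
            cx = rng.uniform(0.0, W - 1.0)
            m = _rasterize_ellipse(H, W, cy, cx, a, b, theta)
            if not spec.allow_overlap and (m.astype(bool) & occupied).any():
                continue
            occupied |= m.astype(bool)
            nucleus_masks.append(m)
            metadata.append({"center": (cy, cx), "axes": (a, b), "rotation": theta,
                             "intensity": rng.uniform(*spec.fg_intensity_range)})
            placed = True
            break
        if not placed:
            raise ContractViolation(
                f"could not place nucleus without overlap after "
                f"{spec.max_place_tries} tries (image {H}x{W}, "
                f"radii {spec.radius_range}, n={n})"
            )

    mask = np.zeros((1, H, W), dtype=np.uint8)
    for m in nucleus_masks:
        mask[0] |= m

    gray = _background(rng, H, W, spec)
    for m, meta in zip(nucleus_masks, metadata):
        gray = np.where(m.astype(bool), np.maximum(gray, meta["intensity"]), gray)
    image = np.repeat(gray[None], 3, axis=0)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return SyntheticSample(image=image, mask=mask,
                           nucleus_masks=nucleus_masks, metadata=metadata)


def _sample_id(spec: SyntheticSpec, index: int) -> str:
    return f"synth_{spec.seed:08d}_{index:05d}"


def generate_dataset(spec: SyntheticSpec, n_samples: int, out_dir,
                     overwrite: bool = False) -> dict:
    """Write ``n_samples`` tiles in Bowl-2018 stage-1 layout; return the manifest.

    Layout per sample: ``<id>/images/<id>.png`` (8-bit RGB) and
    ``<id>/masks/<k>.png`` (one {0,255} PNG per nucleus).  A
    ``manifest.json`` at the root records the spec and sample ids.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise ConfigurationError(
            f"output directory {out} is not empty; pass overwrite=True to replace"
        )
    out.mkdir(parents=True, exist_ok=True)
    ids = []
    for index in range(n_samples):
        sample = generate_sample(spec, index)
        sid = _sample_id(spec, index)
        ids.append(sid)
        img_dir = out / sid / "images"
        msk_dir = out / sid / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        msk_dir.mkdir(parents=True, exist_ok=True)
        img8 = (np.round(sample.image * 255.0)).astype(np.uint8).transpose(1, 2, 0)
        Image.fromarray(img8, mode="RGB").save(img_dir / f"{sid}.png")
        for k, m in enumerate(sample.nucleus_masks):
            Image.fromarray((m * 255).astype(np.uint8), mode="L").save(
                msk_dir / f"{k:03d}.png"
            )
    manifest = {"spec": spec.to_dict(), "n_samples": n_samples, "ids": ids}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
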