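"""Dataset readers and paired image/mask augmentation.

Readers return a :class:`DatasetHandle` — an ordered list of samples, each
an RGB image in [0,1] (channels-first) with a single composed binary mask.
Supported layouts:

* Bowl-2018 stage 1: one directory per sample with ``images/<id>.png`` and
  ``masks/*.png`` (one PNG per nucleus, unioned on read);
* generic paired directories: ``images/<name>.png`` + ``masks/<name>.png``.

Augmentation applies one sampled similarity transform (rotation, flips,
isotropic scale) identically to image and mask — bilinear for the image,
nearest-neighbor for the mask so it stays binary — then resizes to the
model input size and normalizes intensities.  The sampled parameters are
returned so the exact coordinate map can be replayed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ContractViolation, DataLayoutError

__all__ = [
    "DatasetHandle",
    "load_bowl2018",
    "load_paired_dir",
    "GeomParams",
    "sample_geom_params",
    "apply_geom",
    "augment_batch",
    "IntensityStats",
    "compute_intensity_stats",
    "split_ids",
]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_image(path: Path) -> np.ndarray:
    """PNG → float (3, H, W) in [0, 1]."""
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0
    return arr.transpose(2, 0, 1)


def _read_mask(path: Path) -> np.ndarray:
    """Monochrome PNG → {0,1} (H, W); any nonzero pixel is foreground."""
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:
        if not (arr == arr[..., :1]).all():
            raise DataLayoutError(f"mask file {path} is not monochrome")
        arr = arr[..., 0]
    return (arr != 0).astype(np.uint8)


@dataclass
class DatasetHandle:
    """Ordered (image, mask, id) triples; eager arrays or lazy paths."""

    records: list  # (id, image_source, mask_sources)
    lazy: bool = True
    _cache: dict = field(default_factory=dict, repr=False)

    def __len__(self):
        return len(self.records)

    @property
    def ids(self):
        return [r[0] for r in self.records]

    def get(self, i: int):
        sid, img_src, mask_srcs = self.records[i]
        if i in self._cache:
            return self._cache[i]
        if isinstance(img_src, np.ndarray):
            image = img_src
            mask = mask_srcs
        else:
            image = _read_image(img_src)
            H, W = image.shape[1:]
            mask = np.zeros((H, W), dtype=np.uint8)
            for mp in mask_srcs:
                m = _read_mask(mp)
                if m.shape != (H, W):
                    raise DataLayoutError(
                        f"sample {sid}: mask {mp.name} shape {m.shape} "
                        f"differs from image {(H, W)}"
                    )
                mask |= m
            mask = mask[None]
        item = (image, mask, sid)
        if not self.lazy:
            self._cache[i] = item
        return item

    def __getitem__(self, i: int):
        return self.get(i)

    def __iter__(self):
        return (self.get(i) for i in range(len(self)))


def load_bowl2018(root) -> DatasetHandle:
    """Read a Bowl-2018 stage-1 style directory tree.

    Per-nucleus masks are unioned into one binary mask per sample; sample
    order is lexicographic in id.
    """
    root = Path(root)
    if not root.is_dir():
        raise DataLayoutError(f"dataset root {root} is not a directory")
    records = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        img_dir, msk_dir = sub / "images", sub / "masks"
        if not img_dir.is_dir() or not msk_dir.is_dir():
            raise DataLayoutError(
                f"sample {sub.name}: missing images/ or masks/ subdirectory"
            )
        images = sorted(img_dir.glob("*.png"))
        if len(images) != 1:
            raise DataLayoutError(
                f"sample {sub.name}: expected exactly one image PNG, found {len(images)}"
            )
        masks = sorted(msk_dir.glob("*.png"))
        records.append((sub.name, images[0], masks))
    if not records:
        raise DataLayoutError(f"no sample directories found under {root}")
    return DatasetHandle(records=records)


def load_paired_dir(root) -> DatasetHandle:
    """Read ``images/<name>.png`` + ``masks/<name>.png`` pairs."""
    root = Path(root)
    img_dir, msk_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not msk_dir.is_dir():
        raise DataLayoutError(f"{root} must contain images/ and masks/ directories")
    records = []
    for img_path in sorted(img_dir.glob("*.png")):
        mask_path = msk_dir / img_path.name
        if not mask_path.exists():
            raise DataLayoutError(f"no mask for image {img_path.name}")
        records.append((img_path.stem, img_path, [mask_path]))
    if not records:
        raise DataLayoutError(f"no image PNGs found under {img_dir}")
    return DatasetHandle(records=records)


# ---------------------------------------------------------------------------
# train/val split
# ---------------------------------------------------------------------------


def split_ids(ids, seed: int, train_fraction: float = 0.8):
    """Deterministic per-id split: membership depends only on (seed, id)."""
    if not 0.0 < train_fraction < 1.0:
        raise ContractViolation(f"train fraction must be in (0,1), got {train_fraction}")
    train, val = [], []
    for sid in ids:
        h = hashlib.sha256(f"{seed}:{sid}".encode()).digest()
        u = int.from_bytes(h[:8], "big") / 2**64
        (train if u < train_fraction else val).append(sid)
    return train, val


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeomParams:
    """One sampled similarity transform plus the resize to model input."""

    angle_deg: float
    scale: float
    hflip: bool
    vflip: bool
    in_shape: tuple
    out_size: tuple

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Forward affine map q = A p + t from input to output pixel coords."""
        H, W = self.in_shape
        S0, S1 = self.out_size
        th = np.deg2rad(self.angle_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        A = (self.scale * R)
        A = np.diag([S0 / H, S1 / W]) @ A
        A = np.diag([-1.0 if self.vflip else 1.0, -1.0 if self.hflip else 1.0]) @ A
        c_in = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
        c_out = np.array([(S0 - 1) / 2.0, (S1 - 1) / 2.0])
        t = c_out - A @ c_in
        return A, t

    def apply_to_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (n, 2) arrays of (row, col) input coordinates to output coords."""
        A, t = self.matrix()
        return np.asarray(pts) @ A.T + t


def sample_geom_params(rng: np.random.Generator, in_shape, out_size,
                       rotate: bool = True, flip: bool = True, scale: bool = True,
                       rot_range: float = 90.0, scale_range=(0.8, 1.25)) -> GeomParams:
    return GeomParams(
        angle_deg=float(rng.uniform(-rot_range, rot_range)) if rotate else 0.0,
        scale=float(rng.uniform(*scale_range)) if scale else 1.0,
        hflip=bool(rng.random() < 0.5) if flip else False,
        vflip=bool(rng.random() < 0.5) if flip else False,
        in_shape=tuple(in_shape),
        out_size=tuple(out_size),
    )


def apply_geom(image: np.ndarray, mask: np.ndarray, params: GeomParams):
    """Warp one (3,H,W) image and (1,H,W) mask with the same transform."""
    A, t = params.matrix()
    Ainv = np.linalg.inv(A)
    offset = -Ainv @ t
    S0, S1 = params.out_size
    out_img = np.stack([
        ndimage.affine_transform(ch, Ainv, offset=offset, output_shape=(S0, S1),
                                 order=1, mode="reflect")
        for ch in image
    ])
    out_mask = ndimage.affine_transform(mask[0], Ainv, offset=offset,
                                        output_shape=(S0, S1), order=0,
                                        mode="constant", cval=0)
    return out_img, out_mask[None].astype(np.uint8)


@dataclass(frozen=True)
class IntensityStats:
    """Per-channel mean/std used for input standardization."""

    mean: tuple
    std: tuple

    def normalize(self, image: np.ndarray) -> np.ndarray:
        m = np.asarray(self.mean).reshape(3, 1, 1)
        s = np.asarray(self.std).reshape(3, 1, 1)
        return (image - m) / s


def compute_intensity_stats(data, ids=None) -> IntensityStats:
    """Channel statistics over a dataset (typically the training split)."""
    want = set(ids) if ids is not None else None
    total = np.zeros(3)
    total_sq = np.zeros(3)
    n = 0
    for image, _mask, sid in data:
        if want is not None and sid not in want:
            continue
        total += image.sum(axis=(1, 2))
        total_sq += (image**2).sum(axis=(1, 2))
        n += image.shape[1] * image.shape[2]
    if n == 0:
        raise ContractViolation("no images selected for intensity statistics")
    mean = total / n
    var = np.maximum(total_sq / n - mean**2, 1e-12)
    return IntensityStats(mean=tuple(mean), std=tuple(np.sqrt(var)))


def augment_batch(images, masks, out_size, rng: np.random.Generator | None = None,
                  train: bool = True, stats: IntensityStats | None = None,
                  rotate: bool = True, flip: bool = True, scale: bool = True,
                  rot_range: float = 90.0, scale_range=(0.8, 1.25)):
    """Augment (or merely resize+normalize) a list of paired samples.

    Returns stacked arrays (N,3,S,S) / (N,1,S,S) and the list of sampled
    :class:`GeomParams` (identity-like records in eval mode).
    """
    if isinstance(out_size, int):
        out_size = (out_size, out_size)
    out_imgs, out_masks, all_params = [], [], []
    for image, mask in zip(images, masks):
        in_shape = image.shape[1:]
        if train:
            if rng is None:
                raise ContractViolation("training-mode augmentation needs an rng")
            params = sample_geom_params(rng, in_shape, out_size, rotate=rotate,
                                        flip=flip, scale=scale,
                                        rot_range=rot_range, scale_range=scale_range)
        else:
            params = GeomParams(0.0, 1.0, False, False, tuple(in_shape), tuple(out_size))
        img_t, mask_t = apply_geom(image, mask, params)
        if stats is not None:
            img_t = stats.normalize(img_t)
        out_imgs.append(img_t)
        out_masks.append(mask_t)
        all_params.append(params)
    return np.stack(out_imgs), np.stack(out_masks), all_params
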