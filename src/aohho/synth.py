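"""Synthetic 4-class, 64x64 grayscale dataset emulating brain-MRI slices.

Each image is a smooth elliptical "brain" on a dark background plus a
class-specific lesion template:

* ``glioma`` — a large, irregular, off-center blob with a diffuse edge
  (superposition of several broad Gaussians);
* ``meningioma`` — a compact round bright blob at the periphery;
* ``pituitary`` — a small central bright blob;
* ``notumor`` — no lesion.

Lesion geometry (center, size, orientation, amplitude) is jittered per image,
Gaussian pixel noise of standard deviation ``noise_sd`` is added, and a
``class_overlap`` dial in [0, 1] blends every class's lesion field toward the
across-class mean, hardening the task continuously.  Images are clipped to
[0, 1] and generation is a pure function of :class:`SynthesisParams`.

The templates are geometric caricatures, not anatomy; the module's contract
is statistical class separability with a difficulty dial, which is what the
optimizer pipeline needs.  Default class counts follow a 1321/1339/1595/1457
train and 300/306/405/300 test composition (glioma/meningioma/notumor/
pituitary).

The preprocessing operators used on real image folders live here too:
``normalize`` (intensity / 255) and ``augment`` (random rotation within
±15°, horizontal flip with probability 0.5, zoom in [0.9, 1.1], width/height
shifts within ±10%), plus integer / one-hot label encoding with a stable
alphabetical class order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CLASS_NAMES",
    "TRAIN_COUNTS",
    "TEST_COUNTS",
    "ImageDataset",
    "SynthesisParams",
    "generate_dataset",
    "generate_train_test",
    "normalize",
    "augment",
    "encode_labels",
    "decode_labels",
]

CLASS_NAMES = ("glioma", "meningioma", "notumor", "pituitary")
TRAIN_COUNTS = (1321, 1339, 1595, 1457)
TEST_COUNTS = (300, 306, 405, 300)


@dataclass(frozen=True)
class ImageDataset:
    """A stack of grayscale images with integer labels."""

    images: np.ndarray            # (n, size, size) float32 in [0, 1]
    labels: np.ndarray            # (n,) int in {0..3}
    class_names: tuple[str, ...] = CLASS_NAMES
    split_tag: str = "train"

    def __post_init__(self) -> None:
        if self.images.shape[0] != self.labels.shape[0]:
            raise ValueError("images and labels must have the same length")

    def __len__(self) -> int:
        return self.images.shape[0]

    def save_folder(self, out_dir) -> Path:
        """Write the class-subfolder PNG layout (one directory per class)."""
        from PIL import Image

        out = Path(out_dir)
        for c, name in enumerate(self.class_names):
            cdir = out / name
            cdir.mkdir(parents=True, exist_ok=True)
            for i in np.flatnonzero(self.labels == c):
                arr = np.round(self.images[i] * 255.0).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(cdir / f"{self.split_tag}_{i:05d}.png")
        return out


@dataclass(frozen=True)
class SynthesisParams:
    """Generator settings: per-class counts (glioma, meningioma, notumor,
    pituitary), pixel-noise SD, class-overlap dial and image size."""

    n_per_class: tuple[int, int, int, int] = TRAIN_COUNTS
    noise_sd: float = 0.05
    class_overlap: float = 0.0
    image_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 4 or any(n < 1 for n in self.n_per_class):
            raise ValueError("n_per_class must be four positive counts")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.class_overlap <= 1.0):
            raise ValueError("class_overlap must lie in [0, 1]")


def _gaussian_blob(yy, xx, cy, cx, sy, sx, amplitude):
    return amplitude * np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2) / 2.0)


def _brain_background(yy, xx, size, rng):
    cy = size / 2 + rng.uniform(-0.15, 0.15)
    cx = size / 2 + rng.uniform(-0.15, 0.15)
    ay = size * (0.44 + rng.uniform(-0.005, 0.005))
    ax = size * (0.38 + rng.uniform(-0.005, 0.005))
    dist = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    mask = 1.0 / (1.0 + np.exp((dist - 1.0) / 0.04))
    shading = 1.0 + 0.15 * (yy - cy) / size - 0.25 * dist**2
    level = 0.45 + rng.uniform(-0.005, 0.005)
    return level * mask * shading, mask


def _lesion_fields(yy, xx, size, rng):
    """All four class lesion fields from one jitter draw (order = CLASS_NAMES).

    Lesion locations are anchored per class (with small per-image jitter) so
    that class means stay well separated while every image remains distinct.
    """
    center = size / 2

    # glioma: 3 broad overlapping blobs in the upper-left region, diffuse edge
    theta = 0.60 * np.pi + rng.uniform(-0.06, 0.06)
    r0 = size * (0.17 + rng.uniform(-0.005, 0.005))
    gy, gx = center - r0 * np.sin(theta), center + r0 * np.cos(theta)
    glioma = np.zeros_like(yy, dtype=float)
    for k, (dy, dx) in enumerate(((0.0, 0.0), (0.04, 0.03), (-0.03, 0.04))):
        oy = gy + (dy + rng.uniform(-0.005, 0.005)) * size
        ox = gx + (dx + rng.uniform(-0.005, 0.005)) * size
        sy = size * (0.10 + rng.uniform(-0.005, 0.005))
        sx = size * (0.10 + rng.uniform(-0.005, 0.005))
        glioma += _gaussian_blob(yy, xx, oy, ox, sy, sx, 0.15 + rng.uniform(-0.008, 0.008))

    # meningioma: compact bright blob at the lower-right periphery
    phi = -0.25 * np.pi + rng.uniform(-0.04, 0.04)
    r1 = size * (0.27 + rng.uniform(-0.005, 0.005))
    s1 = size * (0.060 + rng.uniform(-0.002, 0.002))
    meningioma = _gaussian_blob(yy, xx, center - r1 * np.sin(phi), center + r1 * np.cos(phi),
                                s1, s1, 0.48 + rng.uniform(-0.02, 0.02))

    notumor = np.zeros_like(yy, dtype=float)

    # pituitary: small central bright blob
    py = center + rng.uniform(-0.3, 0.3)
    px = center + rng.uniform(-0.3, 0.3)
    s2 = size * (0.045 + rng.uniform(-0.002, 0.002))
    pituitary = _gaussian_blob(yy, xx, py, px, s2, s2, 0.55 + rng.uniform(-0.02, 0.02))

    return glioma, meningioma, notumor, pituitary


def generate_dataset(params: SynthesisParams, split_tag: str = "train") -> ImageDataset:
    """Generate a labeled image stack; fully reproducible from ``params.seed``."""
    size = params.image_size
    rng = np.random.default_rng(params.seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    images, labels = [], []
    for c in range(4):
        for _ in range(params.n_per_class[c]):
            background, mask = _brain_background(yy, xx, size, rng)
            fields = _lesion_fields(yy, xx, size, rng)
            lam = params.class_overlap
            lesion = (1.0 - lam) * fields[c] + lam * np.mean(fields, axis=0)
            img = background + lesion * mask
            if params.noise_sd > 0:
                img = img + rng.normal(0.0, params.noise_sd, img.shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(c)
    return ImageDataset(
        images=np.asarray(images, dtype=np.float32),
        labels=np.asarray(labels, dtype=int),
        split_tag=split_tag,
    )


def generate_train_test(
    n_train_per_class: tuple[int, int, int, int] = TRAIN_COUNTS,
    n_test_per_class: tuple[int, int, int, int] = TEST_COUNTS,
    noise_sd: float = 0.05,
    class_overlap: float = 0.0,
    image_size: int = 64,
    seed: int = 0,
) -> tuple[ImageDataset, ImageDataset]:
    """Independent train and test draws from the same generator settings."""
    train_seed, test_seed = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    train = generate_dataset(SynthesisParams(tuple(n_train_per_class), noise_sd,
                                             class_overlap, image_size, int(train_seed)), "train")
    test = generate_dataset(SynthesisParams(tuple(n_test_per_class), noise_sd,
                                            class_overlap, image_size, int(test_seed)), "test")
    return train, test


def normalize(image: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to [0, 1] by dividing by 255 exactly."""
    arr = np.asarray(image, dtype=float)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr / 255.0


def augment(
    image: np.ndarray,
    rng: np.random.Generator,
    angle: float | None = None,
    flip: bool | None = None,
    zoom: float | None = None,
    shift: tuple[float, float] | None = None,
) -> np.ndarray:
    """Random rotation (±15°), horizontal flip (p=0.5), zoom (0.9-1.1) and
    width/height shift (±10% of size), with bilinear interpolation and edge
    padding; output shape and [0, 1] range are preserved.

    Any of the four draws can be forced for testing; ``None`` means draw.
    The identity transform (angle 0, no flip, zoom 1, shift 0) returns the
    image unchanged, exactly.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("augment expects a single 2-D image")
    size_y, size_x = img.shape
    if angle is None:
        angle = rng.uniform(-15.0, 15.0)
    if flip is None:
        flip = bool(rng.random() < 0.5)
    if zoom is None:
        zoom = rng.uniform(0.9, 1.1)
    if shift is None:
        shift = (rng.uniform(-0.1, 0.1) * size_y, rng.uniform(-0.1, 0.1) * size_x)

    out = img[:, ::-1] if flip else img
    if angle != 0.0 or zoom != 1.0 or shift != (0.0, 0.0):
        # positive angle rotates the scene counterclockwise (y up); in (row,
        # col) coordinates with row increasing downward this is the inverse
        # rotation by +theta applied to output pixels
        theta = np.deg2rad(angle)
        m_inv = np.array([[np.cos(theta), np.sin(theta)],
                          [-np.sin(theta), np.cos(theta)]]) / zoom
        center = np.array([(size_y - 1) / 2.0, (size_x - 1) / 2.0])
        offset = center - m_inv @ (center + np.asarray(shift, dtype=float))
        out = ndimage.affine_transform(out, m_inv, offset=offset, order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


def encode_labels(labels, mode: str = "integer"):
    """Encode class names as integers or one-hot rows (alphabetical order)."""
    codes = []
    for name in labels:
        if name not in CLASS_NAMES:
            raise ValueError(f"unknown class name {name!r}; expected one of {CLASS_NAMES}")
        codes.append(CLASS_NAMES.index(name))
    codes = np.asarray(codes, dtype=int)
    if mode == "integer":
        return codes
    if mode == "one_hot":
        return np.eye(len(CLASS_NAMES), dtype=int)[codes]
    raise ValueError("mode must be 'integer' or 'one_hot'")


def decode_labels(codes) -> list[str]:
    """Inverse of integer label encoding."""
    return [CLASS_NAMES[int(c)] for c in np.asarray(codes).ravel()]
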