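"""Dataset handling: deterministic splits, labeled-fraction partitions,
mirror/rotation augmentation, preprocessing to 128x128x3 in [0, 1], a
class-per-folder reader, and a synthetic leaf-lesion image generator used
as the test-bed when no real corpus is available.

All size arithmetic uses round-half-up: splitting n records at ratios
(r1, r2, ..., rm) assigns ``round_half_up(ri * n)`` records to every
component after the first and the remainder to the first, and a labeled
fraction f marks ``round_half_up(f * n)`` records of the training pool as
labeled.  This convention reproduces, e.g., a 50% partition of 32,581
records as 16,291 labeled / 16,290 unlabeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

UNLABELED_DIR = "_unlabeled"


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SampleRecord:
    image: object                     # path or (H, W, C) array
    label: str | int | None = None
    labeled: bool = True

    def __post_init__(self):
        if self.labeled and self.label is None:
            raise ValueError("labeled records must carry a label")

    def unlabel(self) -> "SampleRecord":
        return replace(self, label=None, labeled=False)


@dataclass(frozen=True)
class SplitSpec:
    """Ratios are (train, val, test) or (train, test); must sum to 1."""

    ratios: tuple = (0.6, 0.2, 0.2)
    labeled_fraction: float = 1.0
    seed: int = 0
    per_class: bool = True

    def __post_init__(self):
        if len(self.ratios) not in (2, 3) or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("need 2 or 3 ratios summing to 1")
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ValueError("labeled fraction must be in (0, 1]")


@dataclass(frozen=True)
class DatasetSplit:
    train: list
    validation: list
    test: list
    labeled_fraction: float = 1.0

    @property
    def train_labeled(self) -> list:
        return [r for r in self.train if r.labeled]

    @property
    def train_unlabeled(self) -> list:
        return [r for r in self.train if not r.labeled]


def _split_sizes(n: int, ratios: tuple) -> list[int]:
    tail = [round_half_up(r * n) for r in ratios[1:]]
    head = n - sum(tail)
    if head < 0:
        raise ValueError(f"cannot split {n} records at ratios {ratios}")
    return [head] + tail


def _split_one(records: list, ratios: tuple, rng: np.random.Generator):
    order = rng.permutation(len(records))
    sizes = _split_sizes(len(records), ratios)
    parts, start = [], 0
    for size in sizes:
        parts.append([records[i] for i in order[start:start + size]])
        start += size
    while len(parts) < 3:
        parts.insert(1, [])          # two-way split has no validation part
    return parts


def split_dataset(records: list, spec: SplitSpec) -> DatasetSplit:
    """Deterministically split records into train/validation/test pools."""
    if not records:
        raise ValueError("cannot split an empty record list")
    rng = np.random.default_rng(spec.seed)
    if spec.per_class:
        by_class: dict = {}
        for r in records:
            by_class.setdefault(r.label, []).append(r)
        parts = [[], [], []]
        for label in sorted(by_class, key=str):
            for part, chunk in zip(parts, _split_one(by_class[label], spec.ratios, rng)):
                part.extend(chunk)
        train, val, test = parts
    else:
        train, val, test = _split_one(records, spec.ratios, rng)
    if spec.labeled_fraction < 1.0:
        labeled, unlabeled = label_partition(train, spec.labeled_fraction, spec.seed)
        train = labeled + [r.unlabel() for r in unlabeled]
    return DatasetSplit(train=train, validation=val, test=test,
                        labeled_fraction=spec.labeled_fraction)


def label_partition(train_pool: list, fraction: float, seed: int):
    """Split the training pool into (labeled, unlabeled) sub-pools."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(train_pool)
    n_labeled = round_half_up(fraction * n)
    order = np.random.default_rng(seed).permutation(n)
    labeled = [train_pool[i] for i in order[:n_labeled]]
    unlabeled = [train_pool[i] for i in order[n_labeled:]]
    return labeled, unlabeled


def augment_mirror_rotate(images: list) -> list:
    """Triple the pool: for each image emit (original, mirror, rot-180)."""
    out = []
    for img in images:
        arr = np.asarray(img)
        out.append(arr)
        out.append(arr[:, ::-1].copy())          # horizontal mirror
        out.append(arr[::-1, ::-1].copy())       # 180 degree rotation
    return out


def preprocess(image, side: int = 128) -> np.ndarray:
    """Decode/resize to (side, side, 3) float32 in [0, 1] (bilinear)."""
    if isinstance(image, (str, Path)):
        try:
            with Image.open(image) as im:
                pil = im.convert("RGB")
        except Exception as exc:
            raise OSError(f"cannot read image file {image}: {exc}") from exc
    elif isinstance(image, Image.Image):
        pil = image.convert("RGB")
    else:
        arr = np.asarray(image)
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0.0, 1.0)
            arr = (arr * 255).round().astype(np.uint8)
        pil = Image.fromarray(arr).convert("RGB")
    if pil.size != (side, side):
        pil = pil.resize((side, side), Image.BILINEAR)
    return np.asarray(pil, dtype=np.float32) / 255.0


def read_class_folders(root) -> list[SampleRecord]:
    """Read the `root/<class>/*.png|jpg` layout; `_unlabeled/` is the pool."""
    root = Path(root)
    records = []
    exts = {".png", ".jpg", ".jpeg"}
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for path in sorted(class_dir.iterdir()):
            if path.suffix.lower() not in exts:
                continue
            if class_dir.name == UNLABELED_DIR:
                records.append(SampleRecord(image=path, label=None, labeled=False))
            else:
                records.append(SampleRecord(image=path, label=class_dir.name))
    if not records:
        raise ValueError(f"no images found under {root}")
    return records


# ---------------------------------------------------------------------------
# synthetic leaf-lesion generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassSpec:
    """Lesion statistics of one synthetic disease class.

    A "healthy" class draws zero lesions; disease classes differ in lesion
    colour, count and radius so that classes are visually separable while
    sharing the same leaf/soil layout statistics.
    """

    name: str
    lesion_color: tuple = (0.45, 0.27, 0.12)
    lesion_count: tuple = (0, 0)          # inclusive range
    lesion_radius: tuple = (2, 4)         # pixels at side 128, scaled down
    def __post_init__(self):
        if self.lesion_count[0] > self.lesion_count[1] or self.lesion_count[0] < 0:
            raise ValueError("invalid lesion count range")
        if self.lesion_radius[0] > self.lesion_radius[1] or self.lesion_radius[0] <= 0:
            raise ValueError("invalid lesion radius range")


def default_class_specs() -> list[ClassSpec]:
    """Four classes: healthy + three diseases with distinct lesion spectra."""
    # lesion colours are chosen chromatically distant from both the leaf
    # green and the soil brown (whose texture noise is common-mode), so the
    # classes are visually separable the way distinct necroses are
    return [
        ClassSpec("healthy"),
        ClassSpec("rust_spot", lesion_color=(0.52, 0.10, 0.08),
                  lesion_count=(6, 12), lesion_radius=(3, 6)),
        ClassSpec("yellow_blight", lesion_color=(0.85, 0.80, 0.15),
                  lesion_count=(3, 7), lesion_radius=(6, 11)),
        ClassSpec("gray_mold", lesion_color=(0.72, 0.74, 0.80),
                  lesion_count=(10, 20), lesion_radius=(2, 4)),
    ]


def _smooth_noise(rng: np.random.Generator, side: int, sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    return gaussian_filter(rng.standard_normal((side, side)), sigma)


def _render_leaf_image(spec: ClassSpec, side: int, rng: np.random.Generator) -> np.ndarray:
    img = np.empty((side, side, 3), dtype=np.float32)
    # textured soil background
    soil = np.array([0.36, 0.26, 0.16])
    tex = _smooth_noise(rng, side, sigma=side / 24)
    for c in range(3):
        img[..., c] = np.clip(soil[c] + 0.35 * tex + 0.03 * rng.standard_normal((side, side)), 0, 1)
    # green leaf ellipse with vein-like texture noise
    yy, xx = np.mgrid[0:side, 0:side]
    cy = side / 2 + rng.uniform(-side / 16, side / 16)
    cx = side / 2 + rng.uniform(-side / 16, side / 16)
    ay = rng.uniform(0.30, 0.42) * side
    ax = rng.uniform(0.30, 0.42) * side
    theta = rng.uniform(0, np.pi)
    yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    inside = (yr / ay) ** 2 + (xr / ax) ** 2 <= 1.0
    leaf = np.array([0.18, 0.52, 0.16]) + rng.uniform(-0.04, 0.04, 3)
    vein = _smooth_noise(rng, side, sigma=side / 48)
    for c in range(3):
        img[..., c][inside] = np.clip(leaf[c] + 0.10 * vein[inside]
                                      + 0.02 * rng.standard_normal(inside.sum()), 0, 1)
    # class-specific lesion disks, kept on the leaf
    n_lesions = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
    scale = side / 128.0
    ys, xs = np.nonzero(inside)
    for _ in range(n_lesions):
        if len(ys) == 0:
            break
        j = rng.integers(len(ys))
        ly, lx = ys[j], xs[j]
        radius = max(1.0, rng.uniform(*spec.lesion_radius) * scale)
        mask = (yy - ly) ** 2 + (xx - lx) ** 2 <= radius ** 2
        mask &= inside
        color = np.clip(np.array(spec.lesion_color) + rng.uniform(-0.05, 0.05, 3), 0, 1)
        for c in range(3):
            img[..., c][mask] = color[c]
    return img


def synth_generate(n_per_class: int, class_specs: list[ClassSpec] | None = None,
                   seed: int = 0, side: int = 128, n_unlabeled: int = 0):
    """Generate labeled and unlabeled synthetic leaf pools.

    Returns ``(images, labels, class_names, unlabeled_images)`` with images
    float32 channels-last in [0, 1].  Fully deterministic given the seed.
    """
    specs = class_specs if class_specs is not None else default_class_specs()
    if len(specs) < 2:
        raise ValueError("need at least two class specs")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for ci, spec in enumerate(specs):
        for _ in range(n_per_class):
            images.append(_render_leaf_image(spec, side, rng))
            labels.append(ci)
    unlabeled = []
    for _ in range(n_unlabeled):
        spec = specs[rng.integers(len(specs))]
        unlabeled.append(_render_leaf_image(spec, side, rng))
    images = np.asarray(images, dtype=np.float32).reshape(-1, side, side, 3)
    labels = np.asarray(labels, dtype=np.int64)
    unlabeled = (np.asarray(unlabeled, dtype=np.float32).reshape(-1, side, side, 3)
                 if unlabeled else np.empty((0, side, side, 3), dtype=np.float32))
    return images, labels, [s.name for s in specs], unlabeled


def write_class_folders(root, images: np.ndarray, labels: np.ndarray,
                        class_names: list[str], unlabeled: np.ndarray | None = None):
    """Write images as `root/<class>/NNNN.png` (plus `_unlabeled/`)."""
    root = Path(root)
    counters: dict = {}
    for img, label in zip(images, labels):
        name = class_names[int(label)]
        d = root / name
        d.mkdir(parents=True, exist_ok=True)
        i = counters.get(name, 0)
        counters[name] = i + 1
        Image.fromarray((np.clip(img, 0, 1) * 255).round().astype(np.uint8)).save(
            d / f"{i:04d}.png")
    if unlabeled is not None and len(unlabeled):
        d = root / UNLABELED_DIR
        d.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(unlabeled):
            Image.fromarray((np.clip(img, 0, 1) * 255).round().astype(np.uint8)).save(
                d / f"{i:04d}.png")
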