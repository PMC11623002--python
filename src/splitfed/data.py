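"""Dataset handling for imbalanced grayscale image classification.

The in-memory currency is :class:`LabeledImageSet`: a list of 2-D float
images in [0, 1] with integer class labels, an ordered class-name map and a
per-image real/synthetic provenance flag. Operations here cover imbalance
accounting, ratio-preserving subsampling, stratified train/test splitting,
IID client sharding, the training-time augmentation pipeline and
class-per-folder PNG I/O.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

#: Fixed class-index convention used throughout the package.
DEFAULT_CLASS_NAMES = ["Mild Dementia", "Moderate Dementia", "Non Dementia"]

REAL = "real"
SYNTHETIC = "synthetic"


class DatasetError(ValueError):
    """Raised for invalid dataset contents or arguments."""


@dataclass
class LabeledImageSet:
    """Grayscale images plus labels, class names and provenance flags."""

    images: list
    labels: np.ndarray
    class_names: list
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise DatasetError("images and labels must have equal length")
        if not self.provenance:
            self.provenance = [REAL] * len(self.images)
        if len(self.provenance) != len(self.images):
            raise DatasetError("provenance must match the number of images")
        if len(self.labels) and self.labels.max(initial=-1) >= len(self.class_names):
            raise DatasetError("label exceeds the number of class names")
        if len(self.labels) and self.labels.min(initial=0) < 0:
            raise DatasetError("negative class label")
        for im in self.images:
            if im.ndim != 2:
                raise DatasetError("images must be 2-D grayscale arrays")
            if im.min() < -1e-6 or im.max() > 1 + 1e-6:
                raise DatasetError("pixel values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices) -> "LabeledImageSet":
        indices = np.asarray(indices, dtype=np.int64)
        return LabeledImageSet(
            images=[self.images[i] for i in indices],
            labels=self.labels[indices],
            class_names=list(self.class_names),
            provenance=[self.provenance[i] for i in indices],
        )

    def stack(self) -> np.ndarray:
        """(N, H, W) float32 array; requires homogeneous image sizes."""
        return np.stack(self.images).astype(np.float32)

    @staticmethod
    def concatenate(sets: list) -> "LabeledImageSet":
        if not sets:
            raise DatasetError("nothing to concatenate")
        return LabeledImageSet(
            images=[im for s in sets for im in s.images],
            labels=np.concatenate([s.labels for s in sets]),
            class_names=list(sets[0].class_names),
            provenance=[p for s in sets for p in s.provenance],
        )


@dataclass
class ClassDistribution:
    """Per-class counts and imbalance ratios relative to the majority class."""

    counts: np.ndarray
    ratios: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.ratios = np.asarray(self.ratios, dtype=np.float64)


@dataclass
class AugmentationConfig:
    """Training-time augmentation settings (grayscale)."""

    output_size: int = 224
    random_resized_crop: bool = True
    crop_scale: tuple = (0.8, 1.0)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_degrees: float = 15.0
    color_jitter: float = 0.2
    random_grayscale: bool = True
    normalize_mean: float = 0.5
    normalize_std: float = 0.5

    def __post_init__(self):
        if self.output_size <= 0:
            raise DatasetError("output_size must be positive")
        if self.rotation_degrees < 0:
            raise DatasetError("rotation_degrees must be nonnegative")


# --------------------------------------------------------------- imbalance
def compute_imbalance_ratio(minority_count: int, majority_count: int) -> float:
    """Minority-to-majority sample-count ratio in [0, 1]."""
    if majority_count == 0:
        raise DatasetError("imbalance ratio undefined for an empty majority class")
    if minority_count < 0:
        raise DatasetError("counts must be nonnegative")
    if minority_count > majority_count:
        raise DatasetError(
            "minority count exceeds majority count; arguments are swapped")
    return minority_count / majority_count


def class_distribution(dataset: LabeledImageSet) -> ClassDistribution:
    """Per-class counts and ratios versus the most populous class."""
    if len(dataset) == 0:
        raise DatasetError("empty dataset")
    counts = np.bincount(dataset.labels, minlength=dataset.n_classes)
    majority = counts.max()
    return ClassDistribution(counts=counts, ratios=counts / majority)


def _class_indices(dataset: LabeledImageSet) -> dict:
    return {c: np.flatnonzero(dataset.labels == c)
            for c in range(dataset.n_classes)}


def subsample_preserving_ratio(dataset: LabeledImageSet, fraction: float,
                               seed: int) -> LabeledImageSet:
    """Keep floor(fraction x count) of each class, sampled uniformly.

    Floor is used so a fractional quota never inflates a minority class.
    """
    if not (0 < fraction <= 1):
        raise DatasetError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    chosen = []
    for c, idx in sorted(_class_indices(dataset).items()):
        if len(idx) == 0:
            continue
        k = int(np.floor(fraction * len(idx)))
        if k < 1:
            raise DatasetError(
                f"class {dataset.class_names[c]!r} would drop to 0 samples")
        chosen.append(rng.choice(idx, size=k, replace=False))
    return dataset.subset(np.sort(np.concatenate(chosen)))


def stratified_split(dataset: LabeledImageSet, train_fraction: float,
                     seed: int):
    """Per-class split with train count = round(train_fraction x class count)."""
    if not (0 < train_fraction < 1):
        raise DatasetError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c, idx in sorted(_class_indices(dataset).items()):
        if len(idx) == 0:
            continue
        if len(idx) < 2:
            raise DatasetError(
                f"class {dataset.class_names[c]!r} has fewer than 2 samples")
        perm = rng.permutation(idx)
        k = int(np.floor(train_fraction * len(idx) + 0.5))  # round half up
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    return (dataset.subset(np.sort(np.concatenate(train_idx))),
            dataset.subset(np.sort(np.concatenate(test_idx))))


def partition_clients(dataset: LabeledImageSet, n_clients: int,
                      seed: int, scheme: str = "iid") -> list:
    """IID stratified sharding: class-sorted shuffled indices dealt round-robin,
    so shard sizes differ by at most one and per-class proportions match.

    ``scheme`` is a forward-compatibility hook; only "iid" is implemented.
    """
    if scheme != "iid":
        raise NotImplementedError(
            f"partition scheme {scheme!r} is not implemented (only 'iid')")
    if n_clients < 1:
        raise DatasetError("n_clients must be positive")
    if n_clients > len(dataset):
        raise DatasetError("more clients than samples")
    rng = np.random.default_rng(seed)
    order = []
    for c, idx in sorted(_class_indices(dataset).items()):
        order.append(rng.permutation(idx))
    order = np.concatenate(order)
    shards = [order[k::n_clients] for k in range(n_clients)]
    return [dataset.subset(np.sort(s)) for s in shards]


# ------------------------------------------------------------ augmentation
def _resize01(image: np.ndarray, size: int) -> np.ndarray:
    out = _sk_resize(image, (size, size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def build_augmentation(config: AugmentationConfig, seed: int):
    """Return a seeded callable image -> augmented image.

    Order: random resized crop (or plain resize), flips, rotation, intensity
    jitter (brightness + contrast for grayscale), grayscale conversion
    (identity here since inputs are single-channel), then normalization —
    normalization is always last.
    """
    rng = np.random.default_rng(seed)
    size = config.output_size

    def transform(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float32)
        if config.random_resized_crop:
            h, w = img.shape
            scale = rng.uniform(*config.crop_scale)
            ch = max(1, int(round(h * np.sqrt(scale))))
            cw = max(1, int(round(w * np.sqrt(scale))))
            top = rng.integers(0, h - ch + 1)
            left = rng.integers(0, w - cw + 1)
            img = img[top:top + ch, left:left + cw]
            img = _resize01(img, size)
        elif img.shape != (size, size):
            img = _resize01(img, size)
        if config.horizontal_flip and rng.random() < 0.5:
            img = img[:, ::-1]
        if config.vertical_flip and rng.random() < 0.5:
            img = img[::-1, :]
        if config.rotation_degrees > 0:
            angle = rng.uniform(-config.rotation_degrees, config.rotation_degrees)
            img = ndimage.rotate(img, angle, reshape=False, order=1,
                                 mode="nearest")
            img = np.clip(img, 0.0, 1.0)
        if config.color_jitter > 0:
            j = config.color_jitter
            img = img * rng.uniform(1 - j, 1 + j)           # brightness
            mean = img.mean()
            img = (img - mean) * rng.uniform(1 - j, 1 + j) + mean  # contrast
            img = np.clip(img, 0.0, 1.0)
        if config.random_grayscale:
            pass  # inputs are already single-channel
        img = (img - config.normalize_mean) / config.normalize_std
        return np.ascontiguousarray(img, dtype=np.float32)

    return transform


# ---------------------------------------------------------------- file I/O
def load_image_folder(root, class_names=None) -> LabeledImageSet:
    """Read a class-per-folder tree of PNG/JPEG grayscale images."""
    root = Path(root)
    if class_names is None:
        class_names = sorted(p.name for p in root.iterdir() if p.is_dir())
    images, labels, prov = [], [], []
    for ci, cname in enumerate(class_names):
        cdir = root / cname
        for f in sorted(cdir.glob("*")):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            arr = np.asarray(Image.open(f).convert("L"), dtype=np.float32) / 255.0
            images.append(arr)
            labels.append(ci)
            prov.append(SYNTHETIC if "synthetic" in f.stem else REAL)
    return LabeledImageSet(images, np.array(labels, dtype=np.int64),
                           list(class_names), prov)


def save_image_folder(dataset: LabeledImageSet, root) -> None:
    """Write a class-per-folder PNG tree (8-bit grayscale)."""
    root = Path(root)
    counters = {}
    for img, lab, prov in zip(dataset.images, dataset.labels, dataset.provenance):
        cname = dataset.class_names[lab]
        cdir = root / cname
        cdir.mkdir(parents=True, exist_ok=True)
        n = counters.get((cname, prov), 0)
        counters[(cname, prov)] = n + 1
        tag = "synthetic_" if prov == SYNTHETIC else ""
        arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(cdir / f"{tag}{n:05d}.png")


def write_manifest(dataset: LabeledImageSet, root, path) -> None:
    """CSV manifest (path, label, provenance) matching save_image_folder."""
    root = Path(root)
    counters = {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "label", "provenance"])
        for lab, prov in zip(dataset.labels, dataset.provenance):
            cname = dataset.class_names[lab]
            n = counters.get((cname, prov), 0)
            counters[(cname, prov)] = n + 1
            tag = "synthetic_" if prov == SYNTHETIC else ""
            w.writerow([str(root / cname / f"{tag}{n:05d}.png"), int(lab), prov])
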