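"""Synthetic "phantom" brain-scan generator.

Each phantom is a bright elliptical rim (the skull) around textured tissue
with a dark central cavity. The cavity area grows with the class index —
a crude geometric analogue of ventricular enlargement — so a small
classifier has a genuine, resize- and contrast-robust signal to learn.
Generation is a pure function of :class:`PhantomSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import LabeledImageSet, DEFAULT_CLASS_NAMES, REAL, DatasetError


@dataclass
class PhantomSpec:
    image_size: int = 64
    n_per_class: tuple = (800, 224, 16)
    noise_sd: float = 0.05
    severity_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise DatasetError("image_size must be at least 16")
        if any(n < 1 for n in self.n_per_class):
            raise DatasetError("every class needs at least one sample")
        if self.noise_sd < 0:
            raise DatasetError("noise_sd must be nonnegative")


def _phantom_image(size: int, class_idx: int, severity_scale: float,
                   noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    y = (yy - cy) / (size / 2.0)
    x = (xx - cx) / (size / 2.0)

    # slight per-image anatomical variation
    ea = 0.90 * rng.uniform(0.98, 1.02)   # skull semi-axis (x)
    eb = 0.78 * rng.uniform(0.98, 1.02)   # skull semi-axis (y)
    r2 = (x / ea) ** 2 + (y / eb) ** 2

    img = np.zeros((size, size), dtype=np.float64)
    interior = r2 < 1.0

    # textured tissue: smoothed noise over a mid-gray base
    tex = rng.standard_normal((size, size))
    tex = ndimage.gaussian_filter(tex, sigma=size / 16.0)
    tex = tex / (tex.std() + 1e-12)
    img[interior] = 0.55 + 0.05 * tex[interior]

    # skull rim: a bright band just inside the ellipse boundary
    rim = (r2 >= 0.82) & (r2 < 1.0)
    img[rim] = 0.92

    # central cavity whose area scales with class index x severity
    base_r = 0.18
    radius = base_r * np.sqrt(1.0 + class_idx * severity_scale)
    radius *= rng.uniform(0.96, 1.04)
    ccy = rng.uniform(-0.03, 0.03)
    ccx = rng.uniform(-0.03, 0.03)
    d = np.sqrt((x - ccx) ** 2 + ((y - ccy) / 0.8) ** 2)
    cavity = 1.0 / (1.0 + np.exp((d - radius) / 0.015))   # soft edge
    img = img * (1.0 - cavity) + 0.04 * cavity

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=(size, size))
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_phantom_dataset(spec: PhantomSpec) -> LabeledImageSet:
    """Deterministically generate the phantom set described by ``spec``."""
    ss = np.random.SeedSequence(spec.seed)
    class_seeds = ss.spawn(len(spec.n_per_class))
    images, labels = [], []
    for ci, (n, cs) in enumerate(zip(spec.n_per_class, class_seeds)):
        rng = np.random.default_rng(cs)
        for _ in range(n):
            images.append(_phantom_image(spec.image_size, ci,
                                         spec.severity_scale, spec.noise_sd, rng))
            labels.append(ci)
    names = (DEFAULT_CLASS_NAMES if len(spec.n_per_class) == 3 else
             [f"class_{i}" for i in range(len(spec.n_per_class))])
    return LabeledImageSet(images, np.array(labels, dtype=np.int64),
                           list(names), [REAL] * len(images))


def mean_cavity_area(dataset: LabeledImageSet, threshold: float = 0.15) -> np.ndarray:
    """Mean per-class count of near-black interior pixels (cavity proxy)."""
    areas = np.zeros(dataset.n_classes)
    counts = np.zeros(dataset.n_classes)
    for img, lab in zip(dataset.images, dataset.labels):
        h, w = img.shape
        core = img[h // 4: 3 * h // 4, w // 4: 3 * w // 4]
        areas[lab] += (core < threshold).sum()
        counts[lab] += 1
    return areas / np.maximum(counts, 1)


def phantom_separability(dataset: LabeledImageSet, min_per_class: int = 10) -> float:
    """Leave-one-out nearest-class-centroid accuracy on 16x16 thumbnails.

    A deliberately simple non-neural probe: if this is high the phantom
    classes carry a signal any reasonable classifier can find.
    """
    counts = np.bincount(dataset.labels, minlength=dataset.n_classes)
    present = counts > 0
    if counts[present].min() < min_per_class:
        raise DatasetError(
            f"need at least {min_per_class} samples per class for the probe")
    from skimage.transform import resize
    feats = np.stack([
        resize(img, (16, 16), order=1, mode="edge", anti_aliasing=False,
               preserve_range=True).ravel()
        for img in dataset.images
    ]).astype(np.float64)
    labels = dataset.labels
    sums = np.zeros((dataset.n_classes, feats.shape[1]))
    for c in range(dataset.n_classes):
        sums[c] = feats[labels == c].sum(axis=0)
    correct = 0
    for i in range(len(feats)):
        cents = sums.copy()
        n = counts.astype(np.float64).copy()
        cents[labels[i]] -= feats[i]
        n[labels[i]] -= 1
        cents /= np.maximum(n, 1)[:, None]
        d = ((cents - feats[i]) ** 2).sum(axis=1)
        if int(np.argmin(d)) == labels[i]:
            correct += 1
    return correct / len(feats)
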