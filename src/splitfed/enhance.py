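"""Image enhancement: CLAHE local-contrast equalization and resizing.

CLAHE here follows the common OpenCV convention: per-tile 256-bin
histograms clipped at ``clip_limit`` times the uniform bin height, the
excess redistributed across bins, tile mappings blended bilinearly at each
pixel. Enhancement precedes the resize to the classifier input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .data import LabeledImageSet, DatasetError

_NBINS = 256


@dataclass
class EnhanceConfig:
    clip_limit: float = 2.0
    tile_grid: tuple = (8, 8)
    target_size: int = 224

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise DatasetError("clip_limit must be positive")
        if any(t < 1 for t in self.tile_grid):
            raise DatasetError("tile_grid entries must be >= 1")
        if self.target_size < 2:
            raise DatasetError("target_size must be >= 2")


def _tile_luts(img_q: np.ndarray, gh: int, gw: int, th: int, tw: int,
               clip_limit: float) -> np.ndarray:
    """Per-tile clipped-histogram equalization lookup tables, (gh, gw, 256)."""
    area = th * tw
    clip = max(1.0, clip_limit * area / _NBINS)
    luts = np.empty((gh, gw, _NBINS), dtype=np.float64)
    for i in range(gh):
        for j in range(gw):
            tile = img_q[i * th:(i + 1) * th, j * tw:(j + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=_NBINS).astype(np.float64)
            excess = np.maximum(hist - clip, 0.0).sum()
            hist = np.minimum(hist, clip) + excess / _NBINS
            cdf = hist.cumsum()
            # midpoint rule keeps already-equalized tiles (near) fixed points
            luts[i, j] = ((cdf - hist / 2.0) / area) * (_NBINS - 1)
    return luts


def apply_clahe(image: np.ndarray, config: EnhanceConfig) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of a [0,1] image."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise DatasetError("apply_clahe expects a 2-D grayscale image")
    h, w = image.shape
    gh, gw = config.tile_grid
    # pad by edge replication so the grid divides evenly
    th = -(-h // gh)
    tw = -(-w // gw)
    ph, pw = gh * th - h, gw * tw - w
    padded = np.pad(image, ((0, ph), (0, pw)), mode="edge")

    q = np.minimum((padded * _NBINS).astype(np.int64), _NBINS - 1)
    luts = _tile_luts(q, gh, gw, th, tw, config.clip_limit)

    # bilinear blend between the four surrounding tile mappings
    hh, ww = padded.shape
    ty = (np.arange(hh) - (th - 1) / 2.0) / th
    tx = (np.arange(ww) - (tw - 1) / 2.0) / tw
    y0 = np.clip(np.floor(ty).astype(int), 0, gh - 1)
    x0 = np.clip(np.floor(tx).astype(int), 0, gw - 1)
    y1 = np.minimum(y0 + 1, gh - 1)
    x1 = np.minimum(x0 + 1, gw - 1)
    wy = np.clip(ty - y0, 0.0, 1.0)[:, None]
    wx = np.clip(tx - x0, 0.0, 1.0)[None, :]

    b = q
    Y0 = y0[:, None]
    Y1 = y1[:, None]
    X0 = x0[None, :]
    X1 = x1[None, :]
    v00 = luts[Y0, X0, b]
    v01 = luts[Y0, X1, b]
    v10 = luts[Y1, X0, b]
    v11 = luts[Y1, X1, b]
    out = ((1 - wy) * ((1 - wx) * v00 + wx * v01)
           + wy * ((1 - wx) * v10 + wx * v11)) / (_NBINS - 1)
    return np.clip(out[:h, :w], 0.0, 1.0).astype(np.float32)


def resize_image(image: np.ndarray, target_size: int) -> np.ndarray:
    """Bilinear resize to target_size x target_size, range kept in [0,1]."""
    image = np.asarray(image)
    if image.ndim != 2 or min(image.shape) < 2:
        raise DatasetError("resize_image expects a 2-D image of size >= 2x2")
    if image.shape == (target_size, target_size):
        return image.astype(np.float32)
    out = _sk_resize(image, (target_size, target_size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def enhance_batch(dataset: LabeledImageSet, config: EnhanceConfig) -> LabeledImageSet:
    """CLAHE then resize for every image; labels and provenance untouched."""
    images = [resize_image(apply_clahe(im, config), config.target_size)
              for im in dataset.images]
    return LabeledImageSet(images, dataset.labels.copy(),
                           list(dataset.class_names),
                           list(dataset.provenance))
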