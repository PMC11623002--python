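"""CLAHE local-contrast enhancement and resizing.

Applies the enhancement stage to a low-contrast phantom and reports the
contrast gain and the resize to the classifier input size.
"""

import numpy as np

from splitfed.enhance import EnhanceConfig, apply_clahe, resize_image
from splitfed.phantom import PhantomSpec, generate_phantom_dataset

ds = generate_phantom_dataset(
    PhantomSpec(image_size=256, n_per_class=(1, 1, 1), noise_sd=0.02, seed=3))
img = (ds.images[0] * 0.3 + 0.35).astype(np.float32)   # compress contrast

cfg = EnhanceConfig(clip_limit=2.0, tile_grid=(8, 8), target_size=224)
enhanced = apply_clahe(img, cfg)
resized = resize_image(enhanced, cfg.target_size)

print(f"input:    std={img.std():.4f}  range=({img.min():.2f}, {img.max():.2f})")
print(f"CLAHE:    std={enhanced.std():.4f}  range=({enhanced.min():.2f}, {enhanced.max():.2f})")
print(f"resized:  {resized.shape}  values stay in [0, 1]")
# CLAHE raises the local contrast (larger std / wider range) without
# clipping outside [0,1]; the resize produces the 224x224 network input.
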