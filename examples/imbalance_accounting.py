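"""Imbalance accounting on the reference class counts.

Computes minority/majority imbalance ratios for the 3-class working set
(Mild 896, Moderate 64, Non 3200) and shows that a quarter subsample
preserves them.
"""

from splitfed.data import (class_distribution, compute_imbalance_ratio,
                           subsample_preserving_ratio)
from splitfed.phantom import PhantomSpec, generate_phantom_dataset

print("Imbalance ratio Mild/Non:    ", compute_imbalance_ratio(896, 3200))
print("Imbalance ratio Moderate/Non:", compute_imbalance_ratio(64, 3200))

# quarter subsample of a phantom stand-in with the same counts
ds = generate_phantom_dataset(
    PhantomSpec(image_size=32, n_per_class=(3200, 896, 64), seed=0))
quarter = subsample_preserving_ratio(ds, 0.25, seed=0)
dist = class_distribution(quarter)
print("Quarter-subsample counts:", dist.counts.tolist(),
      "ratios:", dist.ratios.round(4).tolist())
# Expected: counts [800, 224, 16]; the 0.28 and 0.02 ratios survive the
# subsample because sampling is per class with floored quotas.
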