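"""Adapted Rand error on toy instance segmentations.

A-rand = 1 - F-score of Rand precision/recall over foreground pixel
pairs; 0 means the partitions agree (up to relabeling), values near 1
mean they share almost no co-clustered pairs.  Merging two objects into
one predicted label keeps recall perfect but halves precision.
"""

import numpy as np

import emdeblur as ed

gt = np.zeros((4, 4), dtype=int)
gt[:2], gt[2:] = 1, 2  # two 8-pixel objects

perfect = gt.copy()
relabeled = np.where(gt == 1, 5, np.where(gt == 2, 3, 0))
merged = np.ones_like(gt)
split = gt.copy()
split[0] = 7  # one object split in two

for name, pred in [("perfect", perfect), ("relabeled", relabeled),
                   ("merged", merged), ("oversplit", split)]:
    print(f"{name:<10} A-rand = {ed.adapted_rand_error(pred, gt):.4f}")

print("\nRelabeling is free (A-rand is permutation invariant); merging and "
      "splitting both cost pairs.")
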