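"""Brain masking for phantom-like images.

The rule is deliberately simple and deterministic: threshold the temporal
mean at 0.25 x its 98th percentile, keep the largest connected component,
and fill holes.  That is adequate for synthetic tissue phantoms with a dark
background; it is not a general skull-stripper.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import Mask, Scan

__all__ = ["compute_brain_mask"]


def compute_brain_mask(scan: Scan, threshold_fraction: float = 0.25) -> Mask:
    """Threshold-based mask from the temporal-mean image.

    Using the temporal mean makes the result invariant to volume order.
    Raises on an all-zero image, which cannot be masked meaningfully.
    """
    mean_img = scan.retained().data.mean(axis=3)
    if not np.any(mean_img):
        raise ValueError("cannot mask empty image")
    cutoff = threshold_fraction * np.percentile(mean_img, 98)
    grid = mean_img > cutoff
    if not grid.any():
        # pathologically flat image: fall back to any nonzero voxel
        grid = mean_img > 0
    labels, n = ndimage.label(grid)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        grid = labels == (1 + int(np.argmax(sizes)))
    grid = ndimage.binary_fill_holes(grid)
    return Mask(grid)
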