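"""Binarization and morphological suppression of thin liver-border artifacts.

The raw network output is restricted to the liver and thresholded (strictly
greater than 0.5 by default). Thin false positives occurring where dark
structures such as large vessels touch the liver are then removed: the liver
mask is eroded with a 7x7 per-slice square kernel, the difference between
liver and its erosion defines a border band, and the tumor mask is filtered
within that band by a 3x3 per-slice opening. Tumor voxels in the liver
interior are never modified.

Kernels are 2D per-slice squares: the data's slices are thick (2-5 mm), so
through-plane morphology at a fixed voxel radius would act on a very
different physical scale.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import PostprocessConfig
from .volume import MaskVolume, Volume

__all__ = ["PostprocessConfig", "binarize_in_liver", "border_cleanup", "postprocess_prediction"]


def _slab(kernel: int) -> np.ndarray:
    """Per-slice square structuring element of the given odd extent."""
    return np.ones((kernel, kernel, 1), dtype=bool)


def binarize_in_liver(prob: Volume, liver: MaskVolume, threshold: float = 0.5) -> MaskVolume:
    """Voxelwise ``prob > threshold AND liver`` (strict inequality)."""
    prob.check_same_grid(liver)
    out = (prob.data > threshold) & (liver.data > 0)
    return liver.like(out.astype(np.uint8))


def border_cleanup(
    tumor: MaskVolume,
    liver: MaskVolume,
    cfg: PostprocessConfig | None = None,
) -> MaskVolume:
    """Remove thin tumor structures inside the liver border band.

    border = liver - erode(liver);  output = (tumor \\ border) | opening(tumor & border).
    The operation never adds voxels, keeps the output inside the liver
    restriction of its input, and is idempotent.
    """
    cfg = cfg or PostprocessConfig()
    tumor.check_same_grid(liver)
    liver_b = liver.data > 0
    tumor_b = tumor.data > 0
    eroded = ndimage.binary_erosion(liver_b, structure=_slab(cfg.erosion_kernel))
    border = liver_b & ~eroded
    in_border = tumor_b & border
    opened = ndimage.binary_opening(in_border, structure=_slab(cfg.opening_kernel))
    out = (tumor_b & ~border) | opened
    return tumor.like(out.astype(np.uint8))


def postprocess_prediction(
    prob: Volume,
    liver: MaskVolume,
    cfg: PostprocessConfig | None = None,
) -> MaskVolume:
    """Full post-processing: threshold within the liver, then border cleanup."""
    cfg = cfg or PostprocessConfig()
    return border_cleanup(binarize_in_liver(prob, liver, cfg.threshold), liver, cfg)
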