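"""On-the-fly patch augmentation: axis flips and gray-value transforms.

Three transforms are applied when a training patch is served, each drawn
fresh per patch: flipping along every image axis with 50 % probability per
axis (applied identically to image, label and weight patches), a linear
rescaling of the voxel-value distance from the patch mean by a factor
``a ~ U[0.75, 1.25)`` (contrast), and a shift of the mean by
``b ~ N(0, 0.25)``. Intensity transforms touch only the image:

    v' = m + a * (v - m) + b          with m the image-patch mean.

The "gray value mean" is the per-patch mean, the only scope available at
augmentation time.
"""

from __future__ import annotations

import numpy as np

from .config import AugmentConfig

__all__ = ["AugmentConfig", "augment_patch"]


def augment_patch(
    image: np.ndarray,
    label: np.ndarray,
    weight: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply one fresh draw of the three augmentation transforms.

    All three patches must share one shape. The label patch stays binary and
    the weight patch is never intensity-transformed. Draw order (flips per
    axis, then contrast, then shift) is fixed, so a seeded generator yields a
    reproducible augmentation stream.
    """
    if not (image.shape == label.shape == weight.shape):
        raise ValueError(
            f"patch shape mismatch: {image.shape}, {label.shape}, {weight.shape}")

    flip_axes = tuple(ax for ax in range(image.ndim)
                      if rng.random() < cfg.flip_prob)
    a = rng.uniform(cfg.contrast_low, cfg.contrast_high)
    b = rng.normal(0.0, cfg.shift_std) if cfg.shift_std > 0 else 0.0

    if flip_axes:
        image = np.flip(image, axis=flip_axes)
        label = np.flip(label, axis=flip_axes)
        weight = np.flip(weight, axis=flip_axes)

    m = image.mean()
    # algebraically m + a*(v - m) + b; this form is exact for a=1, b=0
    image = image + (a - 1.0) * (image - m) + b
    return image, label, weight
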