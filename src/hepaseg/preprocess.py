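"""In-plane resampling to a common resolution and percentile normalization.

The image grid is resampled in-plane (default to 1 mm) while the slice axis
is left untouched, to avoid through-plane interpolation artifacts on small
lesions with thick slices. Gray values are normalized per case by linearly
mapping two percentiles of the intensity distribution inside the liver mask
(defaults: 2nd and 98th) to 0 and 1, without clipping values outside that
interval. MRI gray values carry no absolute scale, so this affine
normalization removes the arbitrary per-case scale and offset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import MaskVolume, Volume


@dataclass
class NormalizationParams:
    """Fitted percentile gray values measured within the liver mask."""

    low_rank: float
    high_rank: float
    low_value: float
    high_value: float

    def __post_init__(self) -> None:
        if not 0 < self.low_rank < self.high_rank < 100:
            raise ValueError("ranks must satisfy 0 < low < high < 100")
        if not self.high_value > self.low_value:
            raise ValueError("degenerate normalization: high percentile == low percentile")


def _round_half_up(x: np.ndarray | float) -> np.ndarray:
    return np.floor(np.asarray(x) + 0.5).astype(int)


def resample_inplane(
    v: Volume,
    target_mm: float = 1.0,
    masks: list[MaskVolume] | None = None,
) -> tuple[Volume, list[MaskVolume]]:
    """Resample the first two axes to ``target_mm``; the slice axis is untouched.

    The output grid keeps the world origin; the new in-plane shape is
    ``round(old_shape * old_spacing / target)`` (round half up). The image is
    interpolated linearly, masks by nearest neighbor so they stay binary.
    If the volume already has the target in-plane spacing, data pass through
    unchanged.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    masks = list(masks) if masks is not None else []
    for m in masks:
        v.check_same_grid(m)

    sx, sy, sz = v.spacing
    new_spacing = (float(target_mm), float(target_mm), sz)
    if abs(sx - target_mm) < 1e-12 and abs(sy - target_mm) < 1e-12:
        return v, masks

    nx = int(_round_half_up(v.shape[0] * sx / target_mm))
    ny = int(_round_half_up(v.shape[1] * sy / target_mm))
    nz = v.shape[2]
    # Voxel-centered mapping: new index j lies at world j*target, i.e. at old
    # index j*target/old_spacing.
    cx = np.arange(nx) * (target_mm / sx)
    cy = np.arange(ny) * (target_mm / sy)
    cz = np.arange(nz, dtype=float)
    grid = np.meshgrid(cx, cy, cz, indexing="ij")
    coords = np.stack(grid)

    data = ndimage.map_coordinates(
        v.data.astype(np.float32), coords, order=1, mode="nearest")
    out_v = Volume(data, new_spacing, v.origin)
    out_masks = []
    for m in masks:
        md = ndimage.map_coordinates(m.data, coords, order=0, mode="nearest")
        out_masks.append(MaskVolume(md, new_spacing, m.origin))
    return out_v, out_masks


def fit_normalization(
    v: Volume,
    liver: MaskVolume,
    low_rank: float = 2.0,
    high_rank: float = 98.0,
) -> NormalizationParams:
    """Measure the normalization percentiles inside the liver mask.

    Percentiles use linear interpolation between order statistics (numpy's
    default definition). Raises on an empty liver mask or when both
    percentiles coincide (a constant liver region cannot be normalized).
    """
    v.check_same_grid(liver)
    values = v.data[liver.data > 0]
    if values.size == 0:
        raise ValueError("empty liver mask: cannot fit normalization")
    low, high = np.percentile(values, [low_rank, high_rank])
    if not high > low:
        raise ValueError("degenerate gray-value distribution inside the liver")
    return NormalizationParams(low_rank, high_rank, float(low), float(high))


def apply_normalization(v: Volume, p: NormalizationParams) -> Volume:
    """Map ``p.low_value`` to 0 and ``p.high_value`` to 1 on the whole volume.

    The map is affine and applied everywhere (the network also sees non-liver
    context); values outside the percentile interval are NOT clipped and map
    below 0 / above 1.
    """
    data = (v.data.astype(np.float64) - p.low_value) / (p.high_value - p.low_value)
    return Volume(data, v.spacing, v.origin)


def preprocess_case(
    v: Volume,
    liver: MaskVolume,
    lesions: list[MaskVolume],
    target_mm: float = 1.0,
    low_rank: float = 2.0,
    high_rank: float = 98.0,
) -> tuple[Volume, MaskVolume, list[MaskVolume], NormalizationParams]:
    """Resample in-plane, then fit and apply normalization on the new grid."""
    out_v, out_masks = resample_inplane(v, target_mm, [liver] + list(lesions))
    out_liver, out_lesions = out_masks[0], out_masks[1:]
    params = fit_normalization(out_v, out_liver, low_rank, high_rank)
    return apply_normalization(out_v, params), out_liver, out_lesions, params
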