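"""Core in-memory containers for volumetric images and binary masks.

Arrays are indexed ``(x, y, z)``: the first two axes are in-plane, the third
runs across slices. Voxels are point samples on a voxel-centered grid, so the
world position of index ``(i, j, k)`` is ``origin + index * spacing``.
Spacing is given per axis in millimetres and is allowed to be anisotropic
(late-phase liver MRI typically has 0.74-1.76 mm in-plane and 2-5 mm between
slices).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Absolute tolerance (mm) for deciding that two grids coincide.
GRID_ATOL = 1e-6


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and world origin.

    Parameters
    ----------
    data
        3D array of finite scalar values, indexed (x, y, z).
    spacing
        Per-axis voxel edge length in mm; all components positive.
    origin
        World coordinates (mm) of the voxel with index (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got {self.data.ndim} axes")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have three components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "Volume | MaskVolume", atol: float = GRID_ATOL) -> bool:
        """True if *other* lives on an identical grid (shape, spacing, origin)."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol, rtol=0.0)
            and np.allclose(self.origin, other.origin, atol=atol, rtol=0.0)
        )

    def check_same_grid(self, other: "Volume | MaskVolume") -> None:
        if not self.same_grid(other):
            raise ValueError(
                "grid mismatch: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )


@dataclass
class MaskVolume(Volume):
    """A binary mask sharing the grid of a :class:`Volume`.

    Values are restricted to {0, 1} and stored as ``uint8``. The same type is
    used for liver masks, lesion reference masks (one per rater), and binarized
    predictions; the role is contextual.
    """

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0, 1}}, found {vals[:10]}")
        self.data = arr.astype(np.uint8, copy=False)
        super().__post_init__()

    @property
    def num_voxels(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def like(self, data: np.ndarray) -> "MaskVolume":
        """New mask with the same grid and the given data."""
        return MaskVolume(data=data, spacing=self.spacing, origin=self.origin)
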