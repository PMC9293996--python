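"""Synthetic late-phase liver phantoms with ground truth and simulated raters.

The generator emulates the salient properties of late hepatocellular phase
DCE-MRI for testing purposes: anisotropic voxels (sub-millimetre to ~1.8 mm
in-plane, thick 2-5 mm slices), bright liver parenchyma after hepatocyte
specific contrast uptake, hypointense (dark) lesions of varying size and
count, an arbitrary global gray-value scale and offset per case (MRI
intensities are not standardized), and several slightly disagreeing
reference masks per case, mimicking independent human raters.

It does not attempt MRI physics: no bias fields, no motion, no vessel trees,
no partial-volume modelling beyond grid discretisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import MaskVolume, Volume

log = logging.getLogger("hepaseg")

#: 6-neighborhood (face connectivity); the package-wide convention for what
#: constitutes one lesion.
STRUCT_6 = ndimage.generate_binary_structure(3, 1)

_PLACEMENT_RETRIES = 1000


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    Defaults model a mid-range scanner protocol: 1.2 mm in-plane resolution
    (clinical protocols span 0.74-1.76 mm), 3 mm slices (range 2-5 mm), three
    lesions of 4-10 mm radius, lesions at 45 % of parenchyma intensity, and
    moderate additive noise.
    """

    shape: tuple[int, int, int] = (96, 96, 28)
    in_plane_mm: float = 1.2
    slice_mm: float = 3.0
    n_lesions: int = 3
    lesion_radius_mm: tuple[float, float] = (4.0, 10.0)
    parenchyma_mean: float = 400.0
    lesion_fraction: float = 0.45       # lesion intensity / parenchyma intensity
    noise_std: float = 20.0
    intensity_scale: float = 1.0        # global affine distortion emulating
    intensity_offset: float = 0.0       # non-standardized gray values
    rater_magnitude_mm: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_radius_mm
        if not 0 < lo <= hi:
            raise ValueError("lesion radius range must satisfy 0 < low <= high")
        if lo <= max(self.in_plane_mm, self.slice_mm):
            raise ValueError(
                "smallest lesion radius must exceed the largest spacing component "
                "so lesions span at least one voxel in every axis")
        if not 0.0 < self.lesion_fraction < 1.0:
            raise ValueError("lesion_fraction must be in (0, 1): lesions are hypointense")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.in_plane_mm, self.in_plane_mm, self.slice_mm)


def _world_grid(shape, spacing):
    axes = [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _liver_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Large smooth blob: an ellipsoid with low-frequency boundary perturbation."""
    gx, gy, gz = _world_grid(spec.shape, spec.spacing)
    extent = [n * s for n, s in zip(spec.shape, spec.spacing)]
    center = [0.5 * e for e in extent]
    semi = [0.38 * e for e in extent]
    q = (((gx - center[0]) / semi[0]) ** 2
         + ((gy - center[1]) / semi[1]) ** 2
         + ((gz - center[2]) / semi[2]) ** 2)
    # Smooth radial perturbation from upsampled coarse noise, ~15 % of radius.
    coarse = rng.standard_normal((4, 4, 3))
    pert = ndimage.zoom(coarse, [n / c for n, c in zip(spec.shape, coarse.shape)], order=3)
    pert = pert[: spec.shape[0], : spec.shape[1], : spec.shape[2]]
    pert /= max(np.abs(pert).max(), 1e-9)
    return q <= 1.0 + 0.3 * pert


def _ellipsoid_mask(shape, spacing, center_vox, radii_mm) -> np.ndarray:
    gx, gy, gz = _world_grid(shape, spacing)
    cx, cy, cz = (c * s for c, s in zip(center_vox, spacing))
    q = (((gx - cx) / radii_mm[0]) ** 2
         + ((gy - cy) / radii_mm[1]) ** 2
         + ((gz - cz) / radii_mm[2]) ** 2)
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, MaskVolume, MaskVolume]:
    """Generate one phantom case: (image, liver mask, lesion mask).

    Lesions are ellipsoids placed by rejection sampling, fully inside the
    liver, pairwise disjoint (with a one-voxel separation so they remain
    distinct connected components under face connectivity), and darker than
    parenchyma. Identical specs (including seed) produce bit-identical
    output.

    Raises ``RuntimeError`` if a lesion cannot be placed within the retry cap.
    """
    rng = np.random.default_rng(spec.seed)
    liver = _liver_mask(spec, rng)
    if not liver.any():
        raise RuntimeError("degenerate spec: empty liver mask")

    # Lesions must fit inside the liver; sample centers from an eroded core.
    lesions = np.zeros(spec.shape, dtype=bool)
    occupied = np.zeros(spec.shape, dtype=bool)   # lesions + 1-voxel separation
    core = ndimage.binary_erosion(liver, structure=STRUCT_6, iterations=2)
    core_idx = np.argwhere(core)
    for i in range(spec.n_lesions):
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            center = core_idx[rng.integers(len(core_idx))]
            radii = rng.uniform(*spec.lesion_radius_mm, size=3)
            m = _ellipsoid_mask(spec.shape, spec.spacing, center, radii)
            if not m.any():
                continue
            if (m & ~liver).any():
                continue
            if (m & occupied).any():
                continue
            lesions |= m
            occupied |= ndimage.binary_dilation(m, structure=STRUCT_6)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place lesion {i + 1}/{spec.n_lesions} disjointly "
                f"within {_PLACEMENT_RETRIES} retries")

    image = np.full(spec.shape, 0.15 * spec.parenchyma_mean, dtype=np.float64)
    image[liver] = spec.parenchyma_mean
    image[lesions] = spec.lesion_fraction * spec.parenchyma_mean
    image += rng.normal(0.0, spec.noise_std, size=spec.shape)
    image = spec.intensity_scale * image + spec.intensity_offset

    vol = Volume(image, spec.spacing)
    return (
        vol,
        MaskVolume(liver.astype(np.uint8), spec.spacing),
        MaskVolume(lesions.astype(np.uint8), spec.spacing),
    )


def simulate_raters(
    lesions: MaskVolume,
    n_raters: int,
    magnitude_mm: float,
    seed: int,
    drop_prob: float = 0.1,
    drop_volume_mm3: float = 150.0,
) -> list[MaskVolume]:
    """Simulate independent human raters by perturbing the lesion mask.

    Each rater variant perturbs every lesion component independently: a
    signed radius drawn uniformly from [-magnitude, +magnitude] mm dilates
    (positive) or erodes (negative) the component, with the mm radius
    converted to per-axis voxel radii so anisotropic grids perturb plausibly.
    Lesions smaller than ``drop_volume_mm3`` are additionally dropped with
    probability ``drop_prob`` (a rater overlooking a small lesion). Variants
    are clipped to nothing outside the image and are deterministic per seed.

    With ``magnitude_mm == 0`` and ``drop_prob == 0`` every variant equals
    the input.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(lesions.spacing)
    voxel_mm3 = float(np.prod(spacing))
    labels, n_comp = ndimage.label(lesions.data, structure=STRUCT_6)
    out: list[MaskVolume] = []
    for _ in range(n_raters):
        variant = np.zeros_like(lesions.data, dtype=bool)
        for comp in range(1, n_comp + 1):
            m = labels == comp
            if (drop_prob > 0 and m.sum() * voxel_mm3 < drop_volume_mm3
                    and rng.random() < drop_prob):
                continue
            r = rng.uniform(-magnitude_mm, magnitude_mm) if magnitude_mm > 0 else 0.0
            radii_vox = np.rint(abs(r) / spacing).astype(int)
            if radii_vox.any():
                footprint = _ellipsoid_footprint(radii_vox)
                if r > 0:
                    m = ndimage.binary_dilation(m, structure=footprint)
                else:
                    m = ndimage.binary_erosion(m, structure=footprint)
            variant |= m
        out.append(lesions.like(variant.astype(np.uint8)))
    return out


def _ellipsoid_footprint(radii_vox: np.ndarray) -> np.ndarray:
    """Ellipsoidal structuring element with the given per-axis voxel radii."""
    r = np.maximum(radii_vox, 0)
    grids = np.meshgrid(*[np.arange(-ri, ri + 1) for ri in r], indexing="ij")
    q = sum((g / max(ri, 1)) ** 2 for g, ri in zip(grids, r))
    return q <= 1.0
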