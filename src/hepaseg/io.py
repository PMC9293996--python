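"""NIfTI reading and writing for volumes and masks.

Volumes are stored with a diagonal affine built from spacing and origin;
oblique orientations are out of scope (phantoms and the supported clinical
exports are axis-aligned). Masks are written as unsigned 8-bit so that a
round trip is bit exact.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .volume import MaskVolume, Volume


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3D NIfTI file (.nii / .nii.gz) as a :class:`Volume`.

    Spacing is taken from the header zooms, the origin from the affine
    translation. Raises for missing files, non-3D images and non-finite data.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.ndim} axes")
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return Volume(data=data, spacing=spacing, origin=origin)


def read_mask(path: str | os.PathLike) -> MaskVolume:
    """Read a binary mask; values must be {0, 1}."""
    v = read_volume(path)
    return MaskVolume(data=v.data, spacing=v.spacing, origin=v.origin)


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume (or mask) to NIfTI with spacing in the header.

    Masks are written as uint8, scalar volumes as float32 (or their integer
    dtype if already integral).
    """
    path = os.fspath(path)
    data = v.data
    if isinstance(v, MaskVolume):
        data = data.astype(np.uint8)
    elif not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, path)


def case_paths(case_dir: str | os.PathLike) -> dict[str, str]:
    """Standard file layout of one case directory."""
    d = os.fspath(case_dir)
    return {
        "image": os.path.join(d, "image.nii.gz"),
        "liver": os.path.join(d, "liver.nii.gz"),
        "lesions": os.path.join(d, "lesions.nii.gz"),
    }
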