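"""Binary ROI masks on a voxel grid and the set/morphology algebra used to
build region-of-interest definitions.

A :class:`Mask` is a 3D boolean field together with a voxel-to-world affine.
All pairwise operations require identical grids; morphological erosion treats
everything outside the grid as background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Mask",
    "mask_union",
    "mask_overlap",
    "erode_mask",
    "subsample_mask",
    "split_mask_lr",
    "resample_mask",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class Mask:
    """3D boolean field with a voxel->world (mm) affine.

    The fixed voxel ordering used for pattern vectors is C-order over
    ``np.nonzero(data)``; every sample extracted with this mask shares it.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        data = np.asarray(self.data, dtype=bool)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got shape {data.shape}")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def indices(self) -> tuple[np.ndarray, ...]:
        """Voxel indices of true voxels, in the canonical C-order."""
        return np.nonzero(self.data)

    def world_coords(self) -> np.ndarray:
        """(n, 3) world-mm coordinates of true voxel centers."""
        ijk = np.column_stack(self.indices())
        hom = np.column_stack([ijk, np.ones(len(ijk))])
        return (hom @ self.affine.T)[:, :3]

    def issubset(self, other: "Mask") -> bool:
        _check_same_grid(self, other)
        return bool(np.all(~self.data | other.data))

    # -- NIfTI round trip ---------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    @classmethod
    def from_nifti(cls, img) -> "Mask":
        if isinstance(img, (str, bytes)) or hasattr(img, "__fspath__"):
            img = nib.load(img)
        return cls(np.asanyarray(img.dataobj) > 0, img.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


def _check_same_grid(a: Mask, b: Mask) -> None:
    if a.grid_shape != b.grid_shape or not np.allclose(a.affine, b.affine):
        raise ValueError("masks are defined on different grids")


def mask_union(a: Mask, b: Mask) -> Mask:
    """Voxelwise OR of two masks on the same grid."""
    _check_same_grid(a, b)
    return Mask(a.data | b.data, a.affine)


def mask_overlap(a: Mask, b: Mask) -> Mask:
    """Voxelwise AND of two masks on the same grid."""
    _check_same_grid(a, b)
    return Mask(a.data & b.data, a.affine)


def erode_mask(mask: Mask, layers: int, connectivity: int = 6) -> Mask:
    """Iterated morphological erosion.

    ``layers=0`` is the identity. Voxels outside the grid count as
    background, so the mask also erodes inward from the grid boundary.
    ``connectivity`` selects the neighborhood: 6 (faces), 18 (faces+edges)
    or 26 (full 3x3x3 box, FSL's default kernel).
    """
    if layers < 0:
        raise ValueError("layers must be >= 0")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    if layers == 0:
        return mask
    out = ndimage.binary_erosion(
        mask.data, structure=_STRUCTURES[connectivity], iterations=layers,
        border_value=0,
    )
    return Mask(out, mask.affine)


def subsample_mask(mask: Mask, n_target: int, seed: int) -> Mask:
    """Keep exactly ``n_target`` true voxels, chosen uniformly without
    replacement; reproducible for a given seed."""
    n = mask.voxel_count
    if n_target > n:
        raise ValueError(f"n_target={n_target} exceeds voxel_count={n}")
    if n_target == n:
        return mask
    rng = np.random.default_rng(seed)
    keep = rng.choice(n, size=n_target, replace=False)
    flat_idx = np.flatnonzero(mask.data.ravel())[np.sort(keep)]
    out = np.zeros(mask.data.size, dtype=bool)
    out[flat_idx] = True
    return Mask(out.reshape(mask.grid_shape), mask.affine)


def split_mask_lr(mask: Mask) -> dict[str, Mask]:
    """Partition a mask by the world x coordinate of each voxel center:
    x <= 0 goes left, x > 0 goes right."""
    i, j, k = np.indices(mask.grid_shape)
    a = mask.affine
    world_x = a[0, 0] * i + a[0, 1] * j + a[0, 2] * k + a[0, 3]
    left = Mask(mask.data & (world_x <= 0), mask.affine)
    right = Mask(mask.data & (world_x > 0), mask.affine)
    return {"left": left, "right": right}


def resample_mask(mask: Mask, target_voxel_size: float | tuple) -> Mask:
    """Nearest-neighbor resampling onto a grid with the requested voxel size.

    The target grid keeps the source orientation and corner origin and covers
    the source's world footprint (to within one voxel). Assumes an
    axis-aligned affine (diagonal rotation part up to sign), which holds for
    all grids produced in this package.
    """
    vox = np.atleast_1d(np.asarray(target_voxel_size, dtype=float))
    if vox.size == 1:
        vox = np.repeat(vox, 3)
    if np.any(vox <= 0):
        raise ValueError("target voxel size must be positive")
    rot = mask.affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0):
        raise ValueError("resample_mask requires an axis-aligned affine")
    src_vox = np.diag(rot)
    if np.allclose(np.abs(src_vox), vox):
        return mask
    shape = np.asarray(mask.grid_shape)
    # physical extent along each axis (mm), preserving direction signs
    new_shape = np.maximum(1, np.ceil(shape * np.abs(src_vox) / vox).astype(int))
    new_rot = np.diag(np.sign(src_vox) * vox)
    # keep the world position of the corner voxel-center edge:
    # source voxel centers are at origin + i*src_vox; align the target so its
    # voxel 0 center sits at the same corner offset scaled to the new size.
    origin = mask.affine[:3, 3] + (np.sign(src_vox) * (vox - np.abs(src_vox)) / 2.0)
    new_affine = np.eye(4)
    new_affine[:3, :3] = new_rot
    new_affine[:3, 3] = origin

    # map each target voxel center back into source voxel coordinates
    inv = np.linalg.inv(mask.affine)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in new_shape], indexing="ij")
    hom = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4)
    world = hom @ new_affine.T
    src_ijk = np.rint(world @ inv.T)[:, :3].astype(int)
    inside = np.all((src_ijk >= 0) & (src_ijk < shape), axis=1)
    out = np.zeros(np.prod(new_shape), dtype=bool)
    sel = src_ijk[inside]
    out[inside] = mask.data[sel[:, 0], sel[:, 1], sel[:, 2]]
    return Mask(out.reshape(tuple(new_shape)), new_affine)
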