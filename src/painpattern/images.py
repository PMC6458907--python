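"""4D volume series container with NIfTI round trip."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeSeries"]


@dataclass
class VolumeSeries:
    """A subject/run 4D BOLD series: ``data[x, y, z, t]`` with repetition
    time ``tr`` (seconds) and a voxel->world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tr: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"series must be 4D, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr))
        return img

    @classmethod
    def from_nifti(cls, img, tr: float | None = None) -> "VolumeSeries":
        if isinstance(img, (str, bytes)) or hasattr(img, "__fspath__"):
            img = nib.load(img)
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        return cls(np.asanyarray(img.dataobj), img.affine, tr)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))
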