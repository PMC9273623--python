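"""Minimal volumetric image container.

All computation in this package happens in voxel space; NIfTI affines are
carried through untouched so outputs can be overlaid on the inputs they came
from. Intensities are stored as float64 regardless of on-disk dtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VoxelImage"]


@dataclass
class VoxelImage:
    """A 3D grid of non-negative intensities plus geometry metadata.

    Parameters
    ----------
    data
        3D float array of intensities.
    affine
        4x4 voxel-to-world matrix (NIfTI convention).
    voxel_size_mm
        Isotropic voxel edge length in millimetres. Used to convert smoothing
        kernel widths from mm to voxels.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def scaled(self, factor: float) -> "VoxelImage":
        """Return a copy with all intensities multiplied by ``factor``."""
        return VoxelImage(self.data * factor, self.affine.copy(), self.voxel_size_mm)

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VoxelImage":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
        return cls(data=data, affine=np.asarray(img.affine), voxel_size_mm=float(zooms[0]))

    def to_nifti(self, path: str | Path) -> None:
        out = nib.Nifti1Image(self.data.astype(np.float64), self.affine)
        out.header.set_zooms((self.voxel_size_mm,) * 3)
        nib.save(out, str(path))
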