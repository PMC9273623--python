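"""Scaled-subprofile-model preprocessing: masking, log transform, double centering.

The SSM removes two nuisance terms from log-intensity data before PCA:
each subject's own mean log intensity (a proxy for global metabolic
activity — multiplicative scanner/dose effects become additive offsets after
the log and vanish under row centering) and the cohort's group mean profile
(GMP, the voxel-wise mean of row-centred log profiles). What remains is the
subject residual profile (SRP) matrix on which covariance patterns are
estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .image import VoxelImage

__all__ = [
    "AnalysisMask",
    "LogProfileMatrix",
    "SrpMatrix",
    "build_mask",
    "to_log_profiles",
    "double_center",
]


@dataclass
class AnalysisMask:
    """Boolean voxel-inclusion map for the SSM analysis.

    Masked voxel values are always extracted in a fixed lexicographic order
    with the x index varying fastest (Fortran raveling of the 3D grid), so
    flat vectors are portable across runs and serialized bundles.
    """

    data: np.ndarray
    threshold_fraction: float
    _flat_indices: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self._flat_indices = np.flatnonzero(self.data.ravel(order="F"))
        if self.n_voxels < 2:
            raise ValueError("mask must contain at least 2 voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Masked values of ``volume`` in the canonical (x-fastest) order."""
        if volume.shape != self.data.shape:
            raise ValueError(f"volume shape {volume.shape} != mask shape {self.data.shape}")
        return volume.ravel(order="F")[self._flat_indices]

    def insert(self, values: np.ndarray) -> np.ndarray:
        """Scatter a flat masked vector back into a 3D volume (zeros outside)."""
        if values.shape != (self.n_voxels,):
            raise ValueError("values length does not match mask voxel count")
        flat = np.zeros(int(np.prod(self.data.shape)), dtype=np.float64)
        flat[self._flat_indices] = values
        return flat.reshape(self.data.shape, order="F")


@dataclass
class LogProfileMatrix:
    """Subjects x masked-voxels natural-log intensities.

    ``subject_global_mean`` is each row's mean — the SSM proxy for global
    metabolic activity.
    """

    matrix: np.ndarray
    subject_ids: list[str]
    mask: AnalysisMask

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("log-profile matrix must be 2D")
        if self.matrix.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match number of subjects")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("log-profile matrix contains non-finite entries")

    @property
    def subject_global_mean(self) -> np.ndarray:
        return self.matrix.mean(axis=1)


@dataclass
class SrpMatrix:
    """Doubly centred subject residual profiles plus the removed GMP."""

    matrix: np.ndarray
    gmp: np.ndarray
    subject_ids: list[str]
    mask: AnalysisMask

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.gmp = np.asarray(self.gmp, dtype=np.float64)
        if self.matrix.shape[1] != self.gmp.shape[0]:
            raise ValueError("gmp length does not match voxel count")


def build_mask(images: Sequence[VoxelImage], threshold_fraction: float = 0.2) -> AnalysisMask:
    """Intersection threshold mask: a voxel is kept iff its intensity exceeds
    ``threshold_fraction`` of that image's maximum in *every* image.

    This is the conventional whole-brain masking for PET covariance analysis;
    the per-image (rather than global) maximum makes the rule invariant to
    each subject's global scaling.
    """
    if not images:
        raise ValueError("need at least one image to build a mask")
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    mask = np.ones(images[0].shape, dtype=bool)
    for img in images:
        if img.shape != images[0].shape:
            raise ValueError("all images must share one grid")
        mask &= img.data > threshold_fraction * img.data.max()
    if mask.sum() < 2:
        raise ValueError("mask empty; lower threshold")
    return AnalysisMask(mask, threshold_fraction)


def to_log_profiles(
    images: Sequence[VoxelImage],
    mask: AnalysisMask,
    subject_ids: Sequence[str] | None = None,
) -> LogProfileMatrix:
    """Extract masked intensities and take the natural log, one row per subject."""
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(len(images))]
    if len(subject_ids) != len(images):
        raise ValueError("subject_ids length does not match images")
    rows = np.empty((len(images), mask.n_voxels), dtype=np.float64)
    for i, img in enumerate(images):
        vals = mask.extract(img.data)
        bad = int(np.sum(vals <= 0))
        if bad:
            raise ValueError(
                f"subject {subject_ids[i]!r}: {bad} masked voxel(s) have non-positive "
                "intensity; cannot log-transform"
            )
        rows[i] = np.log(vals)
    return LogProfileMatrix(rows, list(subject_ids), mask)


def double_center(profiles: LogProfileMatrix) -> SrpMatrix:
    """Remove each subject's mean log intensity, then the group mean profile.

    SRP[i, v] = L[i, v] - rowmean_i - gmp[v], with gmp the column mean of the
    row-centred matrix. The stored GMP is reused verbatim when scoring scans
    outside the derivation cohort, so row centering is defined to happen
    first.
    """
    if profiles.matrix.shape[0] < 2:
        raise ValueError("double centering needs at least 2 subjects")
    row_centered = profiles.matrix - profiles.matrix.mean(axis=1, keepdims=True)
    gmp = row_centered.mean(axis=0)
    srp = row_centered - gmp
    return SrpMatrix(srp, gmp, profiles.subject_ids, profiles.mask)
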