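"""Synthetic FDG-PET phantom cohorts with a planted covariance pattern.

The generator produces two-group cohorts (patients / controls) of smoothed,
positive-valued brain-like volumes that satisfy the scaled-subprofile-model
assumptions: each subject's scan is a positive baseline activity field scaled
by a subject-specific multiplicative global factor, modulated log-additively
by a shared spatial pattern whose subject-level expression differs between
groups, plus voxel-wise log-normal noise. An MMSE-like integer cognition
score is generated to correlate negatively with pattern expression.

Because the generative model plants a known ground-truth pattern and known
per-subject expressions, every downstream stage (preprocessing, PCA pattern
derivation, expression scoring, bootstrap reliability, cross-validation) can
be tested quantitatively without access to clinical scans.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image import VoxelImage

__all__ = [
    "Blob",
    "BaselineSpec",
    "ClinicalSpec",
    "PhantomConfig",
    "PlantedTruth",
    "default_config",
    "ellipsoid_mask",
    "make_pattern_template",
    "simulate_cohort",
    "write_cohort",
]

# FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Blob:
    """One focal region of the planted pattern.

    ``sign`` is -1 for a relatively hypometabolic region and +1 for a
    relatively hypermetabolic one; ``amplitude`` scales the Gaussian bump
    before the whole template is centred and normalised.
    """

    center: tuple[float, float, float]
    radius: float
    sign: int
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("blob radius must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("blob sign must be -1 or +1")
        if self.amplitude <= 0:
            raise ValueError("blob amplitude must be positive")


@dataclass(frozen=True)
class BaselineSpec:
    """Smooth positive baseline activity: constant level plus a low-frequency
    cosine ripple so that intensity-threshold masking is non-degenerate."""

    level: float = 100.0
    ripple_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.level * (1.0 - abs(self.ripple_frac)) <= 0:
            raise ValueError("baseline must be strictly positive")


@dataclass(frozen=True)
class ClinicalSpec:
    """Linear map from pattern expression to an MMSE-like integer score:
    score = clip(round(intercept - slope * expression + noise), floor, ceiling).
    """

    intercept: float = 28.7
    slope: float = 5.35
    noise_sd: float = 1.1
    floor: int = 0
    ceiling: int = 30

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("clinical noise_sd must be >= 0")
        if self.floor >= self.ceiling:
            raise ValueError("clinical floor must be < ceiling")


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (32, 40, 32)
    voxel_size_mm: float = 2.0
    mask_semiaxes: tuple[float, float, float] = (14.0, 18.0, 14.0)
    baseline: BaselineSpec = field(default_factory=BaselineSpec)
    blobs: tuple[Blob, ...] = ()
    n_per_group: int = 20
    effect_delta: float = 2.0
    expr_sd: float = 0.5
    global_sd: float = 0.15
    noise_sd: float = 0.1
    smooth_fwhm_mm: float = 10.0
    clinical: ClinicalSpec = field(default_factory=ClinicalSpec)
    control_label: str = "NC"
    patient_label: str = "AD"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive integers")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if any(a <= 0 for a in self.mask_semiaxes):
            raise ValueError("mask semi-axes must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("expr_sd", "global_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth of one simulated cohort.

    ``pattern_map`` is zero outside the brain mask and has zero mean and unit
    Euclidean norm over the mask. Per-subject arrays are aligned with the
    manifest rows (controls first, then patients).
    """

    pattern_map: np.ndarray
    brain_mask: np.ndarray
    expression: np.ndarray
    global_factor: np.ndarray
    clinical_score: np.ndarray

    def __post_init__(self) -> None:
        vals = self.pattern_map[self.brain_mask]
        if abs(vals.mean()) > 1e-10 or abs(np.linalg.norm(vals) - 1.0) > 1e-10:
            raise ValueError("pattern_map must be zero-mean, unit-norm over the mask")
        if np.any(self.global_factor <= 0):
            raise ValueError("global factors must be positive")


def default_config(**overrides) -> PhantomConfig:
    """The reference phantom: a 32x40x32 ellipsoidal 'brain' with bilateral
    temporoparietal, posterior midline and thalamic hypometabolic blobs
    co-varying with a hypermetabolic cerebellar blob."""
    blobs = (
        Blob(center=(7.0, 27.0, 17.0), radius=3.5, sign=-1, amplitude=1.0),
        Blob(center=(24.0, 27.0, 17.0), radius=3.5, sign=-1, amplitude=1.0),
        Blob(center=(15.5, 29.0, 13.0), radius=3.0, sign=-1, amplitude=0.8),
        Blob(center=(15.5, 19.0, 15.0), radius=2.5, sign=-1, amplitude=0.6),
        Blob(center=(15.5, 8.0, 9.0), radius=4.0, sign=+1, amplitude=1.0),
    )
    return dataclasses.replace(PhantomConfig(blobs=blobs), **overrides)


def ellipsoid_mask(config: PhantomConfig) -> np.ndarray:
    """Boolean brain mask: an axis-aligned ellipsoid centred on the grid."""
    nx, ny, nz = config.grid_shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ax, ay, az = config.mask_semiaxes
    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    r2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    return r2 <= 1.0


def _blob_field(config: PhantomConfig) -> np.ndarray:
    """Raw (uncentred) sum of truncated Gaussian bumps, evaluated everywhere."""
    nx, ny, nz = config.grid_shape
    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    out = np.zeros(config.grid_shape, dtype=np.float64)
    for blob in config.blobs:
        bx, by, bz = blob.center
        d2 = (x - bx) ** 2.0 + (y - by) ** 2.0 + (z - bz) ** 2.0
        bump = blob.sign * blob.amplitude * np.exp(-d2 / (2.0 * blob.radius**2))
        # truncated at 3 radii: compact support keeps blobs localisable
        bump = np.where(d2 <= (3.0 * blob.radius) ** 2, bump, 0.0)
        out += bump
    return out


def make_pattern_template(config: PhantomConfig) -> np.ndarray:
    """Build the planted pattern map: blobs inside the brain mask, centred to
    zero mean and scaled to unit Euclidean norm over the mask, zero outside.

    Raises
    ------
    ValueError
        If every blob falls outside the mask ("empty pattern").
    """
    mask = ellipsoid_mask(config)
    raw = _blob_field(config)
    raw[~mask] = 0.0
    vals = raw[mask]
    if not np.any(vals != 0.0):
        raise ValueError("empty pattern: no blob overlaps the brain mask")
    vals = vals - vals.mean()
    norm = np.linalg.norm(vals)
    if norm == 0.0:
        raise ValueError("empty pattern: blobs cancel exactly after centering")
    vals = vals / norm
    out = np.zeros_like(raw)
    out[mask] = vals
    return out


def _baseline_field(config: PhantomConfig) -> np.ndarray:
    nx, ny, nz = config.grid_shape
    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    ripple = (
        np.cos(2.0 * np.pi * x / nx)
        * np.cos(2.0 * np.pi * y / ny)
        * np.cos(2.0 * np.pi * z / nz)
    )
    base = config.baseline.level * (1.0 + config.baseline.ripple_frac * ripple)
    if np.any(base <= 0):
        raise ValueError("non-positive baseline field")
    return np.broadcast_to(base, config.grid_shape).copy()


def _masked_smooth(vol: np.ndarray, mask: np.ndarray, sigma_vox: float) -> np.ndarray:
    """Normalized (masked) Gaussian smoothing: convolve the volume and the
    mask indicator separately with zero padding and take their ratio inside
    the mask. Brain voxels are averaged only with other brain voxels, so the
    smoothed phantom keeps a crisp boundary instead of bleeding into the
    empty background."""
    num = gaussian_filter(vol, sigma=sigma_vox, mode="constant", cval=0.0)
    den = gaussian_filter(mask.astype(np.float64), sigma=sigma_vox, mode="constant", cval=0.0)
    out = np.zeros_like(vol)
    out[mask] = num[mask] / den[mask]
    return out


def _subject_rng(seed: int, group_index: int, subject_index: int) -> np.random.Generator:
    # One substream per (group, subject): adding subjects or groups never
    # reshuffles draws for existing subjects.
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(group_index, subject_index))
    return np.random.default_rng(ss)


def simulate_cohort(
    config: PhantomConfig,
) -> tuple[list[VoxelImage], pd.DataFrame, PlantedTruth]:
    """Simulate a two-group cohort under the planted-pattern generative model.

    Inside the brain mask each subject's pre-smoothing intensity is

        image_i(v) = g_i * baseline(v) * exp(e_i * pattern(v) + eps_i(v))

    with ``g_i = exp(N(0, global_sd))`` the global activity factor, ``e_i``
    the pattern expression (control mean 0, patient mean ``effect_delta``,
    common SD ``expr_sd``) and ``eps_i`` iid ``N(0, noise_sd)`` voxel noise.
    Outside the mask intensity is zero. The volume is then smoothed with an
    isotropic 3D Gaussian kernel of ``smooth_fwhm_mm`` FWHM, applied as a
    mask-normalized convolution so brain activity is not diluted into the
    empty background. Identical configs (including seed) give bit-identical
    output.

    Returns the subject images, a manifest (subject_id, group,
    clinical_score, image_path — empty until :func:`write_cohort`), and the
    :class:`PlantedTruth`.
    """
    mask = ellipsoid_mask(config)
    pattern = make_pattern_template(config)
    baseline = _baseline_field(config)

    sigma_vox = 0.0
    if config.smooth_fwhm_mm > 0:
        sigma_vox = config.smooth_fwhm_mm / (_FWHM_PER_SIGMA * config.voxel_size_mm)

    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    n = config.n_per_group
    groups = [(0, config.control_label, 0.0), (1, config.patient_label, config.effect_delta)]

    images: list[VoxelImage] = []
    rows = []
    expressions = np.empty(2 * n)
    global_factors = np.empty(2 * n)
    clinical = np.empty(2 * n, dtype=np.int64)

    i = 0
    for gi, label, mu in groups:
        for j in range(n):
            rng = _subject_rng(config.seed, gi, j)
            expr = mu + config.expr_sd * rng.standard_normal()
            log_g = config.global_sd * rng.standard_normal()
            noise = config.noise_sd * rng.standard_normal(config.grid_shape)
            clin_noise = config.clinical.noise_sd * rng.standard_normal()

            g = float(np.exp(log_g))
            vol = np.zeros(config.grid_shape, dtype=np.float64)
            vol[mask] = g * baseline[mask] * np.exp(expr * pattern[mask] + noise[mask])
            if sigma_vox > 0:
                vol = _masked_smooth(vol, mask, sigma_vox)

            score = int(
                np.clip(
                    np.round(config.clinical.intercept - config.clinical.slope * expr + clin_noise),
                    config.clinical.floor,
                    config.clinical.ceiling,
                )
            )
            subject_id = f"{label}_{j:03d}"
            images.append(VoxelImage(vol, affine.copy(), config.voxel_size_mm))
            rows.append(
                {"subject_id": subject_id, "group": label, "clinical_score": score, "image_path": ""}
            )
            expressions[i] = expr
            global_factors[i] = g
            clinical[i] = score
            i += 1

    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "clinical_score", "image_path"])
    truth = PlantedTruth(
        pattern_map=pattern,
        brain_mask=mask,
        expression=expressions,
        global_factor=global_factors,
        clinical_score=clinical,
    )
    return images, manifest, truth


def write_cohort(
    config: PhantomConfig,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate a cohort and persist it: one ``.nii.gz`` per subject,
    ``manifest.tsv``, ``truth.json`` with the planted per-subject parameters
    and ``pattern_truth.nii.gz``. Returns the on-disk manifest and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, manifest, truth = simulate_cohort(config)

    paths = []
    for img, sid in zip(images, manifest["subject_id"]):
        p = out / f"{sid}.nii.gz"
        img.to_nifti(p)
        paths.append(p.name)
    manifest = manifest.assign(image_path=paths)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)

    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    VoxelImage(truth.pattern_map, affine, config.voxel_size_mm).to_nifti(out / "pattern_truth.nii.gz")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "effect_delta": config.effect_delta,
                "expr_sd": config.expr_sd,
                "global_sd": config.global_sd,
                "noise_sd": config.noise_sd,
                "smooth_fwhm_mm": config.smooth_fwhm_mm,
                "subject_id": manifest["subject_id"].tolist(),
                "expression": truth.expression.tolist(),
                "global_factor": truth.global_factor.tolist(),
                "clinical_score": truth.clinical_score.tolist(),
            },
            fh,
            indent=2,
        )
    return manifest, truth
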