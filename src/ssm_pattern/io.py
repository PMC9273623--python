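"""Cohort manifests, pattern-bundle serialization and run logging.

A pattern bundle is a directory holding ``weights.nii.gz`` (the unit-norm
voxel weights scattered into the 3D grid), ``mask.nii.gz`` (0/1) and
``pattern.json`` with everything else: the GMP as a flat array in the
declared voxel order, the selected components and combination coefficients,
the reference-group moments and provenance. Bundles carry a format version
and the voxel-order spec so they remain portable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .derive import FORMAT_VERSION, VOXEL_ORDER, MetabolicPattern
from .image import VoxelImage
from .preprocess import AnalysisMask

__all__ = [
    "read_manifest",
    "load_cohort_images",
    "save_pattern",
    "load_pattern",
    "write_run_log",
]

logger = logging.getLogger("ssm_pattern")

MANIFEST_COLUMNS = ["subject_id", "group", "clinical_score", "image_path"]


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Read and validate a cohort manifest (TSV with header).

    Columns: subject_id, group, clinical_score, image_path. Missing clinical
    scores stay missing (NaN), never zero. Relative image paths are resolved
    against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str, "image_path": str})
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest missing required column(s): {', '.join(missing_cols)}")
    dup = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate subject_id(s) in manifest: {', '.join(sorted(set(dup)))}")
    df["clinical_score"] = pd.to_numeric(df["clinical_score"], errors="coerce")
    root = path.parent
    resolved = [str((root / p)) if not Path(p).is_absolute() else p for p in df["image_path"].fillna("")]
    df = df.assign(image_path=resolved)
    if check_paths:
        bad = [p for p in df["image_path"] if not Path(p).exists()]
        if bad:
            raise ValueError("unresolvable image path(s): " + ", ".join(bad[:5]))
    return df[MANIFEST_COLUMNS]


def load_cohort_images(manifest: pd.DataFrame) -> list[VoxelImage]:
    return [VoxelImage.from_nifti(p) for p in manifest["image_path"]]


def save_pattern(pattern: MetabolicPattern, out_dir: str | Path) -> Path:
    """Persist a pattern bundle; returns the bundle directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = pattern.provenance.get("affine")
    affine = np.asarray(affine, dtype=np.float64) if affine is not None else np.eye(4)

    nib.save(nib.Nifti1Image(pattern.weights_volume(), affine), str(out / "weights.nii.gz"))
    nib.save(
        nib.Nifti1Image(pattern.mask.data.astype(np.uint8), affine), str(out / "mask.nii.gz")
    )
    sidecar = {
        "format_version": FORMAT_VERSION,
        "voxel_order": VOXEL_ORDER,
        "mask_threshold_fraction": pattern.mask.threshold_fraction,
        "gmp": pattern.gmp.tolist(),
        "selected_components": pattern.selected_components,
        "combination_coefficients": pattern.combination_coefficients,
        "vaf": pattern.vaf,
        "reference_mean": pattern.reference_mean,
        "reference_sd": pattern.reference_sd,
        "provenance": _jsonable(pattern.provenance),
    }
    with open(out / "pattern.json", "w") as fh:
        json.dump(sidecar, fh)
    return out


def load_pattern(bundle_dir: str | Path) -> MetabolicPattern:
    """Load a pattern bundle written by :func:`save_pattern`."""
    bundle = Path(bundle_dir)
    sidecar_path = bundle / "pattern.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    version = sidecar.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unknown format_version {version!r}; expected {FORMAT_VERSION!r}")

    weights_img = nib.load(str(bundle / "weights.nii.gz"))
    mask_img = nib.load(str(bundle / "mask.nii.gz"))
    weights_vol = np.asarray(weights_img.get_fdata(), dtype=np.float64)
    mask_data = np.asarray(mask_img.get_fdata()) > 0.5
    if weights_vol.shape != mask_data.shape:
        raise ValueError("weights and mask grids disagree")
    mask = AnalysisMask(mask_data, float(sidecar.get("mask_threshold_fraction", 0.2)))
    gmp = np.asarray(sidecar["gmp"], dtype=np.float64)
    if gmp.shape[0] != mask.n_voxels:
        raise ValueError("gmp length mismatch")
    return MetabolicPattern(
        weights=mask.extract(weights_vol),
        gmp=gmp,
        mask=mask,
        selected_components=[int(k) for k in sidecar["selected_components"]],
        combination_coefficients=[float(c) for c in sidecar["combination_coefficients"]],
        vaf=[float(v) for v in sidecar["vaf"]],
        reference_mean=float(sidecar["reference_mean"]),
        reference_sd=float(sidecar["reference_sd"]),
        provenance=sidecar.get("provenance", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_run_log(out_dir: str | Path, command: str, config: dict) -> Path:
    """Write a JSON run log (resolved configuration, seeds, package version)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"command": command, "package_version": __version__, "config": _jsonable(config)}
    log_path = out / f"{command}.log.json"
    with open(log_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    logger.info("wrote run log %s", log_path)
    return log_path
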