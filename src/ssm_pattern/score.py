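"""Topographic profile rating: expression of a stored pattern in any scan.

A new scan is log-transformed over the pattern's mask, centred by its own
mean (removing the subject's global activity), centred again by the
*derivation* cohort's group mean profile, and projected onto the pattern's
voxel weights. Raw scores are standardised against the reference control
group's moments frozen in the pattern bundle, so scores from different
cohorts live on one common Z scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .derive import MetabolicPattern
from .image import VoxelImage

__all__ = ["SubjectScore", "tpr_score", "z_transform", "score_cohort"]


@dataclass(frozen=True)
class SubjectScore:
    subject_id: str
    raw: float
    z: float


def tpr_score(image: VoxelImage, pattern: MetabolicPattern) -> float:
    """Raw pattern-expression score of one scan.

    l = ln(masked intensities); l -= mean(l); l -= gmp; raw = l . weights.
    Invariant to any positive global rescaling of the image (the ln c offset
    is absorbed by the mean subtraction).
    """
    if image.shape != pattern.mask.shape:
        raise ValueError(
            f"image grid {image.shape} does not match pattern mask grid {pattern.mask.shape}"
        )
    vals = pattern.mask.extract(image.data)
    bad = int(np.sum(vals <= 0))
    if bad:
        raise ValueError(f"{bad} masked voxel(s) have non-positive intensity; cannot score")
    l = np.log(vals)
    l = l - l.mean()
    l = l - pattern.gmp
    return float(l @ pattern.weights)


def z_transform(
    raws: Sequence[float], pattern: MetabolicPattern, subject_ids: Sequence[str] | None = None
) -> list[SubjectScore]:
    """Standardise raw scores by the bundle's reference-group moments."""
    if not pattern.reference_sd > 0:
        raise ValueError("reference_sd must be positive")
    raws = [float(r) for r in raws]
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(len(raws))]
    return [
        SubjectScore(sid, r, (r - pattern.reference_mean) / pattern.reference_sd)
        for sid, r in zip(subject_ids, raws)
    ]


def score_cohort(
    images: Sequence[VoxelImage],
    pattern: MetabolicPattern,
    subject_ids: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score a list of scans; returns a table with subject_id, group, raw, z."""
    raws = [tpr_score(img, pattern) for img in images]
    scores = z_transform(raws, pattern, subject_ids)
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in scores],
            "group": list(groups) if groups is not None else [""] * len(scores),
            "raw": [s.raw for s in scores],
            "z": [s.z for s in scores],
        }
    )
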