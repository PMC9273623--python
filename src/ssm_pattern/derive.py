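"""Covariance pattern derivation from subject residual profiles.

The derivation follows the standard SSM recipe for disease-related pattern
identification: PCA of the SRP matrix (computed through the small
subjects-by-subjects covariance, since voxels vastly outnumber subjects),
screening of components by variance accounted for (VAF), selection of a
component subset by the Akaike Information Criterion of logistic
group-discrimination models, and linear combination of the selected
component loadings into a single unit-norm voxel-weight map. The final map
is oriented so that patients express it more strongly than controls, and the
designated control group's raw expression moments are stored for
Z-transformation of all subsequent scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .image import VoxelImage
from .preprocess import AnalysisMask, SrpMatrix, build_mask, double_center, to_log_profiles

__all__ = [
    "PcSet",
    "MetabolicPattern",
    "DerivationResult",
    "pca_srp",
    "select_components",
    "fit_logistic_aic",
    "assemble_pattern",
    "derive_pattern",
]

FORMAT_VERSION = "1"
VOXEL_ORDER = "lexicographic, x fastest, 0-based indices"

# relative eigenvalue cutoff below which a component is treated as null space
_RANK_TOL = 1e-10


@dataclass
class PcSet:
    """Principal components of an SRP matrix.

    ``loadings`` is components x voxels (unit-norm rows), ``subject_scores``
    subjects x components with score[i, k] = SRP_i . loading_k, and ``vaf``
    the per-component fraction of total variance, in descending order.
    """

    loadings: np.ndarray
    subject_scores: np.ndarray
    vaf: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


@dataclass
class MetabolicPattern:
    """Everything needed to score a new scan's expression of the pattern.

    The bundle is self-contained: the analysis mask, the derivation GMP, the
    unit-norm voxel weights, and the reference (control) group's raw-score
    mean/SD used for the Z-transform. Scoring never re-estimates any of
    these from the scored cohort.
    """

    weights: np.ndarray
    gmp: np.ndarray
    mask: AnalysisMask
    selected_components: list[int]
    combination_coefficients: list[float]
    vaf: list[float]
    reference_mean: float
    reference_sd: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.gmp = np.asarray(self.gmp, dtype=np.float64)
        if self.weights.shape != (self.mask.n_voxels,):
            raise ValueError("weights length does not match mask voxel count")
        if self.gmp.shape != (self.mask.n_voxels,):
            raise ValueError("gmp length mismatch")
        if abs(np.linalg.norm(self.weights) - 1.0) > 1e-8:
            raise ValueError("pattern weights must have unit Euclidean norm")
        if not self.reference_sd > 0:
            raise ValueError("reference_sd must be positive")

    def weights_volume(self) -> np.ndarray:
        return self.mask.insert(self.weights)


@dataclass
class DerivationResult:
    """Pattern plus the intermediate objects useful for reporting/tests."""

    pattern: MetabolicPattern
    pcs: PcSet
    srp: SrpMatrix
    raw_scores: np.ndarray
    z_scores: np.ndarray
    labels: list[str]
    aic_table: dict[tuple[int, ...], float]


def pca_srp(srp: SrpMatrix) -> PcSet:
    """PCA of the SRP via the subjects-by-subjects covariance S S^T.

    Eigenvectors of the small matrix are mapped to voxel loadings by
    loading_k ∝ S^T u_k (unit-normalised); VAF_k = lambda_k / sum(lambda).
    Each loading's sign is fixed by making its largest-magnitude entry
    positive (the final pattern orientation is handled separately).
    """
    s = srp.matrix
    if s.shape[0] < 3:
        raise ValueError("PCA needs at least 3 subjects")
    cov = s @ s.T
    lam, u = np.linalg.eigh(cov)
    lam, u = lam[::-1], u[:, ::-1]
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("SRP matrix has rank 0; nothing to decompose")
    keep = lam > _RANK_TOL * lam[0]
    lam_kept = lam[keep]
    u_kept = u[:, keep]

    loadings = s.T @ u_kept  # voxels x k
    loadings /= np.linalg.norm(loadings, axis=0, keepdims=True)
    # deterministic sign: largest-|entry| positive
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    loadings *= signs
    scores = s @ loadings
    return PcSet(
        loadings=loadings.T,
        subject_scores=scores,
        vaf=lam_kept / total,
        eigenvalues=lam_kept,
    )


def select_components(pcs: PcSet | np.ndarray, vaf_min: float = 0.05) -> list[int]:
    """Indices of all components whose VAF is at least ``vaf_min``, in
    descending-VAF order ("at least": the boundary case is included)."""
    if not 0.0 < vaf_min < 1.0:
        raise ValueError("vaf_min must lie in (0, 1)")
    vaf = pcs.vaf if isinstance(pcs, PcSet) else np.asarray(pcs, dtype=np.float64)
    selected = [int(k) for k in range(len(vaf)) if vaf[k] >= vaf_min]
    if not selected:
        raise ValueError("no components reach VAF threshold")
    return selected


def _loglik(scores: np.ndarray, labels: np.ndarray, intercept: float, coef: np.ndarray) -> float:
    """Unpenalised Bernoulli log-likelihood at given logistic coefficients."""
    eta = intercept + scores @ coef
    # log sigmoid, numerically stable
    return float(-np.sum(np.logaddexp(0.0, -eta) * labels + np.logaddexp(0.0, eta) * (1 - labels)))


def fit_logistic_aic(
    subject_scores: np.ndarray,
    labels: np.ndarray,
    candidate_subsets: Sequence[Sequence[int]],
    ridge: float = 1e-4,
) -> tuple[tuple[int, ...], dict, dict[tuple[int, ...], float]]:
    """Fit one logistic group-discrimination model per candidate component
    subset and return the AIC-minimising subset.

    A small ridge penalty on the slope coefficients guarantees convergence
    under complete separation (common at n = 20 + 20); AIC = 2(k+1) - 2*ll
    is computed from the *unpenalised* log-likelihood at the converged
    coefficients, with k the subset size. Ties break toward the smaller,
    then lexicographically first, subset.
    """
    labels = np.asarray(labels)
    if labels.dtype != bool:
        labels = labels.astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to fit logistic models")
    if len(candidate_subsets) == 0:
        raise ValueError("candidate_subsets must be nonempty")
    y = labels.astype(np.float64)

    aics: dict[tuple[int, ...], float] = {}
    fits: dict[tuple[int, ...], tuple[float, np.ndarray]] = {}
    for subset in candidate_subsets:
        subset = tuple(int(k) for k in subset)
        x = subject_scores[:, list(subset)]
        # sklearn objective: 0.5||w||^2 + C * sum(loss); C = 0.5/ridge gives
        # loss + ridge*||w||^2 (intercept unpenalised with lbfgs)
        clf = LogisticRegression(C=0.5 / ridge, solver="lbfgs", max_iter=10_000, tol=1e-10)
        clf.fit(x, y)
        intercept = float(clf.intercept_[0])
        coef = clf.coef_[0].astype(np.float64)
        ll = _loglik(x, y, intercept, coef)
        aics[subset] = 2.0 * (len(subset) + 1) - 2.0 * ll
        fits[subset] = (intercept, coef)

    best = min(aics, key=lambda s: (aics[s], len(s), s))
    intercept, coef = fits[best]
    coefficients = {"intercept": intercept, "components": {k: float(c) for k, c in zip(best, coef)}}
    return best, coefficients, aics


def assemble_pattern(
    pcs: PcSet,
    subset: Sequence[int],
    coefficients: Sequence[float],
    srp: SrpMatrix,
    patient_mask: np.ndarray,
    reference_mask: np.ndarray,
    provenance: dict | None = None,
) -> MetabolicPattern:
    """Combine selected component loadings into the final unit-norm pattern.

    weights ∝ sum_k coeff_k * loading_k; the sign is flipped if needed so the
    mean patient raw score exceeds the mean control raw score; the reference
    group's raw-score mean and sample SD (ddof=1) against the final pattern
    are stored for Z-transformation.
    """
    subset = [int(k) for k in subset]
    coefficients = np.asarray(list(coefficients), dtype=np.float64)
    if len(subset) != coefficients.shape[0]:
        raise ValueError("coefficients must align with subset")
    w = pcs.loadings[subset].T @ coefficients
    norm = np.linalg.norm(w)
    if norm == 0.0:
        raise ValueError("combined pattern vector is zero")
    w = w / norm

    raw = srp.matrix @ w
    patient_mask = np.asarray(patient_mask, dtype=bool)
    control_mask = ~patient_mask
    if raw[patient_mask].mean() < raw[control_mask].mean():
        w = -w
        raw = -raw

    ref = raw[np.asarray(reference_mask, dtype=bool)]
    if ref.size < 2:
        raise ValueError("reference group needs at least 2 subjects")
    ref_mean = float(ref.mean())
    ref_sd = float(ref.std(ddof=1))
    if ref_sd <= 0:
        raise ValueError("reference group scores are constant; SD must be positive")

    return MetabolicPattern(
        weights=w,
        gmp=srp.gmp,
        mask=srp.mask,
        selected_components=subset,
        combination_coefficients=[float(c) for c in coefficients],
        vaf=[float(v) for v in pcs.vaf],
        reference_mean=ref_mean,
        reference_sd=ref_sd,
        provenance=provenance or {},
    )


def _candidate_subsets(
    selected: Sequence[int], family: Literal["prefix", "all"]
) -> list[tuple[int, ...]]:
    selected = [int(k) for k in selected]
    if family == "prefix":
        return [tuple(selected[: i + 1]) for i in range(len(selected))]
    if family == "all":
        out: list[tuple[int, ...]] = []
        for r in range(1, len(selected) + 1):
            out.extend(itertools.combinations(selected, r))
        return out
    raise ValueError(f"unknown candidate family {family!r}")


def derive_pattern(
    images: Sequence[VoxelImage],
    labels: Sequence[str],
    *,
    patient_label: str,
    control_label: str,
    subject_ids: Sequence[str] | None = None,
    vaf_min: float = 0.05,
    mask: AnalysisMask | None = None,
    mask_threshold: float = 0.2,
    candidate_family: Literal["prefix", "all"] = "prefix",
    forced_subset: Sequence[int] | None = None,
    ridge: float = 1e-4,
    provenance: dict | None = None,
) -> DerivationResult:
    """Run the full derivation: mask → log → double centre → PCA → VAF screen
    → AIC logistic selection → pattern assembly and orientation.

    The candidate logistic models default to nested prefixes of the
    VAF-screened list ({PC1}, {PC1,PC2}, ...); pass ``candidate_family="all"``
    to search every nonempty subset, or ``forced_subset`` to pin the
    component subset and skip the VAF screen and AIC search (used when
    bootstrap replicates freeze the original selection). An externally
    supplied ``mask`` (e.g. during bootstrap resampling) bypasses mask
    construction.
    """
    labels = [str(l) for l in labels]
    if len(labels) != len(images):
        raise ValueError("labels length does not match images")
    patient = np.array([l == patient_label for l in labels])
    control = np.array([l == control_label for l in labels])
    if not patient.any() or not control.any():
        raise ValueError("both patient and control labels must be present")

    if mask is None:
        mask = build_mask(images, mask_threshold)
    logm = to_log_profiles(images, mask, subject_ids)
    srp = double_center(logm)
    pcs = pca_srp(srp)
    if forced_subset is not None:
        subset = tuple(int(k) for k in forced_subset)
        if max(subset) >= pcs.n_components:
            raise ValueError("forced_subset refers to a component beyond the PCA rank")
        candidates = [subset]
    else:
        selected = select_components(pcs, vaf_min)
        candidates = _candidate_subsets(selected, candidate_family)
    best, coefs, aics = fit_logistic_aic(pcs.subject_scores, patient, candidates, ridge)

    prov = dict(provenance or {})
    prov.setdefault("subject_ids", srp.subject_ids)
    prov.setdefault("patient_label", patient_label)
    prov.setdefault("control_label", control_label)
    prov.setdefault("vaf_min", vaf_min)
    pattern = assemble_pattern(
        pcs,
        list(best),
        [coefs["components"][k] for k in best],
        srp,
        patient_mask=patient,
        reference_mask=control,
        provenance=prov,
    )
    raw = srp.matrix @ pattern.weights
    z = (raw - pattern.reference_mean) / pattern.reference_sd
    return DerivationResult(
        pattern=pattern,
        pcs=pcs,
        srp=srp,
        raw_scores=raw,
        z_scores=z,
        labels=labels,
        aic_table=aics,
    )
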