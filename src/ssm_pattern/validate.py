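"""Validation statistics for a derived covariance pattern.

Covers the reliability and inference tools that normally accompany an
SSM/PCA pattern: voxel-wise bootstrap inverse-coefficient-of-variation (ICV)
maps, k-fold topography cross-validation, the exact Fisher-Pitman two-sample
permutation test on expression scores, ROC analysis with the Youden-index
operating point, and clinical correlations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .derive import DerivationResult, derive_pattern
from .image import VoxelImage
from .preprocess import AnalysisMask, build_mask

__all__ = [
    "IcvMap",
    "PermTestResult",
    "RocResult",
    "bootstrap_icv",
    "kfold_topography",
    "fisher_pitman",
    "roc_youden",
    "correlate",
]


@dataclass
class IcvMap:
    """Voxel-wise mean/SD of pattern weights over bootstrap replicates.

    ``icv`` is a 3D map (zero outside the analysis mask); voxels whose
    replicate SD is exactly zero get +/- infinity with the sign of the mean.
    ``|icv| >= threshold`` (default 1.96) is read as voxel reliability at
    two-sided p < 0.05.
    """

    icv: np.ndarray
    mask: AnalysisMask
    n_replicates: int
    threshold: float = 1.96
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")

    @property
    def suprathreshold(self) -> np.ndarray:
        """Boolean 3D map of reliably weighted voxels."""
        out = np.abs(self.icv) >= self.threshold
        out &= self.mask.data
        return out


@dataclass
class PermTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    exact: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


@dataclass
class RocResult:
    auc: float
    optimal_threshold: float
    sensitivity: float
    specificity: float
    thresholds: np.ndarray = field(repr=False)
    sens_curve: np.ndarray = field(repr=False)
    spec_curve: np.ndarray = field(repr=False)

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _resample_within_groups(
    labels: np.ndarray, rng: np.random.Generator, max_redraws: int = 1000
) -> tuple[np.ndarray, int]:
    """Indices resampled with replacement within each group, sizes preserved.

    Replicates in which any group collapses to fewer than 2 distinct
    subjects are redrawn (returned count reports how many times).
    """
    redrawn = 0
    for _ in range(max_redraws):
        idx = np.empty(labels.shape[0], dtype=np.intp)
        pos = 0
        ok = True
        for g in np.unique(labels):
            members = np.flatnonzero(labels == g)
            draw = rng.choice(members, size=members.size, replace=True)
            if np.unique(draw).size < 2:
                ok = False
                break
            idx[pos : pos + members.size] = draw
            pos += members.size
        if ok:
            return idx, redrawn
        redrawn += 1
    raise RuntimeError("could not draw a valid bootstrap replicate")


def bootstrap_icv(
    images: Sequence[VoxelImage],
    labels: Sequence[str],
    *,
    patient_label: str,
    control_label: str,
    n_replicates: int = 1000,
    seed: int = 0,
    vaf_min: float = 0.05,
    threshold: float = 1.96,
    mask_threshold: float = 0.2,
    freeze_selection: bool = False,
) -> IcvMap:
    """Bootstrap reliability of the derived pattern's voxel weights.

    The analysis mask is built once from the full cohort and held fixed.
    Each replicate resamples subjects with replacement within each group
    (group sizes preserved), reruns the derivation on the fixed mask —
    including the VAF screen and AIC component selection, unless
    ``freeze_selection`` pins the original subset — and sign-aligns the
    replicate pattern to the original by the sign of their correlation.
    ICV = mean / SD (ddof=1) per voxel over replicates.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    labels = np.asarray([str(l) for l in labels])
    mask = build_mask(images, mask_threshold)
    original = derive_pattern(
        list(images),
        list(labels),
        patient_label=patient_label,
        control_label=control_label,
        mask=mask,
        vaf_min=vaf_min,
    )
    w0 = original.pattern.weights
    frozen = original.pattern.selected_components if freeze_selection else None

    rng = np.random.default_rng(seed)
    acc = np.zeros((n_replicates, mask.n_voxels), dtype=np.float64)
    total_redrawn = 0
    for b in range(n_replicates):
        idx, redrawn = _resample_within_groups(labels, rng)
        total_redrawn += redrawn
        rep_images = [images[i] for i in idx]
        rep_labels = [labels[i] for i in idx]
        rep_ids = [f"rep{b}_{i}" for i in range(len(idx))]
        try:
            rep = derive_pattern(
                rep_images,
                rep_labels,
                subject_ids=rep_ids,
                patient_label=patient_label,
                control_label=control_label,
                mask=mask,
                vaf_min=vaf_min,
                forced_subset=frozen,
            )
            w = rep.pattern.weights
        except ValueError:
            # degenerate replicate (e.g. constant reference scores): redraw
            idx, _ = _resample_within_groups(labels, rng)
            total_redrawn += 1
            rep = derive_pattern(
                [images[i] for i in idx],
                [labels[i] for i in idx],
                subject_ids=rep_ids,
                patient_label=patient_label,
                control_label=control_label,
                mask=mask,
                vaf_min=vaf_min,
                forced_subset=frozen,
            )
            w = rep.pattern.weights
        if float(w @ w0) < 0:
            w = -w
        acc[b] = w

    mean = acc.mean(axis=0)
    sd = acc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        icv_flat = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.sign(mean) * np.inf)
    icv_flat = np.where((sd == 0) & (mean == 0), 0.0, icv_flat)
    return IcvMap(
        icv=mask.insert(np.nan_to_num(icv_flat, nan=0.0, posinf=np.inf, neginf=-np.inf)),
        mask=mask,
        n_replicates=n_replicates,
        threshold=threshold,
        n_redrawn=total_redrawn,
    )


def kfold_topography(
    images: Sequence[VoxelImage],
    labels: Sequence[str],
    *,
    patient_label: str,
    control_label: str,
    k: int = 3,
    seed: int = 0,
    vaf_min: float = 0.05,
    mask_threshold: float = 0.2,
) -> np.ndarray:
    """Pairwise Pearson correlations between patterns derived on k-fold
    training portions.

    Subjects are split into k group-stratified folds; each fold's pattern is
    derived on the other k-1 folds. All patterns share one mask built from
    the full cohort so their voxel-weight maps are directly comparable;
    signs are aligned to the first pattern. Returns the k(k-1)/2 pairwise
    correlations.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels_arr = np.asarray([str(l) for l in labels])
    for g in np.unique(labels_arr):
        if np.sum(labels_arr == g) < k:
            raise ValueError(f"group {g!r} has fewer subjects than k={k}")
    mask = build_mask(images, mask_threshold)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    patterns = []
    for train_idx, _test_idx in skf.split(np.zeros(len(labels_arr)), labels_arr):
        tr_labels = labels_arr[train_idx]
        if min(np.sum(tr_labels == patient_label), np.sum(tr_labels == control_label)) < 2:
            raise ValueError("a fold's training portion has < 2 subjects in a group")
        res = derive_pattern(
            [images[i] for i in train_idx],
            list(tr_labels),
            patient_label=patient_label,
            control_label=control_label,
            mask=mask,
            vaf_min=vaf_min,
        )
        w = res.pattern.weights
        if patterns and float(w @ patterns[0]) < 0:
            w = -w
        patterns.append(w)
    corrs = []
    for a, b in itertools.combinations(range(k), 2):
        corrs.append(float(np.corrcoef(patterns[a], patterns[b])[0, 1]))
    return np.asarray(corrs)


def fisher_pitman(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    *,
    exact_limit: int = 200_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> PermTestResult:
    """Two-sample Fisher-Pitman permutation test on the difference of means.

    The statistic is mean(a) - mean(b). If the number of relabelings
    C(n_a+n_b, n_a) is at most ``exact_limit`` every relabeling is
    enumerated and p is the exact two-tailed proportion with
    |statistic| >= |observed| (the observed labeling is one of them). Above
    the limit a Monte-Carlo approximation with ``n_mc`` random relabelings
    is used, with the add-one correction p = (1 + count) / (1 + n_mc) so the
    test never reports p = 0 and retains its exactness guarantee.
    """
    a = np.asarray(list(scores_a), dtype=np.float64)
    b = np.asarray(list(scores_b), dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    n, na, nb = pooled.size, a.size, b.size
    total = pooled.sum()
    observed = a.mean() - b.mean()
    # tolerance for |stat| >= |obs| comparisons under float arithmetic
    eps = 1e-12 * max(1.0, float(np.abs(pooled).max()))

    n_relabel = math.comb(n, na)
    if n_relabel <= exact_limit:
        count = 0
        for comb in itertools.combinations(range(n), na):
            sa = pooled[list(comb)].sum()
            stat = sa / na - (total - sa) / nb
            if abs(stat) >= abs(observed) - eps:
                count += 1
        return PermTestResult(float(observed), count / n_relabel, n_relabel, exact=True)

    rng = np.random.default_rng(seed)
    # vectorised random relabelings: first na entries of each permutation
    count = 0
    batch = 10_000
    done = 0
    while done < n_mc:
        m = min(batch, n_mc - done)
        order = np.argsort(rng.random((m, n)), axis=1)
        sa = pooled[order[:, :na]].sum(axis=1)
        stat = sa / na - (total - sa) / nb
        count += int(np.sum(np.abs(stat) >= abs(observed) - eps))
        done += m
    return PermTestResult(float(observed), (1 + count) / (1 + n_mc), n_mc, exact=False)


def roc_youden(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC analysis with the Youden-index operating point.

    Positive class = patients; a subject is called positive when its score
    is >= the threshold. AUC is the tie-corrected Mann-Whitney probability
    P(score_patient > score_control) + 0.5 P(tie). Candidate thresholds are
    the midpoints between consecutive distinct scores plus one below the
    minimum and one above the maximum; the threshold maximising
    J = sensitivity + specificity - 1 is returned, ties broken toward higher
    specificity (then the higher threshold).
    """
    scores = np.asarray(list(scores), dtype=np.float64)
    y = np.asarray(list(labels), dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())

    ranks = stats.rankdata(scores)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    u = np.unique(scores)
    midpoints = (u[:-1] + u[1:]) / 2.0
    thresholds = np.concatenate([[u[0] - 1.0], midpoints, [u[-1] + 1.0]])
    sens = np.array([np.mean(scores[y] >= t) for t in thresholds])
    spec = np.array([np.mean(scores[~y] < t) for t in thresholds])
    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.flatnonzero(j >= best_j - 1e-12)
    # favour specificity, then the higher cut-point
    best = tied[np.lexsort((thresholds[tied], spec[tied]))][-1]
    return RocResult(
        auc=float(auc),
        optimal_threshold=float(thresholds[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        thresholds=thresholds,
        sens_curve=sens,
        spec_curve=spec,
    )


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float, int]:
    """Pearson or Spearman correlation with a two-tailed p-value.

    Callers drop incomplete pairs before calling; n is reported back so
    downstream tables can state the per-analysis sample size.
    """
    x = np.asarray(list(x), dtype=np.float64)
    y = np.asarray(list(y), dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), int(x.size)
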