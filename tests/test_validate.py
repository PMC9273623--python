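"""Validation statistics: permutation test, ROC/Youden, correlations,
bootstrap ICV reliability and k-fold topography stability."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ssm_pattern as sp

from conftest import small_config


class TestFisherPitman:
    def test_no_signal(self):
        res = sp.fisher_pitman([5.0], [5.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.exact

    def test_small_case_matches_enumeration(self):
        res = sp.fisher_pitman([1.0, 2.0], [3.0, 4.0])
        assert res.exact and res.n_permutations == 6
        assert res.p_value == pytest.approx(2.0 / 6.0, abs=1e-12)

    def test_exact_p_matches_bruteforce_oracle(self, rng):
        """Full enumeration of all two-group splits, written independently."""
        a = rng.normal(size=4)
        b = rng.normal(size=5)
        res = sp.fisher_pitman(a, b)
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        count = total = 0
        for comb in itertools.combinations(range(9), 4):
            rest = [i for i in range(9) if i not in comb]
            stat = pooled[list(comb)].mean() - pooled[rest].mean()
            total += 1
            if abs(stat) >= abs(obs) - 1e-12:
                count += 1
        assert total == math.comb(9, 4)
        assert res.exact
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_monte_carlo_converges_to_exact(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6) + 0.8
        exact = sp.fisher_pitman(a, b)
        assert exact.exact
        mc = sp.fisher_pitman(a, b, exact_limit=1, n_mc=20_000, seed=4)
        assert not mc.exact
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 20_000)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sp.fisher_pitman([], [1.0])

    def test_null_calibration_exact(self):
        """Rejection rate at alpha = 0.05 under the null stays near nominal
        (exact test on small samples, 300 draws)."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_runs = 300
        for _ in range(n_runs):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            res = sp.fisher_pitman(a, b)
            if res.p_value < 0.05:
                rejections += 1
        rate = rejections / n_runs
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_runs)
        assert 0.05 - half <= rate <= 0.05 + half


class TestRocYouden:
    def test_perfect_separation(self):
        res = sp.roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 3 < res.optimal_threshold <= 10

    def test_all_ties_auc_half(self):
        res = sp.roc_youden([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        assert res.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sp.roc_youden([1.0, 2.0], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_bruteforce_pair_counting_and_threshold_scan(self, seed):
        """AUC by exhaustive concordant/tied pair counting; operating point by
        a brute-force scan over every candidate cut with specificity-favouring
        tie-break."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        scores = np.round(rng.normal(size=n), 1)  # coarse values force ties
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        res = sp.roc_youden(scores, labels)

        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > c) + 0.5 * (p == c) for p in pos for c in neg)
        assert res.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

        u = np.unique(scores)
        cands = np.concatenate([[u[0] - 1], (u[:-1] + u[1:]) / 2, [u[-1] + 1]])
        best = None
        for t in cands:
            sens = np.mean(pos >= t)
            spec = np.mean(neg < t)
            key = (round(sens + spec, 12), round(spec, 12), t)
            if best is None or key > best[0]:
                best = (key, sens, spec)
        assert res.sensitivity == pytest.approx(best[1], abs=1e-12)
        assert res.specificity == pytest.approx(best[2], abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=10)
        labels = np.array([0, 1] * 5, dtype=bool)
        base = sp.roc_youden(scores, labels).auc
        for f in (np.exp, lambda x: x**3, lambda x: 5 * x - 2):
            assert sp.roc_youden(f(scores), labels).auc == pytest.approx(base, abs=1e-12)


class TestCorrelate:
    def test_perfect_linear(self):
        r, p, n = sp.correlate([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_monotone_nonlinear_spearman(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [np.exp(-v) for v in x]
        r, _, _ = sp.correlate(x, y, method="spearman")
        assert r == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        r, p, n = sp.correlate(x, y)
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        t = r_hand * np.sqrt((n - 2) / (1 - r_hand**2))
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t), df=n - 2)
        assert r == pytest.approx(r_hand, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            sp.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sp.correlate([1.0, 2.0], [1.0, 2.0])


class TestBootstrapIcv:
    def test_single_replicate_rejected(self, small_cohort):
        _, images, manifest, _ = small_cohort
        with pytest.raises(ValueError):
            sp.bootstrap_icv(
                images, manifest["group"], patient_label="AD", control_label="NC",
                n_replicates=1,
            )

    def test_noiseless_phantom_entire_mask_suprathreshold(self):
        """With no voxel noise and no smoothing the SRP is rank one, every
        replicate recovers the same pattern, and |ICV| is effectively
        infinite mask-wide."""
        cfg = small_config(noise_sd=0.0, smooth_fwhm_mm=0.0, n_per_group=6)
        images, manifest, _ = sp.simulate_cohort(cfg)
        icv = sp.bootstrap_icv(
            images, manifest["group"], patient_label="AD", control_label="NC",
            n_replicates=20, seed=3,
        )
        assert icv.suprathreshold[icv.mask.data].all()

    def test_blob_centers_reliable_under_noise(self):
        cfg = small_config(n_per_group=10, seed=2)
        images, manifest, _ = sp.simulate_cohort(cfg)
        icv = sp.bootstrap_icv(
            images, manifest["group"], patient_label="AD", control_label="NC",
            n_replicates=60, seed=9,
        )
        for blob in cfg.blobs:
            c = tuple(int(round(v)) for v in blob.center)
            assert abs(icv.icv[c]) >= 1.96

    def test_null_phantom_shows_no_blob_enrichment(self):
        """With effect_delta = 0 the derived weights are noise, so reliable
        voxels (if any) should not concentrate in the planted blob regions."""
        from scipy import stats as sps

        passes = 0
        for seed in (11, 12, 13):
            cfg = small_config(effect_delta=0.0, n_per_group=8, seed=seed)
            images, manifest, truth = sp.simulate_cohort(cfg)
            icv = sp.bootstrap_icv(
                images, manifest["group"], patient_label="AD", control_label="NC",
                n_replicates=60, seed=seed,
            )
            in_mask = icv.mask.data
            blob_region = np.abs(truth.pattern_map) > 0.001
            sup = icv.suprathreshold
            n_sup = int(sup[in_mask].sum())
            if n_sup == 0:
                passes += 1
                continue
            frac_blob = blob_region[in_mask].mean()
            k_blob = int((sup & blob_region)[in_mask].sum())
            p = sps.binomtest(k_blob, n_sup, frac_blob).pvalue
            if p > 0.01:
                passes += 1
        assert passes >= 2


class TestKfoldTopography:
    def test_noiseless_folds_agree_perfectly(self):
        # no noise and no smoothing: the cohort is exactly rank one, so every
        # fold derives the identical pattern
        cfg = small_config(noise_sd=0.0, smooth_fwhm_mm=0.0, n_per_group=9)
        images, manifest, _ = sp.simulate_cohort(cfg)
        corrs = sp.kfold_topography(
            images, manifest["group"], patient_label="AD", control_label="NC", k=3, seed=0
        )
        assert corrs.shape == (3,)
        assert np.all(corrs > 1 - 1e-10)

    def test_noisy_folds_strongly_correlated(self, small_cohort):
        _, images, manifest, _ = small_cohort
        corrs = sp.kfold_topography(
            images, manifest["group"], patient_label="AD", control_label="NC", k=2, seed=1
        )
        assert np.all(corrs >= 0.8)

    def test_k_exceeding_group_size_rejected(self, small_cohort):
        _, images, manifest, _ = small_cohort
        with pytest.raises(ValueError):
            sp.kfold_topography(
                images, manifest["group"], patient_label="AD", control_label="NC", k=50,
            )
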