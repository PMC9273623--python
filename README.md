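# ssm-pattern

Derivation, scoring and validation of disease-related metabolic covariance
patterns from volumetric brain PET data, using the scaled subprofile model
with principal component analysis (SSM/PCA).

Neurodegenerative diseases such as Alzheimer's disease express themselves in
FDG-PET as a *spatial covariance pattern*: a network of regions whose
metabolic activity rises and falls together across subjects, typically
relative hypometabolism in temporoparietal and posterior midline cortex
co-varying with relative hypermetabolism elsewhere (e.g. cerebellum). This
package is for researchers who want to derive such a pattern from a
patient/control cohort, score its expression in new scans on a common Z
scale, and quantify its reliability — without depending on proprietary
analysis suites.

## The model

For subject *i* and masked voxel *v*, let `L[i,v] = ln I[i,v]` be the
log-intensity. The SSM removes the subject's global activity and the
cohort's mean anatomy by double centering:

```
SRP[i,v] = L[i,v] − mean_v L[i,·] − GMP[v]
```

where `GMP` (group mean profile) is the voxel-wise mean of the row-centred
log profiles. Because scanner and dose effects are multiplicative in
intensity, they are additive in `L` and vanish in the row-centring step —
all downstream scores are exactly invariant to global image scaling.

PCA of the SRP matrix (via the small subjects × subjects covariance) yields
components with loadings `P_k` and variance fractions (VAF). Components with
VAF ≥ 5% are screened in; logistic regressions of group on component scores
are compared by AIC, and the winning subset's loadings are combined with the
fitted coefficients into a single unit-norm voxel weight map **w** — the
disease-related pattern — oriented so patients score higher than controls.

A new scan is scored by topographic profile rating (TPR):

```
raw = (l − mean(l) − GMP) · w ,   z = (raw − mean_ref) / sd_ref
```

with the reference mean/SD taken from the derivation controls, so the
reference group sits at z = 0 ± 1 by construction.

Validation tools: voxel-wise bootstrap reliability maps (inverse coefficient
of variation of **w** over within-group resamples, thresholded at |ICV| ≥
1.96), k-fold topography cross-validation, the exact Fisher–Pitman
permutation test on group scores, ROC analysis with the Youden-index
cut-point, and clinical correlations.

A phantom generator (`ssm_pattern.phantom`) simulates two-group cohorts of
smoothed, positive brain-like volumes with a planted covariance pattern,
subject-wise global scaling factors, voxel noise and an MMSE-like cognition
score, providing known ground truth for every stage.

## Worked example

```python
import numpy as np
import ssm_pattern as sp

cfg = sp.default_config(seed=0)                  # 20 patients + 20 controls
images, manifest, truth = sp.simulate_cohort(cfg)
res = sp.derive_pattern(
    images, manifest["group"].tolist(),
    subject_ids=manifest["subject_id"].tolist(),
    patient_label="AD", control_label="NC",
)
print("VAF of leading components:", np.round(res.pcs.vaf[:4], 3))
print("selected components:", res.pattern.selected_components)

planted = res.pattern.mask.extract(truth.pattern_map)
print("corr(derived, planted):",
      round(np.corrcoef(res.pattern.weights, planted)[0, 1], 3))

is_ad = (manifest["group"] == "AD").to_numpy()
print("mean z  NC: %.2f   AD: %.2f"
      % (res.z_scores[~is_ad].mean(), res.z_scores[is_ad].mean()))

imgs2, man2, _ = sp.simulate_cohort(sp.default_config(seed=99))
table = sp.score_cohort(imgs2, res.pattern, man2["subject_id"], man2["group"])
roc = sp.roc_youden(table["z"], (table["group"] == "AD").to_numpy())
print("held-out AUC: %.3f" % roc.auc)

r, p, n = sp.correlate(res.z_scores[is_ad], manifest.loc[is_ad, "clinical_score"])
print("z vs cognition in patients: r(%d) = %.2f, p = %.1e" % (n - 2, r, p))
```

prints

```
VAF of leading components: [0.703 0.019 0.018 0.016]
selected components: [0]
corr(derived, planted): 0.969
mean z  NC: -0.00   AD: 4.24
held-out AUC: 1.000
z vs cognition in patients: r(18) = -0.83, p = 5.6e-06
```

The first component carries 70% of the residual variance and is, alone, the
AIC-preferred discriminator; its weight map correlates 0.97 with the planted
truth. Controls sit at z = 0 by construction; patients express the pattern
about four reference standard deviations more strongly, the pattern
separates a held-out cohort perfectly, and higher expression tracks lower
cognition, as expected from the generative model.

The same pipeline is available from the shell:

```
ssm-pattern simulate --out cohort/ --seed 0
ssm-pattern derive   --manifest cohort/manifest.tsv --out pattern/
ssm-pattern score    --pattern pattern/ --manifest cohort/manifest.tsv --out scores.tsv
ssm-pattern validate --pattern pattern/ --manifest cohort/manifest.tsv \
                     --bootstrap 200 --kfold 3 --out report/
```

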