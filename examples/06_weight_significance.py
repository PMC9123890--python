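"""Permutation test on model weights: which regions does a model rely on?

The model is retrained with shuffled targets to build a null
distribution of each region's weight; the observed weights are compared
against it (empirical permutation p, plus the classical Welch t-test
between the null draws and the 10 cross-validation weights).
"""

import numpy as np

from sparekit import (
    GeneratorConfig,
    SpareModelSpec,
    generate_cohort,
    permutation_weight_test,
    train_spare_ba,
)

config = GeneratorConfig(seed=3)
for study in config.studies:
    study.n_participants = 150

roi, pheno, truth = generate_cohort(config)
cn_ids = pheno.loc[pheno["clinical_dx"] == "CN", "scan_id"].tolist()

ens = train_spare_ba(roi, pheno, cn_ids, version="BA1", seed=4)
spec = SpareModelSpec(task="regression", training_cohort=cn_ids)
report = permutation_weight_test(spec, roi, pheno, ens, n_perm=200, seed=5)

age_rois = roi.columns[truth.age_roi_indices]
null_rois = roi.columns[
    np.setdiff1d(np.arange(145), np.union1d(truth.age_roi_indices, truth.ad_roi_indices))
]
print(f"age-affected regions with adjusted permutation p < 0.05: "
      f"{(report.loc[age_rois, 'p_perm_adj'] < 0.05).sum()} / {len(age_rois)}")
print(f"no-signal regions flagged at the same threshold:          "
      f"{(report.loc[null_rois, 'p_perm_adj'] < 0.05).sum()} / {len(null_rois)}")
print("\nstrongest five regions by |cross-validated weight|:")
print(report["cv_mean"].abs().sort_values(ascending=False).head(5).round(3).to_string())
print("\nThe planted ageing regions light up; pure-noise regions do not.")
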