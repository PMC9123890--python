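"""Train a brain-age SVR and a disease-score SVM on a synthetic cohort.

SPARE-BA is the age predicted from the 145 z-scored region volumes by a
linear support-vector regression; SPARE-AD is the signed distance from
a linear max-margin hyperplane separating controls from cases.
"""

from sparekit import (
    GeneratorConfig,
    build_groups,
    call_molecular_status,
    generate_cohort,
    match_groups,
    score_out_of_sample,
    train_spare_ad,
    train_spare_ba,
)

config = GeneratorConfig(seed=5)
for study in config.studies:
    study.n_participants = 300

roi, pheno, _ = generate_cohort(config)
groups = build_groups(pheno, call_molecular_status(pheno))
cn, ad, _ = match_groups(groups["CN"], groups["ClinicalAD"], pheno, seed=1)

ba = train_spare_ba(roi, pheno, cn, version="BA1", seed=2)
print("brain-age model, 10-fold cross-validated fit:")
print({k: round(v, 2) for k, v in ba.metrics.items()})

svm = train_spare_ad(roi, pheno, cn, ad, version="AD1", seed=3)
print("\ndisease classifier, cross-validated:")
print({k: round(v, 3) for k, v in svm.metrics.items()})

# score scans that never entered training: mean of the 10 fold models
held_out = roi.loc[[s for s in roi.index if s not in svm.training_scan_ids]]
scores = score_out_of_sample(svm, held_out.iloc[:5])
print("\nSPARE-AD scores of five unseen scans (positive = AD-like):")
print(scores.round(2).to_string())
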