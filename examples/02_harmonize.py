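"""Remove study batch effects while preserving the age trend.

Harmonization fits a cubic-spline age trend plus a sex term on
cognitively normal scans only, then removes the study-wise residual
offsets; the train/test variant avoids information leakage.
"""

import numpy as np

from sparekit import GeneratorConfig, StudyConfig, fit_harmonizer, apply_harmonizer, generate_cohort

config = GeneratorConfig(
    studies=[
        StudyConfig(name="SITE_1", n_participants=300, offset=150.0),
        StudyConfig(name="SITE_2", n_participants=300, offset=-120.0),
    ],
    seed=7,
)
roi, pheno, truth = generate_cohort(config)

model = fit_harmonizer(roi, pheno)
harmonized = apply_harmonizer(model, roi, pheno)

est = model.study_offset["SITE_1"] - model.study_offset["SITE_2"]
print(f"planted between-study offset: 270.0 mm^3")
print(f"estimated offset (mean over ROIs): {est.mean():.1f} mm^3")

# the age trend survives: refit the slope of one strongly ageing region
idx = int(truth.age_roi_indices[0])
ages = pheno["age"].to_numpy()
X = np.column_stack([np.ones(len(ages)), ages])
slope = np.linalg.lstsq(X, harmonized.iloc[:, idx].to_numpy(), rcond=None)[0][1]
print(f"planted age slope for {roi.columns[idx]}: {truth.age_slope[idx]:.1f} mm^3/yr")
print(f"slope refitted on harmonized data:     {slope:.1f} mm^3/yr")
print("\nBatch offsets are gone; the biological age trend is untouched.")
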