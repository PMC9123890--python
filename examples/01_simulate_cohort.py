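"""Simulate a small multi-study cohort and inspect its structure.

The generator plants linear age atrophy on 40 regions, disease atrophy
on 30 regions overlapping the first set, study batch effects and
biomarker emissions driven by a latent disease severity.
"""

from sparekit import GeneratorConfig, generate_cohort

config = GeneratorConfig(seed=42)
for study in config.studies:
    study.n_participants = 200  # keep the example quick

roi, pheno, truth = generate_cohort(config)

print(f"scans: {len(roi)}, ROI columns: {roi.shape[1]}")
print("\nclinical diagnoses:")
print(pheno["clinical_dx"].value_counts().to_string())
print("\ntrue amyloid positivity by clinical label:")
print(
    truth.participants.groupby("clinical_dx_baseline")["amyloid_positive"]
    .mean()
    .round(2)
    .to_string()
)
print("\nbiomarker availability (fraction of scans measured):")
print(pheno[["abeta42", "pib_suvr", "florbetapir_suvr", "csf_ttau"]]
      .notna().mean().round(2).to_string())
print(
    "\nThe amyloid rate rises with the clinical label and, among CN"
    "\nparticipants, with age - the asymptomatic pathology the cohort"
    "\nselection below is designed to screen out."
)
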