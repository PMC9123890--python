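# Methods

`sparekit` implements a pipeline for deriving *disentangled* imaging
signatures of typical brain ageing (SPARE-BA) and Alzheimer's disease
(SPARE-AD) from regional brain volumes, together with a synthetic
multi-study cohort generator that makes every stage testable without
access to consortium data. This note records the models, the default
parameters and the design decisions, in that order of importance.

## The scientific problem

A brain-age model (support-vector regression of chronological age on
regional volumes, trained on cognitively normal (CN) adults) and a
disease classifier (support-vector machine separating CN from
Alzheimer's disease (AD), scored as signed hyperplane distance) share
many informative brain regions: medial temporal structures and
ventricular spaces change with both normal ageing and AD. As a result
the *brain-age gap* (predicted minus chronological age, "Gap") and the
disease score are correlated, and neither can be read as a clean
measure of its own process.

The pipeline disentangles the two axes by re-defining the training
samples rather than the models:

| Version | Training sample | Model |
|---|---|---|
| BA1 / AD1 | clinically defined CN vs clinical AD | SVR on CN; SVM CN-vs-AD |
| BA2 / AD2 | amyloid-negative CN (A-/CN) vs amyloid-positive AD continuum | SVR on A-/CN; SVM A-/CN-vs-continuum |
| BA3 | combined A-/CN + AD continuum | SVR (age regression) |
| AD3 | — | AD2 with BA3 linearly regressed out (10-fold) |

Adding AD-continuum cases to the age model's training sample injects
disease-driven variance into the disease-affected regions; since that
variance is unrelated to age, the regression stops relying on those
regions and the resulting Gap no longer tracks disease.

## Cohort construction

**Molecular status.** Amyloid status is called per scan from CSF
amyloid-beta 42, PiB PET and florbetapir PET with conservative
two-threshold bands (defaults: florbetapir A+ >= 1.15 / A- <= 1.05 SUVR;
PiB A+ >= 1.54 / A- <= 1.25; CSF amyloid-beta 42 A+ <= 178 / A- >= 200,
low = positive). Values inside a band are "unclear" and never enter a
molecular group. Disagreeing measures resolve to "unclear" by default
(a priority order CSF > PET is available). Tau status (T+) uses a CSF
total-tau cutoff; when none is configured the study-specific 75th
percentile of CN values is used and logged.

**Groups.** CN and ClinicalAD are defined purely by the clinical label;
A-/CN requires a confirmed negative amyloid call; the AD continuum pools
A+ clinical AD, A+ MCI, and A+T+ CN participants. One scan per
participant: controls contribute their last qualifying scan, cases their
first (better age overlap and harder, more borderline training
examples). Participants qualifying for a case group are excluded from
the corresponding control group so matched pairs stay disjoint.

**Matching.** Case/control pairs are matched by sex-stratified greedy
nearest-age pairing with random tie-breaking, then verified with a
two-sample t-test on age and a chi-squared test on sex (both must exceed
p = 0.2); worst pairs are pruned until the tests pass. The two pairs are
then re-matched at a common size so all four groups share one n.

## Harmonization

Study (batch) effects are removed per region by a location model
anchored on CN scans only: a pooled cubic B-spline age trend (interior
knots at ages 60/70/80 over the 48-95 range) plus an additive sex term
is fitted to CN scans; each study's offset is the mean CN residual, and
an optional scale factor (off by default) is the residual-SD ratio.
Application subtracts the study offset and then the CN-estimated sex
difference; the age trend itself is never removed. This is a
location(-scale) variant of CN-anchored trend-preserving harmonization;
empirical-Bayes shrinkage across regions is deliberately out of scope.
For a train/test split, the training sample is harmonized on its own and
the test sample with a model fitted on the union, so training rows are
never influenced by test data while small test batches borrow strength.

## Models

All models are linear, trained with 10-fold cross-validation on one scan
per participant. Within each fold the 145 harmonized volumes are
z-scored with means/SDs from the *control members of the training
folds*. Regression (SPARE-BA) is epsilon-insensitive linear SVR
(C = 1, epsilon = 0.1, the age target centred before fitting because
liblinear penalizes the intercept); folds are age-stratified.
Classification (SPARE-AD) is a linear hinge-loss SVM (C = 1); folds are
class-stratified; the score is the geometric signed distance
(weights normalized to unit norm), oriented so cases score positive.
Held-out predictions give the cross-validated metrics (RMSE/MAE/R^2,
or AUC and zero-threshold accuracy). Scans outside training are scored
by all ten fold models (each with its own normalizers) and averaged;
training scans always use their held-out score. AD3 = AD2 minus a
10-fold cross-validated linear fit on BA3. A zero-variance region in
the controls raises an error rather than being silently dropped.
The C/epsilon defaults are deliberately plain; a config override exists,
and no inner-loop hyperparameter search is run by default.

## Evaluation statistics

* One evaluation scan per participant, chosen at random under a seed
  while favouring AD- over MCI- over CN-labelled scans.
* Pearson correlation between each Gap/AD pair; the change between
  model generations is tested with the F statistic on Fisher
  z-transformed coefficients, `(z1-z2)^2 / (1/(n1-3) + 1/(n2-3))`,
  referred to a chi-squared(1) tail. The pairs share participants, so
  this independence-based test is approximate; it is nevertheless the
  default, with Williams' dependent-correlation t-test available as an
  option.
* Separability: balanced accuracy at the operating point where
  sensitivity equals specificity, found by linear interpolation between
  achievable operating points (deterministic and resolution-independent),
  plus Cohen's d with (n-1)-weighted pooled SD.
* Spearman tables between scores and clinical/molecular/genetic
  variables (t-approximation p-values, adequate at n >= 10), with
  Benjamini-Hochberg adjustment across the whole table; molecular assays
  whose scales differ across studies are analysed within the single
  study contributing the most complete pairs.
* Nested Gaussian linear models are compared with the likelihood-ratio
  statistic `n * log(RSS_reduced / RSS_full)` on a chi-squared tail with
  df = the number of dropped predictors.

## Weight analysis

Each model is retrained `n_perm` times (default 200; raise for finer
p-value resolution) with its supervised target shuffled - ages for the
regressors, group labels for the classifiers - one full-sample fit per
permutation. Two per-region significance measures are reported:

* `p_perm`: the empirical two-sided permutation p-value of the observed
  full-sample weight against the shuffled-target null. For a region
  carrying no signal this test is calibrated by exchangeability, and the
  type-I error check in the test suite exercises exactly this quantity.
* `p_welch`: the two-tailed Welch t-test between the permutation null
  and the 10 cross-validation weights. This classical comparison is
  reported for completeness but is *anti-conservative* for null regions:
  the 10 CV weights are fitted on 90%-overlapping data, so their
  empirical spread wildly understates the sampling variance of their
  mean. It is useful as a powerful ranking statistic, not as a
  calibrated error rate.

Spearman maps between region volumes and scores, and per-region
Fisher-z tests of correlation changes between model versions (BH
adjusted across the 145 regions, with a -log10 export column), complete
the picture.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume;
it is a study in miniature, not a simulation of MRI.

**Regions and effects.** 145 named regions. Age atrophy is planted on
40 regions and disease atrophy on 30, overlapping in
`ceil(overlap_fraction * 30)` regions (default 15). The overlap regions
(hippocampus, middle temporal gyrus, inferior lateral ventricles, ...)
age at -30..-18 mm^3/year and lose 450-600 mm^3 at full disease
severity - the medial-temporal pattern in which disease-related loss
rivals a lifetime of ageing. Age-only regions (cerebellum, internal
capsule, ...) age at -26..-10 mm^3/year; disease-only regions
(entorhinal, inferior temporal, ...) lose 290-480 mm^3 at full severity.
Ventricular regions expand instead of shrinking. Sex adds 3% of
baseline volume for males. Per-region Gaussian noise has SD 420 mm^3,
deliberately large relative to any single region's signal: no single
region is very informative, mirroring real regional volumes, and
multivariate models must pool - which is what entangles them.

**Latent state.** Each participant carries: a disease severity in
[0, 1] (zero for amyloid-negative CN; Beta-distributed otherwise, mild
for preclinical A+ CN, intermediate and wide for A+ MCI, high for A+
AD); a global ageing offset in years (small SD, elevated in
amyloid-positive dementia - clinical symptoms reflect mixed pathology);
a "vascular-like" offset applied only to the age-only regions
(hippocampal-sparing comorbid neurodegeneration, the dominant pattern in
amyloid-negative clinical dementia); a diffuse-atrophy factor (tissue
down, ventricles up) and a global scale factor shared across all
regions. Clinical diagnosis is an imperfect proxy: CN participants are
amyloid-positive with a probability rising linearly from 0.10 at age 50
to 0.50 at age 90; 85% of clinical AD and 55% of MCI are
amyloid-positive; severity above configurable thresholds upgrades the
label (CN -> MCI -> AD), never the reverse.

**Biomarkers.** Amyloid and tau assays are linear-plus-noise emissions
of latent amyloid/tau burdens, calibrated so the default conservative
cutoffs reproduce sensible positivity rates with a genuine "unclear"
band; availability patterns differ by study (CSF-only, PET-only, mixed).
Psychometric scores are linear in age, severity and the ageing offsets
with noise and caps (MMSE-like integer score capped at 30, plus
continuous scales). APOE e4 allele counts are binomial with a higher
allele frequency in the amyloid-positive.

**Studies.** Three studies with additive offsets (+120/-90/+40 mm^3),
unit scales, different diagnostic mixes and biomarker availability;
1100 participants each by default, yielding matched training groups
near n = 700 - close to the source-scale design - because smaller
defaults proved too noisy for the qualitative weight-shift contrasts to
be stable (support-vector weight estimates at n ~= 400 fluctuate more
across draws than the between-version differences being demonstrated).
Longitudinal mode draws several scans per participant with 1-2.5 year
gaps, progressing severity for amyloid-positive participants and
non-improving diagnoses.

**What the generator does not emulate.** Image acquisition and
segmentation; spatially correlated noise beyond the global factors;
scanner-level nesting below study; assay units beyond rank/threshold
fidelity; within-participant correlated noise beyond the shared latent
state. Passing tests therefore demonstrate that the *pipeline logic*
behaves as designed under known ground truth - not that the same effect
sizes would be observed in any particular real cohort.

## Numerical and reproducibility choices

* One master seed drives everything; each stage derives its own seed as
  a stable SHA-256 hash of the stage name and the master seed, so stages
  can be rerun independently yet reproducibly. All derived seeds are
  below 2^31.
* The test suite and the acceptance script run the default pipeline at
  master seed 0 with permutation analysis disabled; that run takes a few
  minutes on one CPU. The error-calibration checks use small null
  cohorts (220 CN participants, 200 permutations, 15 generator seeds)
  so that the ~2000-replicate Monte-Carlo stays inside a coffee break.
* Degenerate inputs fail loudly: studies without CN scans, unseen study
  labels at harmonization time, constant regions in the controls,
  single-class folds, overlapping train/test scan sets, empty groups.
* Matching ties, fold assignment and evaluation-scan selection are
  randomized under derived seeds; everything else is deterministic given
  the data.

## Known limitations

* The Fisher-z comparison ignores the dependence between correlations
  sharing a sample; the optional Williams test addresses the two-
  correlations-one-shared-variable case only.
* The matcher is greedy, not optimal; it can prune more members than an
  optimal-assignment matcher would at the same verification threshold.
* On synthetic cohorts the *first* disentangling step does not reliably
  reproduce: the clinically trained and the molecularly trained
  generations come out about equally entangled (the training-sample
  draw decides which is slightly worse), whereas on the real consortium
  data the clinically trained generation was clearly more entangled.
  Channel decomposition against the planted ground truth shows why:
  under a robust epsilon-insensitive SVR, contaminating the CN training
  sample with preclinical atrophy only *attenuates* the age model's use
  of disease-affected regions (it cannot inflate it), and a classifier
  trained on a pure molecular severity contrast reads the latent
  severity at least as well as the clinically trained one. Whatever
  drove the real first-step difference (plausibly non-linear effects,
  richer pathology mixtures, or study-composition differences between
  the clinically and molecularly defined samples) is not captured by a
  linear volume generator. The second step - the collapse of the
  entanglement when disease-continuum cases enter the age model's
  training sample - reproduces robustly, and is the central claim.
* The published coefficients of the original consortium analyses are
  not reproducible here by construction: the synthetic cohort shares
  the *structure*, not the data. Quantities reported by the acceptance
  script are properties of the synthetic default conditions.
* With `adjust_scale` enabled the scale factors are estimated per study
  without shrinkage; for very small studies the location-only default
  is safer.
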