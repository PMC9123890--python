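"""Synthetic multi-study cohort generator with a planted ground truth.

Real consortium data behind imaging signatures of brain ageing and
Alzheimer's disease (AD) cannot be redistributed, so every analysis in
this package is exercised on simulated cohorts whose statistical
structure mirrors what those analyses assume:

* per-scan volumes of 145 named brain regions (mm^3) with linear age
  atrophy on an age-affected subset, disease atrophy on an AD-affected
  subset that partially overlaps it, additive sex differences, additive
  (and optionally multiplicative) study batch effects, and Gaussian
  measurement noise;
* a latent, per-participant disease *severity* in [0, 1] that drives
  both regional atrophy and molecular biomarkers (CSF amyloid-beta 42,
  amyloid PET SUVRs, CSF tau, tau PET SUVRs);
* clinical diagnoses (CN / MCI / AD) that are imperfect proxies of the
  molecular state: a fraction of cognitively normal participants is
  amyloid-positive (increasingly so with age) and a fraction of
  clinical-AD participants is amyloid-negative, carrying advanced
  brain ageing rather than amyloid-driven atrophy;
* optional longitudinal scans with strictly increasing ages and
  non-improving diagnoses.

Every planted parameter is recorded in a :class:`GroundTruth` ledger so
that downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rois import DEFAULT_ROI_NAMES, N_ROIS, is_ventricle

AGE_CENTER = 70.0  # years; all linear age parameterizations are centred here

DX_LEVELS = ("CN", "MCI", "AD")
_DX_ORD = {"CN": 0, "MCI": 1, "AD": 2}

#: amyloid biomarker emissions: measure -> (intercept, slope on burden, noise SD)
DEFAULT_AMYLOID_EMISSION: dict[str, tuple[float, float, float]] = {
    "florbetapir_suvr": (0.90, 0.50, 0.02),
    "pib_suvr": (0.815, 1.45, 0.05),
    "abeta42": (233.0, -110.0, 4.0),
}

#: tau biomarker emissions: measure -> (intercept, slope on tau burden, noise SD)
DEFAULT_TAU_EMISSION: dict[str, tuple[float, float, float]] = {
    "csf_ttau": (40.0, 100.0, 8.0),
    "csf_ptau": (18.0, 42.0, 4.0),
    "taupet_entorhinal": (1.05, 0.90, 0.07),
    "taupet_inferior_temporal": (1.00, 0.80, 0.07),
}

#: severity Beta(a, b) for amyloid-positive participants, by clinical diagnosis
DEFAULT_SEVERITY_BETA: dict[str, tuple[float, float]] = {
    "CN": (1.2, 10.0),  # preclinical: barely measurable atrophy
    "MCI": (2.8, 4.2),
    "AD": (8.0, 2.5),
}

#: severity Beta(a, b) for amyloid-negative impaired participants:
#: non-amyloid medial-temporal pathologies (hippocampal sclerosis,
#: TDP-43) atrophy the same regions at moderate intensity.  A- CN
#: severity is exactly zero by construction
DEFAULT_SEVERITY_BETA_ANEG: dict[str, tuple[float, float]] = {
    "MCI": (1.5, 8.5),
    "AD": (2.0, 8.0),
}

#: global ageing-offset (years) mean and SD by (diagnosis, amyloid-positive).
#: Clinical diagnosis reflects cognitive symptoms from *any* cause, so the
#: clinically demented carry elevated background brain ageing (mixed
#: pathology) on top of any amyloid-driven atrophy
DEFAULT_AGEING_OFFSET: dict[tuple[str, bool], tuple[float, float]] = {
    ("CN", False): (0.0, 1.5),
    ("CN", True): (0.0, 1.5),
    ("MCI", False): (3.0, 1.5),
    ("MCI", True): (1.5, 1.5),
    ("AD", False): (5.0, 2.5),
    ("AD", True): (2.5, 1.5),
}

#: additional "vascular-like" ageing offset (years) applied only to the
#: age-affected regions *outside* the disease-affected set (hippocampal-
#: sparing comorbid neurodegeneration); this is what amyloid-negative
#: clinically demented participants carry instead of amyloid pathology
DEFAULT_VASCULAR_OFFSET: dict[tuple[str, bool], tuple[float, float]] = {
    ("CN", False): (0.0, 0.0),
    ("CN", True): (0.0, 0.0),
    ("MCI", False): (2.5, 1.5),
    ("MCI", True): (0.5, 1.0),
    ("AD", False): (5.0, 2.5),
    ("AD", True): (0.5, 1.0),
}

#: probability of being amyloid-positive given a non-CN clinical diagnosis
DEFAULT_AMYLOID_GIVEN_DX: dict[str, float] = {"MCI": 0.55, "AD": 0.85}

#: psychometric emissions: name -> (intercept, age slope, severity slope,
#: ageing-offset slope, noise SD, lower cap, upper cap, round to integer)
DEFAULT_PSYCHOMETRICS: dict[str, tuple] = {
    "mmse": (29.3, -0.02, -7.5, -0.15, 0.9, 0.0, 30.0, True),
    "adas_cog": (8.0, 0.06, 28.0, 0.50, 3.0, 0.0, None, False),
    "logical_memory": (12.0, -0.05, -9.0, -0.30, 2.5, 0.0, None, False),
}

BIOMARKER_COLUMNS = list(DEFAULT_AMYLOID_EMISSION) + list(DEFAULT_TAU_EMISSION)


@dataclass
class StudyConfig:
    """One simulated study (acquisition batch) in the consortium."""

    name: str
    n_participants: int = 1100
    #: additive per-ROI location shift, mm^3 (scalar is broadcast)
    offset: float | np.ndarray = 0.0
    #: multiplicative per-ROI scale (scalar is broadcast); 1.0 = none
    scale: float | np.ndarray = 1.0
    #: marginal probabilities of clinical CN / MCI / AD at baseline
    dx_mix: tuple[float, float, float] = (0.55, 0.25, 0.20)
    #: probability that each biomarker column is measured for a participant
    availability: Mapping[str, float] = field(default_factory=dict)


def default_studies() -> list[StudyConfig]:
    """Three studies with distinct batch effects, case mixes and biomarker
    availability patterns (CSF-only, PET-only, mixed), emulating the
    heterogeneity of a multi-study ageing consortium."""
    return [
        StudyConfig(
            name="STUDY_A",
            n_participants=1100,
            offset=120.0,
            dx_mix=(0.45, 0.30, 0.25),
            availability={
                "abeta42": 0.60,
                "florbetapir_suvr": 0.70,
                "pib_suvr": 0.25,
                "csf_ttau": 0.60,
                "csf_ptau": 0.55,
                "taupet_entorhinal": 0.25,
                "taupet_inferior_temporal": 0.25,
            },
        ),
        StudyConfig(
            name="STUDY_B",
            n_participants=1100,
            offset=-90.0,
            dx_mix=(0.70, 0.15, 0.15),
            availability={"abeta42": 0.80, "csf_ttau": 0.80, "csf_ptau": 0.70},
        ),
        StudyConfig(
            name="STUDY_C",
            n_participants=1100,
            offset=40.0,
            dx_mix=(0.55, 0.25, 0.20),
            availability={"pib_suvr": 0.70, "florbetapir_suvr": 0.50},
        ),
    ]


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    Effect maps left as ``None`` are filled by :func:`default_effect_maps`,
    which plants age slopes on 40 regions and AD effects on 30 regions
    whose overlap with the age-affected set is ``ceil(overlap_fraction *
    30)`` regions.
    """

    studies: list[StudyConfig] = field(default_factory=default_studies)
    age_range: tuple[float, float] = (48.0, 95.0)
    sex_ratio: float = 0.5  # fraction male
    roi_names: Sequence[str] = field(default_factory=lambda: list(DEFAULT_ROI_NAMES))
    baseline_map: np.ndarray | None = None  # mm^3
    age_slope_map: np.ndarray | None = None  # mm^3 / year
    sex_effect_map: np.ndarray | None = None  # mm^3, male minus female
    ad_effect_map: np.ndarray | None = None  # mm^3 at severity 1
    n_age_rois: int = 40
    n_ad_rois: int = 30
    overlap_fraction: float = 0.5
    noise_sd_map: np.ndarray | float = 420.0  # mm^3
    #: SD of a per-scan multiplicative global volume factor (head-size-like,
    #: same sign everywhere); correlated "noise" across all ROIs
    global_scale_sd: float = 0.005
    #: SD of a per-scan diffuse-atrophy factor, as a fraction of baseline
    #: volume: tissue regions shrink while ventricular CSF expands.  Both
    #: the brain-age and the disease models read this factor in the same
    #: direction (more atrophy = older-looking and more disease-like)
    atrophy_factor_sd: float = 0.006
    quadratic_age: bool = False  # add curvature to the age trend
    quadratic_coef_map: np.ndarray | None = None  # mm^3 / year^2
    severity_beta: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_BETA)
    )
    severity_beta_aneg: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_BETA_ANEG)
    )
    ageing_offset: Mapping[tuple[str, bool], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGEING_OFFSET)
    )
    vascular_offset: Mapping[tuple[str, bool], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VASCULAR_OFFSET)
    )
    amyloid_given_dx: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMYLOID_GIVEN_DX)
    )
    #: probability a CN participant is amyloid-positive, linear between
    #: (rate at age 50, rate at age 90); a callable age->prob also works
    asymptomatic_rate: tuple[float, float] | Callable[[np.ndarray], np.ndarray] = (0.10, 0.50)
    amyloid_emission: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AMYLOID_EMISSION)
    )
    tau_emission: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TAU_EMISSION)
    )
    tau_positive_threshold: float = 0.45  # on latent tau burden
    psychometrics: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_PSYCHOMETRICS)
    )
    apoe4_allele_prob: tuple[float, float] = (0.12, 0.35)  # (A-, A+)
    #: distribution of scans per participant, {count: probability}
    scans_per_participant: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    followup_years: tuple[float, float] = (1.0, 2.5)  # uniform inter-scan gap
    progression_rate: tuple[float, float] = (0.02, 0.08)  # severity / year, A+ only
    dx_thresholds: tuple[float, float] = (0.55, 0.80)  # severity bands CN|MCI|AD
    #: multiplicative age ramp on preclinical (A+ CN) severity, linear
    #: between (value at 48, value at 95): amyloid-positive CN accumulate
    #: neurodegeneration with age, with little extra scatter at fixed age
    preclinical_age_ramp: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if len(self.roi_names) != N_ROIS:
            raise ValueError(f"exactly {N_ROIS} ROI labels are required, got {len(self.roi_names)}")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("ROI labels must be unique")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        if not self.studies:
            raise ValueError("at least one study is required")
        self._fill_default_maps()
        if np.any(self.baseline_map <= 0):
            raise ValueError("all baseline volumes must be positive")

    def _fill_default_maps(self) -> None:
        n = len(self.roi_names)
        defaults = default_effect_maps(
            self.roi_names, self.n_age_rois, self.n_ad_rois, self.overlap_fraction
        )
        if self.baseline_map is None:
            self.baseline_map = defaults["baseline"]
        self.baseline_map = np.broadcast_to(np.asarray(self.baseline_map, float), (n,)).copy()
        if self.age_slope_map is None:
            self.age_slope_map = defaults["age_slope"]
        self.age_slope_map = np.asarray(self.age_slope_map, float)
        if self.sex_effect_map is None:
            self.sex_effect_map = 0.03 * self.baseline_map
        self.sex_effect_map = np.broadcast_to(np.asarray(self.sex_effect_map, float), (n,)).copy()
        if self.ad_effect_map is None:
            self.ad_effect_map = defaults["ad_effect"]
        self.ad_effect_map = np.asarray(self.ad_effect_map, float)
        if self.quadratic_coef_map is None:
            # mild curvature on the age-affected set when enabled: atrophy
            # accelerates in late life
            self.quadratic_coef_map = np.where(
                self.age_slope_map != 0, 0.015 * self.age_slope_map, 0.0
            )
        self.noise_sd_map = np.broadcast_to(np.asarray(self.noise_sd_map, float), (n,)).copy()
        self.atrophy_load_map = self.baseline_map * np.array(
            [1.5 if is_ventricle(nm) else -1.0 for nm in self.roi_names]
        )

    # -- derived index sets ------------------------------------------------
    @property
    def age_roi_indices(self) -> np.ndarray:
        return np.flatnonzero(self.age_slope_map != 0)

    @property
    def ad_roi_indices(self) -> np.ndarray:
        return np.flatnonzero(self.ad_effect_map != 0)

    @property
    def overlap_roi_indices(self) -> np.ndarray:
        return np.intersect1d(self.age_roi_indices, self.ad_roi_indices)

    def asymptomatic_prob(self, ages: np.ndarray) -> np.ndarray:
        if callable(self.asymptomatic_rate):
            return np.clip(np.asarray(self.asymptomatic_rate(ages), float), 0.0, 1.0)
        r50, r90 = self.asymptomatic_rate
        return np.clip(r50 + (r90 - r50) * (np.asarray(ages, float) - 50.0) / 40.0, 0.0, 1.0)


def default_effect_maps(
    roi_names: Sequence[str],
    n_age: int = 40,
    n_ad: int = 30,
    overlap_fraction: float = 0.5,
) -> dict[str, np.ndarray]:
    """Deterministic default baselines and effect maps.

    The age-affected set occupies the first ``n_age`` ROIs; the
    AD-affected set takes the last ``ceil(overlap_fraction * n_ad)`` of
    those plus the following ``n_ad - k`` ROIs, so the two sets overlap
    in exactly ``k`` regions.  Ventricular ROIs expand with age and
    disease (positive effects); all other planted effects are atrophic
    (negative).
    """
    n = len(roi_names)
    k = math.ceil(overlap_fraction * n_ad)
    if n_age + (n_ad - k) > n:
        raise ValueError("effect supports exceed the number of ROIs")
    baseline = np.linspace(2800.0, 16000.0, n)
    age_slope = np.zeros(n)
    # the overlap regions (medial temporal pattern) carry the strongest
    # age slopes *and* lose by far the most volume to disease, which is
    # what entangles naive brain-age models with the disease axis
    n_age_only = n_age - k
    mags = np.concatenate(
        [np.linspace(-26.0, -10.0, n_age_only), np.linspace(-30.0, -18.0, k)]
    )
    for j, idx in enumerate(range(n_age)):
        m = mags[j]
        age_slope[idx] = abs(m) * 1.6 if is_ventricle(roi_names[idx]) else m
    ad_effect = np.zeros(n)
    ad_idx = list(range(n_age - k, n_age)) + list(range(n_age, n_age + n_ad - k))
    admags = np.concatenate(
        [np.linspace(-600.0, -450.0, k), np.linspace(-480.0, -290.0, n_ad - k)]
    )
    for j, idx in enumerate(ad_idx):
        m = admags[j]
        ad_effect[idx] = abs(m) * 1.5 if is_ventricle(roi_names[idx]) else m
    return {"baseline": baseline, "age_slope": age_slope, "ad_effect": ad_effect}


@dataclass
class GroundTruth:
    """Planted generator parameters and per-participant latent state."""

    roi_names: list[str]
    baseline: np.ndarray
    age_slope: np.ndarray
    sex_effect: np.ndarray
    ad_effect: np.ndarray
    quadratic_coef: np.ndarray
    noise_sd: np.ndarray
    study_offsets: dict[str, np.ndarray]
    study_scales: dict[str, np.ndarray]
    age_roi_indices: np.ndarray
    ad_roi_indices: np.ndarray
    overlap_roi_indices: np.ndarray
    participants: pd.DataFrame  # participant_id, severity, ageing_offset, ...
    scan_severity: pd.Series  # indexed by scan_id
    seed: int

    def to_json(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "roi_names": self.roi_names,
            "baseline": self.baseline.tolist(),
            "age_slope": self.age_slope.tolist(),
            "sex_effect": self.sex_effect.tolist(),
            "ad_effect": self.ad_effect.tolist(),
            "quadratic_coef": self.quadratic_coef.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "study_offsets": {k: v.tolist() for k, v in self.study_offsets.items()},
            "study_scales": {k: v.tolist() for k, v in self.study_scales.items()},
            "age_roi_indices": self.age_roi_indices.tolist(),
            "ad_roi_indices": self.ad_roi_indices.tolist(),
            "overlap_roi_indices": self.overlap_roi_indices.tolist(),
            "participants": self.participants.to_dict(orient="list"),
            "scan_severity": {
                "scan_id": self.scan_severity.index.tolist(),
                "severity": self.scan_severity.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _band(severity: np.ndarray, thresholds: tuple[float, float]) -> np.ndarray:
    lo, hi = thresholds
    return np.where(severity < lo, 0, np.where(severity < hi, 1, 2))


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a multi-study cohort.

    Returns
    -------
    roi : DataFrame
        scans x 145 ROI volumes (mm^3), indexed by ``scan_id``.
    pheno : DataFrame
        per-scan demographics, diagnoses, biomarkers and psychometrics.
    truth : GroundTruth
        the planted parameters and latent state.
    """
    rng_root = np.random.SeedSequence(config.seed)
    study_seeds = rng_root.spawn(len(config.studies))

    roi_frames: list[pd.DataFrame] = []
    pheno_frames: list[pd.DataFrame] = []
    part_frames: list[pd.DataFrame] = []
    sev_series: list[pd.Series] = []
    study_offsets: dict[str, np.ndarray] = {}
    study_scales: dict[str, np.ndarray] = {}

    n_rois = len(config.roi_names)
    scan_counts = np.array(sorted(config.scans_per_participant), dtype=int)
    scan_probs = np.array([config.scans_per_participant[c] for c in scan_counts], float)
    scan_probs = scan_probs / scan_probs.sum()

    for study, seedseq in zip(config.studies, study_seeds):
        rng = np.random.default_rng(seedseq)
        n = study.n_participants
        offset = np.broadcast_to(np.asarray(study.offset, float), (n_rois,)).copy()
        scale = np.broadcast_to(np.asarray(study.scale, float), (n_rois,)).copy()
        study_offsets[study.name] = offset
        study_scales[study.name] = scale

        ages0 = rng.uniform(*config.age_range, size=n)
        male = rng.random(n) < config.sex_ratio
        mix = np.asarray(study.dx_mix, float)
        dx0 = rng.choice(3, size=n, p=mix / mix.sum())

        # amyloid status: age-dependent among CN, fixed rates otherwise
        p_apos = np.where(
            dx0 == 0,
            config.asymptomatic_prob(ages0),
            np.where(
                dx0 == 1,
                config.amyloid_given_dx.get("MCI", 0.55),
                config.amyloid_given_dx.get("AD", 0.85),
            ),
        )
        apos = rng.random(n) < p_apos

        severity0 = np.zeros(n)
        for dx_i, dx_name in enumerate(DX_LEVELS):
            sel = apos & (dx0 == dx_i)
            if sel.any():
                a, b = config.severity_beta[dx_name]
                severity0[sel] = rng.beta(a, b, size=int(sel.sum()))
                if dx_name == "CN":
                    r48, r95 = config.preclinical_age_ramp
                    ramp = np.clip(
                        r48 + (r95 - r48) * (ages0[sel] - 48.0) / 47.0, 0.0, 1.0
                    )
                    severity0[sel] = severity0[sel] * ramp
            if dx_name in config.severity_beta_aneg:
                sel_n = (~apos) & (dx0 == dx_i)
                if sel_n.any():
                    a, b = config.severity_beta_aneg[dx_name]
                    severity0[sel_n] = rng.beta(a, b, size=int(sel_n.sum()))

        ageing = np.zeros(n)
        for (dx_name, pos), (mu, sd) in config.ageing_offset.items():
            sel = (dx0 == _DX_ORD[dx_name]) & (apos == pos)
            if sel.any():
                ageing[sel] = rng.normal(mu, sd, size=int(sel.sum()))
        vascular = np.zeros(n)
        for (dx_name, pos), (mu, sd) in config.vascular_offset.items():
            sel = (dx0 == _DX_ORD[dx_name]) & (apos == pos)
            if sel.any() and (mu != 0 or sd != 0):
                vascular[sel] = np.maximum(
                    rng.normal(mu, sd, size=int(sel.sum())), 0.0
                )

        # amyloid / tau latent burdens
        u = np.where(
            apos,
            0.55 + 0.40 * rng.beta(2.0, 2.0, size=n),
            0.05 + 0.35 * rng.beta(2.0, 2.0, size=n),
        )
        tau_v = np.where(
            apos,
            np.clip(severity0 + rng.normal(0.0, 0.15, size=n), 0.0, 1.2),
            np.abs(rng.normal(0.0, 0.10, size=n)),
        )
        tpos = tau_v > config.tau_positive_threshold

        p_allele = np.where(apos, config.apoe4_allele_prob[1], config.apoe4_allele_prob[0])
        apoe4 = rng.binomial(2, p_allele)

        prog = np.where(
            apos & (severity0 > 0.05),
            rng.uniform(*config.progression_rate, size=n),
            0.0,
        )
        n_scans = rng.choice(scan_counts, size=n, p=scan_probs)
        max_follow = (n_scans - 1) * config.followup_years[1]
        # keep every scan age inside the configured range
        ages0 = np.minimum(ages0, config.age_range[1] - max_follow)

        avail = {
            m: rng.random(n) < study.availability.get(m, 0.0) for m in BIOMARKER_COLUMNS
        }
        age_only_mask = (
            (config.age_slope_map != 0) & (config.ad_effect_map == 0)
        ).astype(float)

        pid = np.array([f"{study.name}_P{i:04d}" for i in range(n)])
        rows = []
        roi_rows = []
        sev_rows = []
        scan_ids = []
        for i in range(n):
            age_i = ages0[i]
            sev_i = severity0[i]
            for s in range(int(n_scans[i])):
                if s > 0:
                    gap = rng.uniform(*config.followup_years)
                    age_i = age_i + gap
                    sev_i = min(1.0, sev_i + prog[i] * gap)
                dx_scan = max(dx0[i], _band(np.array([sev_i]), config.dx_thresholds)[0])
                scan_id = f"{pid[i]}_S{s + 1:02d}"
                scan_ids.append(scan_id)
                sev_rows.append(sev_i)
                rows.append(
                    {
                        "participant_id": pid[i],
                        "scan_id": scan_id,
                        "age": age_i,
                        "sex": "M" if male[i] else "F",
                        "study": study.name,
                        "clinical_dx": DX_LEVELS[int(dx_scan)],
                        "scan_order": s + 1,
                        "apoe4_count": int(apoe4[i]),
                        "_i": i,
                    }
                )
                # regional volumes
                age_eff = age_i + ageing[i] - AGE_CENTER
                core = (
                    config.baseline_map
                    + config.age_slope_map * age_eff
                    + age_only_mask * config.age_slope_map * vascular[i]
                    + config.sex_effect_map * float(male[i])
                    + config.ad_effect_map * sev_i
                )
                if config.quadratic_age:
                    core = core + config.quadratic_coef_map * age_eff**2
                g = rng.normal(0.0, config.global_scale_sd) if config.global_scale_sd > 0 else 0.0
                atro = (
                    rng.normal(0.0, config.atrophy_factor_sd)
                    if config.atrophy_factor_sd > 0 else 0.0
                )
                core = core + atro * config.atrophy_load_map
                noise = rng.normal(0.0, config.noise_sd_map)
                roi_rows.append(scale * (core * (1.0 + g) + noise) + offset)

        pheno = pd.DataFrame(rows)
        idx = pheno.pop("_i").to_numpy()
        sev_scan = np.asarray(sev_rows)

        # biomarker emissions are driven by the scan-level latent state
        for meas, (b0, b1, nsd) in config.amyloid_emission.items():
            vals = b0 + b1 * u[idx] + rng.normal(0.0, nsd, size=len(idx))
            vals[~avail[meas][idx]] = np.nan
            pheno[meas] = vals
        tau_scan = np.where(
            apos[idx],
            np.clip(tau_v[idx] + (sev_scan - severity0[idx]), 0.0, 1.5),
            tau_v[idx],
        )
        for meas, (b0, b1, nsd) in config.tau_emission.items():
            vals = b0 + b1 * tau_scan + rng.normal(0.0, nsd, size=len(idx))
            vals[~avail[meas][idx]] = np.nan
            pheno[meas] = vals

        for name, (b0, ba, bs, bo, nsd, lo, hi, as_int) in config.psychometrics.items():
            vals = (
                b0
                + ba * (pheno["age"].to_numpy() - AGE_CENTER)
                + bs * sev_scan
                + bo * ageing[idx]
                + rng.normal(0.0, nsd, size=len(idx))
            )
            vals = np.clip(vals, lo, hi if hi is not None else np.inf)
            pheno[name] = np.round(vals) if as_int else vals

        roi = pd.DataFrame(
            np.vstack(roi_rows), index=pd.Index(scan_ids, name="scan_id"),
            columns=list(config.roi_names),
        )
        roi_frames.append(roi)
        pheno_frames.append(pheno)
        sev_series.append(pd.Series(sev_rows, index=scan_ids, name="severity"))
        part_frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "study": study.name,
                    "baseline_age": ages0,
                    "male": male,
                    "clinical_dx_baseline": [DX_LEVELS[d] for d in dx0],
                    "severity": severity0,
                    "ageing_offset": ageing,
                    "vascular_offset": vascular,
                    "amyloid_positive": apos,
                    "tau_positive": tpos,
                    "amyloid_burden": u,
                    "tau_burden": tau_v,
                    "progression_rate": prog,
                    "n_scans": n_scans,
                }
            )
        )

    roi_all = pd.concat(roi_frames)
    pheno_all = pd.concat(pheno_frames, ignore_index=True)
    truth = GroundTruth(
        roi_names=list(config.roi_names),
        baseline=config.baseline_map,
        age_slope=config.age_slope_map,
        sex_effect=config.sex_effect_map,
        ad_effect=config.ad_effect_map,
        quadratic_coef=config.quadratic_coef_map,
        noise_sd=config.noise_sd_map,
        study_offsets=study_offsets,
        study_scales=study_scales,
        age_roi_indices=config.age_roi_indices,
        ad_roi_indices=config.ad_roi_indices,
        overlap_roi_indices=config.overlap_roi_indices,
        participants=pd.concat(part_frames, ignore_index=True),
        scan_severity=pd.concat(sev_series),
        seed=config.seed,
    )
    return roi_all, pheno_all, truth


def emit_longitudinal_scans(config: GeneratorConfig) -> pd.DataFrame:
    """Phenotype rows for a cohort with repeated scans per participant.

    Within a participant, scan ages strictly increase and the clinical
    diagnosis never improves along CN -> MCI -> AD.
    """
    if max(config.scans_per_participant) <= 1:
        raise ValueError(
            "scans_per_participant must allow more than one scan; "
            "e.g. {1: 0.5, 2: 0.3, 3: 0.2}"
        )
    _, pheno, _ = generate_cohort(config)
    return pheno
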