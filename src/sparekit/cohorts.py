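"""Molecular status calling, training-group construction and matching.

Amyloid status is called from CSF amyloid-beta 42 and/or amyloid PET
(PiB, florbetapir) with *conservative* two-threshold bands: values beyond
the positive threshold are A+, values beyond the negative threshold are
A-, and values in between are "unclear".  Tau status is called from CSF
total tau analogously (by default with a single study-specific cutoff at
the 75th percentile of cognitively normal values).

Four training groups are assembled, each with one scan per participant:

* ``CN`` and ``ClinicalAD`` - defined purely by the clinical label;
* ``A-/CN`` - clinically normal and amyloid-negative;
* ``ADContinuum`` - amyloid-positive AD or MCI, plus amyloid- and
  tau-positive cognitively normal participants.

Controls contribute their *last* qualifying scan, cases their *first*,
and case/control pairs are matched on size, mean age and sex ratio
(both tests at p > 0.2) by sex-stratified greedy nearest-age pairing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

AMYLOID_MEASURES = ("abeta42", "pib_suvr", "florbetapir_suvr")
TAU_MEASURES = ("csf_ttau",)

GROUP_NAMES = ("CN", "ClinicalAD", "A-/CN", "ADContinuum")


@dataclass
class MeasureCutoff:
    """Two-threshold conservative band for one biomarker measure."""

    positive: float
    negative: float
    high_is_positive: bool = True

    def __post_init__(self) -> None:
        if self.high_is_positive and self.positive < self.negative:
            raise ValueError("high-is-positive cutoffs require positive >= negative")
        if not self.high_is_positive and self.positive > self.negative:
            raise ValueError("low-is-positive cutoffs require positive <= negative")

    def vote(self, values: np.ndarray) -> np.ndarray:
        """Per-value call in {'+', '-', 'unclear', 'missing'}."""
        v = np.asarray(values, float)
        out = np.full(v.shape, "missing", dtype=object)
        ok = ~np.isnan(v)
        if self.high_is_positive:
            out[ok & (v >= self.positive)] = "+"
            out[ok & (v <= self.negative)] = "-"
        else:
            out[ok & (v <= self.positive)] = "+"
            out[ok & (v >= self.negative)] = "-"
        out[ok & (out == "missing")] = "unclear"
        return out


def default_cutoffs() -> "CutoffConfig":
    return CutoffConfig()


@dataclass
class CutoffConfig:
    """Per-measure (optionally per-study) conservative cutoffs.

    Defaults use the thresholded endpoints of the positive and negative
    group ranges: florbetapir SUVR A+ >= 1.15 / A- <= 1.05; PiB SUVR
    A+ >= 1.54 / A- <= 1.25; CSF amyloid-beta 42 A+ <= 178 / A- >= 200
    (low values are positive).  The CSF total tau cutoff defaults to the
    study-specific 75th percentile of cognitively normal values.
    """

    amyloid: dict[str, MeasureCutoff | dict[str, MeasureCutoff]] = field(
        default_factory=lambda: {
            "florbetapir_suvr": MeasureCutoff(1.15, 1.05, high_is_positive=True),
            "pib_suvr": MeasureCutoff(1.54, 1.25, high_is_positive=True),
            "abeta42": MeasureCutoff(178.0, 200.0, high_is_positive=False),
        }
    )
    tau: dict[str, MeasureCutoff | dict[str, MeasureCutoff] | None] = field(
        default_factory=lambda: {"csf_ttau": None}
    )
    tau_cn_percentile: float = 75.0
    #: 'unclear' resolves disagreeing amyloid measures conservatively;
    #: 'priority' trusts the first available measure in priority order
    conflict_policy: str = "unclear"
    priority_order: tuple[str, ...] = ("abeta42", "pib_suvr", "florbetapir_suvr")

    def cutoff_for(self, measure: str, study: str, kind: str) -> MeasureCutoff | None:
        table = self.amyloid if kind == "amyloid" else self.tau
        entry = table.get(measure)
        if entry is None:
            return None
        if isinstance(entry, dict):
            return entry.get(study)
        return entry


def _combine(votes: dict[str, str], policy: str, priority: tuple[str, ...]) -> tuple[str, str]:
    """Combine per-measure votes into one status plus the source used."""
    present = {m: v for m, v in votes.items() if v != "missing"}
    if not present:
        return "missing", ""
    vals = set(present.values())
    if policy == "priority":
        order = [m for m in priority if m in present] + [
            m for m in present if m not in priority
        ]
        m = order[0]
        return {"+": "+", "-": "-", "unclear": "unclear"}[present[m]], m
    if "+" in vals and "-" in vals:
        return "unclear", "+".join(sorted(present))
    if "+" in vals:
        src = sorted(m for m, v in present.items() if v == "+")
        return "+", "+".join(src)
    if "-" in vals:
        src = sorted(m for m, v in present.items() if v == "-")
        return "-", "+".join(src)
    return "unclear", "+".join(sorted(present))


def call_molecular_status(
    pheno: pd.DataFrame, cutoffs: CutoffConfig | None = None
) -> pd.DataFrame:
    """Per-scan amyloid and tau status.

    Returns a DataFrame indexed by ``scan_id`` with columns ``amyloid``
    (A+/A-/unclear/missing), ``tau`` (T+/T-/unclear/missing) and the
    source measures used.
    """
    cutoffs = cutoffs or CutoffConfig()
    for measure in list(cutoffs.amyloid) + list(cutoffs.tau):
        if measure not in pheno.columns:
            raise KeyError(f"measure column {measure!r} not present in the phenotype table")

    studies = pheno["study"].to_numpy()
    n = len(pheno)

    # resolve tau cutoffs, falling back to per-study CN percentiles
    tau_cut: dict[str, dict[str, MeasureCutoff]] = {}
    for measure, entry in cutoffs.tau.items():
        tau_cut[measure] = {}
        for s in pd.unique(studies):
            cut = cutoffs.cutoff_for(measure, s, "tau") if entry is not None else None
            if cut is None:
                cn_vals = pheno.loc[
                    (pheno["clinical_dx"] == "CN") & (pheno["study"] == s), measure
                ].dropna()
                if len(cn_vals) == 0:
                    continue
                thr = float(np.percentile(cn_vals, cutoffs.tau_cn_percentile))
                logger.info(
                    "tau cutoff for %s in study %s: CN %.0fth percentile = %.2f",
                    measure, s, cutoffs.tau_cn_percentile, thr,
                )
                cut = MeasureCutoff(thr, thr, high_is_positive=True)
            tau_cut[measure][s] = cut

    def _votes(kind: str, measures: dict) -> list[dict[str, str]]:
        per_scan: list[dict[str, str]] = [dict() for _ in range(n)]
        for measure in measures:
            vals = pheno[measure].to_numpy(float)
            for s in pd.unique(studies):
                if kind == "amyloid":
                    cut = cutoffs.cutoff_for(measure, s, "amyloid")
                else:
                    cut = tau_cut.get(measure, {}).get(s)
                sel = np.flatnonzero(studies == s)
                if cut is None:
                    for i in sel:
                        per_scan[i][measure] = "missing"
                    continue
                votes = cut.vote(vals[sel])
                for i, v in zip(sel, votes):
                    per_scan[i][measure] = v
        return per_scan

    amy_votes = _votes("amyloid", cutoffs.amyloid)
    tau_votes = _votes("tau", cutoffs.tau)

    rows = []
    for i in range(n):
        a, a_src = _combine(amy_votes[i], cutoffs.conflict_policy, cutoffs.priority_order)
        t, t_src = _combine(tau_votes[i], cutoffs.conflict_policy, cutoffs.priority_order)
        rows.append(
            {
                "amyloid": {"+": "A+", "-": "A-"}.get(a, a),
                "tau": {"+": "T+", "-": "T-"}.get(t, t),
                "amyloid_source": a_src,
                "tau_source": t_src,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(pheno["scan_id"], name="scan_id"))


def select_scan_per_participant(pheno: pd.DataFrame, role: str) -> list[str]:
    """One scan per participant among the qualifying rows supplied.

    Controls contribute their *last* qualifying scan (best age match to
    the typically older cases); cases contribute their *first* (harder,
    more borderline classification examples).
    """
    if role not in ("control", "case"):
        raise ValueError("role must be 'control' or 'case'")
    if len(pheno) == 0:
        return []
    ordered = pheno.sort_values(["participant_id", "age", "scan_order"])
    grouped = ordered.groupby("participant_id", sort=False)
    picked = grouped.tail(1) if role == "control" else grouped.head(1)
    return picked["scan_id"].tolist()


@dataclass
class CohortDefinition:
    """A named training group: one scan per participant."""

    name: str
    scan_ids: list[str]
    composition: pd.DataFrame  # tally by (clinical_dx, amyloid, tau)

    def __len__(self) -> int:
        return len(self.scan_ids)


def _tally(pheno_idx: pd.DataFrame, status: pd.DataFrame, scan_ids: list[str]) -> pd.DataFrame:
    sub = pheno_idx.loc[scan_ids]
    st = status.loc[scan_ids]
    df = pd.DataFrame(
        {"clinical_dx": sub["clinical_dx"], "amyloid": st["amyloid"], "tau": st["tau"]}
    )
    return df.value_counts().rename("n").reset_index()


def build_groups(
    pheno: pd.DataFrame,
    status: pd.DataFrame | None = None,
    cutoffs: CutoffConfig | None = None,
) -> dict[str, CohortDefinition]:
    """Construct the four training groups from diagnoses and molecular status."""
    if status is None:
        status = call_molecular_status(pheno, cutoffs)
    ph = pheno.merge(
        status[["amyloid", "tau"]], left_on="scan_id", right_index=True, how="left"
    )
    pheno_idx = pheno.set_index("scan_id")

    is_cn = ph["clinical_dx"] == "CN"
    is_ad = ph["clinical_dx"] == "AD"
    is_mci = ph["clinical_dx"] == "MCI"
    apos = ph["amyloid"] == "A+"
    aneg = ph["amyloid"] == "A-"
    tpos = ph["tau"] == "T+"

    # participants who ever qualify as cases are kept out of the
    # corresponding control group so that matched pairs stay disjoint
    ad_participants = set(ph.loc[is_ad, "participant_id"])
    continuum_mask = (apos & (is_ad | is_mci)) | (apos & tpos & is_cn)
    continuum_participants = set(ph.loc[continuum_mask, "participant_id"])

    members: dict[str, list[str]] = {}
    members["CN"] = select_scan_per_participant(
        ph[is_cn & ~ph["participant_id"].isin(ad_participants)], "control"
    )
    members["ClinicalAD"] = select_scan_per_participant(ph[is_ad], "case")
    members["A-/CN"] = select_scan_per_participant(
        ph[is_cn & aneg & ~ph["participant_id"].isin(continuum_participants)], "control"
    )
    members["ADContinuum"] = select_scan_per_participant(ph[continuum_mask], "case")

    groups = {}
    for name in GROUP_NAMES:
        ids = members[name]
        if not ids:
            raise ValueError(f"group {name!r} is empty under the supplied cutoffs")
        groups[name] = CohortDefinition(
            name=name, scan_ids=ids, composition=_tally(pheno_idx, status, ids)
        )
    return groups


@dataclass
class MatchReport:
    """Verification record of a case/control match."""

    n_a: int
    n_b: int
    age_t_stat: float
    age_t_p: float
    sex_chi2_stat: float
    sex_chi2_p: float
    pruned_a: list[str]
    pruned_b: list[str]
    n_dropped_pairs: int

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _match_tests(ages_a, ages_b, male_a, male_b) -> tuple[float, float, float, float]:
    if np.array_equal(np.sort(ages_a), np.sort(ages_b)):
        t_stat, t_p = 0.0, 1.0
    else:
        t_stat, t_p = stats.ttest_ind(ages_a, ages_b)
    table = np.array(
        [
            [male_a.sum(), len(male_a) - male_a.sum()],
            [male_b.sum(), len(male_b) - male_b.sum()],
        ]
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        chi2, chi_p = 0.0, 1.0  # single-sex groups: ratio trivially equal
    else:
        chi2, chi_p, *_ = stats.chi2_contingency(table, correction=False)
    return float(t_stat), float(t_p), float(chi2), float(chi_p)


def match_groups(
    a: CohortDefinition,
    b: CohortDefinition,
    pheno: pd.DataFrame,
    seed: int = 0,
    p_floor: float = 0.2,
    max_iter: int = 2000,
    min_size: int = 10,
    target_size: int | None = None,
) -> tuple[CohortDefinition, CohortDefinition, MatchReport]:
    """Equal-size subsets of two groups matched on age and sex.

    Sex-stratified greedy nearest-age pairing, followed by verification
    with a two-sample t-test on age and a chi-squared test on sex (both
    must reach p > ``p_floor``); the worst age-discrepant pairs are
    pruned until the tests pass.  Ties are broken at random under
    ``seed``.  ``target_size`` trims the result to a fixed number of
    best-matched pairs so that several case/control pairs can share one
    sample size.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    ph = pheno.set_index("scan_id")
    info_a = ph.loc[a.scan_ids, ["age", "sex", "participant_id"]]
    info_b = ph.loc[b.scan_ids, ["age", "sex", "participant_id"]]

    pairs: list[tuple[str, str, float]] = []  # (scan_a, scan_b, |age diff|)
    for sex in ("M", "F"):
        sub_a = info_a[info_a["sex"] == sex]
        sub_b = info_b[info_b["sex"] == sex]
        ids_a = sub_a.index.to_numpy()[rng.permutation(len(sub_a))]
        ids_b = sub_b.index.to_numpy()[rng.permutation(len(sub_b))]
        ages_a = ph.loc[ids_a, "age"].to_numpy()
        ages_b = ph.loc[ids_b, "age"].to_numpy()
        # walk the smaller stratum, popping the nearest-age partner from
        # the larger one so the scarce group drives the pairing
        a_small = len(ids_a) <= len(ids_b)
        ids_s, ages_s = (ids_a, ages_a) if a_small else (ids_b, ages_b)
        ids_l, ages_l = (ids_b, ages_b) if a_small else (ids_a, ages_a)
        order_s = np.argsort(ages_s, kind="stable")
        remaining = list(np.argsort(ages_l, kind="stable"))
        rem_ages = [ages_l[j] for j in remaining]
        for i in order_s:
            if not remaining:
                break
            pos = int(np.searchsorted(rem_ages, ages_s[i]))
            cands = [p for p in (pos - 1, pos) if 0 <= p < len(remaining)]
            best = min(cands, key=lambda p: abs(rem_ages[p] - ages_s[i]))
            j = remaining.pop(best)
            rem_ages.pop(best)
            pair = (ids_s[i], ids_l[j]) if a_small else (ids_l[j], ids_s[i])
            pairs.append((*pair, abs(ages_s[i] - ages_l[j])))

    if not pairs:
        raise ValueError("infeasible matching: no same-sex pairs available")
    pairs.sort(key=lambda t: t[2])
    dropped = 0
    for _ in range(max_iter):
        ids_a = [p[0] for p in pairs]
        ids_b = [p[1] for p in pairs]
        ages_a = ph.loc[ids_a, "age"].to_numpy()
        ages_b = ph.loc[ids_b, "age"].to_numpy()
        male_a = (ph.loc[ids_a, "sex"] == "M").to_numpy()
        male_b = (ph.loc[ids_b, "sex"] == "M").to_numpy()
        t_stat, t_p, chi2, chi_p = _match_tests(ages_a, ages_b, male_a, male_b)
        if (t_p > p_floor and chi_p > p_floor) or len(pairs) <= min_size:
            break
        pairs.pop()  # worst-discrepancy pair
        dropped += 1
    else:
        raise ValueError("matching did not converge within max_iter prunings")
    if not (t_p > p_floor and chi_p > p_floor):
        raise ValueError(
            f"infeasible matching: best subsets reach age p={t_p:.3g}, sex p={chi_p:.3g} "
            f"at size {len(pairs)}"
        )

    if target_size is not None:
        if target_size > len(pairs):
            raise ValueError(
                f"target_size {target_size} exceeds the {len(pairs)} matched pairs"
            )
        pairs = pairs[:target_size]  # keep the best-matched pairs
        ids_a = [p[0] for p in pairs]
        ids_b = [p[1] for p in pairs]
        ages_a = ph.loc[ids_a, "age"].to_numpy()
        ages_b = ph.loc[ids_b, "age"].to_numpy()
        male_a = (ph.loc[ids_a, "sex"] == "M").to_numpy()
        male_b = (ph.loc[ids_b, "sex"] == "M").to_numpy()
        t_stat, t_p, chi2, chi_p = _match_tests(ages_a, ages_b, male_a, male_b)
        if not (t_p > p_floor and chi_p > p_floor):
            raise ValueError(
                f"matching at target size {target_size} fails verification "
                f"(age p={t_p:.3g}, sex p={chi_p:.3g})"
            )

    kept_a, kept_b = set(ids_a), set(ids_b)
    report = MatchReport(
        n_a=len(ids_a),
        n_b=len(ids_b),
        age_t_stat=t_stat,
        age_t_p=t_p,
        sex_chi2_stat=chi2,
        sex_chi2_p=chi_p,
        pruned_a=[s for s in a.scan_ids if s not in kept_a],
        pruned_b=[s for s in b.scan_ids if s not in kept_b],
        n_dropped_pairs=dropped,
    )
    comp_a = ph.loc[ids_a, ["clinical_dx"]].value_counts().rename("n").reset_index()
    comp_b = ph.loc[ids_b, ["clinical_dx"]].value_counts().rename("n").reset_index()
    out_a = CohortDefinition(name=a.name, scan_ids=ids_a, composition=comp_a)
    out_b = CohortDefinition(name=b.name, scan_ids=ids_b, composition=comp_b)
    return out_a, out_b, report
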