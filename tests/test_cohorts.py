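"""Unit tests for molecular status calling, group building and matching."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sparekit.cohorts import (
    CutoffConfig,
    MeasureCutoff,
    build_groups,
    call_molecular_status,
    match_groups,
    select_scan_per_participant,
)


def _pheno(rows):
    base = {
        "age": 70.0,
        "sex": "F",
        "study": "STUDY_A",
        "clinical_dx": "CN",
        "scan_order": 1,
        "abeta42": np.nan,
        "pib_suvr": np.nan,
        "florbetapir_suvr": np.nan,
        "csf_ttau": np.nan,
    }
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d.update(r)
        d.setdefault("scan_id", f"s{i}")
        d.setdefault("participant_id", f"p{i}")
        out.append(d)
    return pd.DataFrame(out)


class TestMolecularStatus:
    def test_florbetapir_band_endpoints(self):
        # conservative band: positive >= 1.15, negative <= 1.05
        ph = _pheno(
            [
                {"florbetapir_suvr": 1.20},
                {"florbetapir_suvr": 0.90},
                {"florbetapir_suvr": 1.10},
            ]
        )
        status = call_molecular_status(ph)
        assert status["amyloid"].tolist() == ["A+", "A-", "unclear"]

    def test_no_measures_means_missing(self):
        status = call_molecular_status(_pheno([{}]))
        assert status["amyloid"].iloc[0] == "missing"
        assert status["tau"].iloc[0] == "missing"

    def test_conflicting_measures_resolve_to_unclear(self):
        ph = _pheno([{"pib_suvr": 1.60, "florbetapir_suvr": 1.00}])
        status = call_molecular_status(ph)
        assert status["amyloid"].iloc[0] == "unclear"

    def test_conflict_table_by_enumeration(self):
        """Brute-force the 3x3 vote-combination table for two measures."""
        vote_values = {"+": 1.60, "-": 1.00, "unclear": 1.40}  # PiB calls
        fbp_values = {"+": 1.20, "-": 0.90, "unclear": 1.10}
        for pib_vote, pib in vote_values.items():
            for fbp_vote, fbp in fbp_values.items():
                ph = _pheno([{"pib_suvr": pib, "florbetapir_suvr": fbp}])
                got = call_molecular_status(ph)["amyloid"].iloc[0]
                votes = {pib_vote, fbp_vote}
                if votes == {"+", "-"}:
                    expected = "unclear"  # conflict policy
                elif "+" in votes:
                    expected = "A+"
                elif "-" in votes:
                    expected = "A-"
                else:
                    expected = "unclear"
                assert got == expected, (pib_vote, fbp_vote)

    def test_priority_policy_trusts_csf_first(self):
        cfg = CutoffConfig(conflict_policy="priority")
        ph = _pheno([{"abeta42": 230.0, "pib_suvr": 1.60}])  # CSF says A-, PET A+
        status = call_molecular_status(ph, cfg)
        assert status["amyloid"].iloc[0] == "A-"
        assert status["amyloid_source"].iloc[0] == "abeta42"

    def test_unknown_measure_column_rejected(self):
        cfg = CutoffConfig()
        cfg.amyloid["nonexistent_assay"] = MeasureCutoff(2.0, 1.0)
        with pytest.raises(KeyError, match="nonexistent_assay"):
            call_molecular_status(_pheno([{}]), cfg)

    def test_monotone_in_measure_value(self):
        """Raising an amyloid value never moves a scan from A+ to A-."""
        order = {"A-": 0, "unclear": 1, "A+": 2, "missing": -1}
        values = np.linspace(0.5, 2.0, 40)
        ph = _pheno([{"florbetapir_suvr": v} for v in values])
        calls = call_molecular_status(ph)["amyloid"].map(order).to_numpy()
        assert np.all(np.diff(calls) >= 0)

    def test_low_is_positive_direction(self):
        ph = _pheno([{"abeta42": 150.0}, {"abeta42": 220.0}, {"abeta42": 190.0}])
        status = call_molecular_status(ph)
        assert status["amyloid"].tolist() == ["A+", "A-", "unclear"]

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            MeasureCutoff(1.0, 1.2, high_is_positive=True)


class TestScanSelection:
    def test_control_takes_last_case_takes_first(self):
        ph = _pheno(
            [
                {"participant_id": "p", "scan_id": "a", "age": 70, "scan_order": 1},
                {"participant_id": "p", "scan_id": "b", "age": 72, "scan_order": 2},
            ]
        )
        assert select_scan_per_participant(ph, "control") == ["b"]
        assert select_scan_per_participant(ph, "case") == ["a"]

    def test_mixed_history_control_vs_case(self):
        # CN scans at 70 and 72, AD scan at 75
        ph = _pheno(
            [
                {"participant_id": "p", "scan_id": "a", "age": 70, "clinical_dx": "CN"},
                {"participant_id": "p", "scan_id": "b", "age": 72, "clinical_dx": "CN"},
                {"participant_id": "p", "scan_id": "c", "age": 75, "clinical_dx": "AD"},
            ]
        )
        cn_rows = ph[ph["clinical_dx"] == "CN"]
        ad_rows = ph[ph["clinical_dx"] == "AD"]
        assert select_scan_per_participant(cn_rows, "control") == ["b"]
        assert select_scan_per_participant(ad_rows, "case") == ["c"]

    def test_single_scan_serves_either_role(self):
        ph = _pheno([{"participant_id": "p", "scan_id": "only"}])
        assert select_scan_per_participant(ph, "control") == ["only"]
        assert select_scan_per_participant(ph, "case") == ["only"]


class TestBuildGroups:
    @staticmethod
    def _cohort_pheno():
        rows = []
        # amyloid-negative CN
        for i in range(6):
            rows.append({"participant_id": f"cn{i}", "clinical_dx": "CN",
                         "florbetapir_suvr": 0.9, "csf_ttau": 40.0})
        # amyloid-positive CN, tau-positive vs tau-unclear-free negative
        rows.append({"participant_id": "cnpos_t", "clinical_dx": "CN",
                     "florbetapir_suvr": 1.3, "csf_ttau": 90.0})
        rows.append({"participant_id": "cnpos_n", "clinical_dx": "CN",
                     "florbetapir_suvr": 1.3, "csf_ttau": 30.0})
        # clinical AD: A+, A-, and no-data
        rows.append({"participant_id": "adp", "clinical_dx": "AD",
                     "florbetapir_suvr": 1.5})
        rows.append({"participant_id": "adn", "clinical_dx": "AD",
                     "florbetapir_suvr": 0.8})
        rows.append({"participant_id": "adm", "clinical_dx": "AD"})
        # A+ MCI
        rows.append({"participant_id": "mcip", "clinical_dx": "MCI",
                     "florbetapir_suvr": 1.4})
        return _pheno(rows)

    def test_group_definitions(self):
        ph = self._cohort_pheno()
        groups = build_groups(ph)
        ids = {name: set(g.scan_ids) for name, g in groups.items()}
        pid = ph.set_index("scan_id")["participant_id"]

        def members(name):
            return {pid[s] for s in ids[name]}

        assert members("ClinicalAD") == {"adp", "adn", "adm"}
        # A- clinical AD stays out of the continuum
        assert members("ADContinuum") == {"adp", "mcip", "cnpos_t"}
        # tau-negative A+ CN excluded from the continuum
        assert "cnpos_n" not in members("ADContinuum")
        # A-/CN subset of clinical CN, disjoint from the continuum
        assert members("A-/CN") <= members("CN")
        assert not members("ADContinuum") & members("A-/CN")

    def test_continuum_partitions_into_three_cells(self):
        ph = self._cohort_pheno()
        groups = build_groups(ph)
        comp = groups["ADContinuum"].composition
        cells = set(zip(comp["clinical_dx"], comp["amyloid"]))
        assert cells == {("AD", "A+"), ("MCI", "A+"), ("CN", "A+")}
        assert comp["n"].sum() == len(groups["ADContinuum"])

    def test_empty_group_is_an_error(self):
        ph = _pheno([{"clinical_dx": "CN", "florbetapir_suvr": 0.9}] * 3)
        with pytest.raises(ValueError, match="ClinicalAD"):
            build_groups(ph)


def _independent_t_and_chi2(ages_a, ages_b, male_a, male_b):
    """Textbook reimplementation used to verify the matcher's report."""
    na, nb = len(ages_a), len(ages_b)
    sp2 = ((na - 1) * np.var(ages_a, ddof=1) + (nb - 1) * np.var(ages_b, ddof=1)) / (
        na + nb - 2
    )
    t = (np.mean(ages_a) - np.mean(ages_b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    t_p = 2 * sps.t.sf(abs(t), na + nb - 2)
    table = np.array(
        [[male_a.sum(), na - male_a.sum()], [male_b.sum(), nb - male_b.sum()]], float
    )
    row = table.sum(1, keepdims=True)
    col = table.sum(0, keepdims=True)
    expected = row @ col / table.sum()
    chi2 = ((table - expected) ** 2 / expected).sum()
    chi_p = sps.chi2.sf(chi2, 1)
    return t_p, chi_p


class TestMatchGroups:
    @staticmethod
    def _two_groups(seed=0, shift=3.0, n_a=120, n_b=90):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_a):
            rows.append({"participant_id": f"a{i}", "scan_id": f"a{i}",
                         "age": rng.uniform(55, 90), "sex": "M" if rng.random() < 0.5 else "F",
                         "clinical_dx": "CN"})
        for i in range(n_b):
            rows.append({"participant_id": f"b{i}", "scan_id": f"b{i}",
                         "age": np.clip(rng.uniform(55, 90) + shift, 48, 95),
                         "sex": "M" if rng.random() < 0.6 else "F",
                         "clinical_dx": "AD"})
        ph = _pheno(rows)
        from sparekit.cohorts import CohortDefinition

        a = CohortDefinition("A", [f"a{i}" for i in range(n_a)], pd.DataFrame())
        b = CohortDefinition("B", [f"b{i}" for i in range(n_b)], pd.DataFrame())
        return a, b, ph

    def test_self_match_retains_everyone(self):
        a, _, ph = self._two_groups()
        out_a, out_b, rep = match_groups(a, a, ph, seed=1)
        assert rep.age_t_stat == 0.0
        assert rep.age_t_p == 1.0
        assert len(out_a) == len(a)

    def test_shifted_groups_match_and_report_verifies(self):
        a, b, ph = self._two_groups(shift=3.0)
        out_a, out_b, rep = match_groups(a, b, ph, seed=2)
        assert len(out_a) == len(out_b) <= min(len(a), len(b))
        idx = ph.set_index("scan_id")
        t_p, chi_p = _independent_t_and_chi2(
            idx.loc[out_a.scan_ids, "age"].to_numpy(),
            idx.loc[out_b.scan_ids, "age"].to_numpy(),
            (idx.loc[out_a.scan_ids, "sex"] == "M").to_numpy(),
            (idx.loc[out_b.scan_ids, "sex"] == "M").to_numpy(),
        )
        assert t_p > 0.2
        assert chi_p > 0.2
        assert rep.age_t_p == pytest.approx(t_p, rel=1e-9)

    def test_output_sizes_bounded_by_smaller_group(self):
        a, b, ph = self._two_groups(n_a=80, n_b=50, shift=0.0)
        out_a, out_b, _ = match_groups(a, b, ph, seed=0)
        assert len(out_a) == len(out_b) <= 50

    def test_no_participant_duplicated(self):
        a, b, ph = self._two_groups()
        out_a, out_b, _ = match_groups(a, b, ph, seed=3)
        assert len(set(out_a.scan_ids)) == len(out_a)
        assert len(set(out_b.scan_ids)) == len(out_b)

    def test_disjoint_age_ranges_fail_with_diagnostic(self):
        a, b, ph = self._two_groups()
        ph = ph.copy()
        sel = ph["scan_id"].str.startswith("b")
        ph.loc[sel, "age"] = ph.loc[sel, "age"] + 200  # force infeasibility
        with pytest.raises(ValueError, match="[Ii]nfeasible|converge"):
            match_groups(a, b, ph, seed=0)


class TestCutoffMonotoneHypothesis:
    """Status calls are monotone in the measured value (direction-aware)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.floats(min_value=0.3, max_value=2.5),
        st.floats(min_value=0.3, max_value=2.5),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_higher_florbetapir_never_less_positive(self, v1, v2):
        lo, hi = sorted((v1, v2))
        order = {"A-": 0, "unclear": 1, "A+": 2}
        ph = _pheno([{"florbetapir_suvr": lo}, {"florbetapir_suvr": hi}])
        calls = call_molecular_status(ph)["amyloid"].map(order).tolist()
        assert calls[1] >= calls[0]
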