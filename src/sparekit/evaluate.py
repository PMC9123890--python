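"""Disentanglement metrics and score-phenotype association statistics.

The central question is whether the brain-age axis (SPARE-BA Gap) and
the disease axis (SPARE-AD) measure separate processes.  This module
provides the statistics used to answer it:

* Pearson correlation between Gap/AD score pairs, and a Fisher
  z-transform based test for the difference of two correlation
  coefficients;
* classification accuracy at the operating point where sensitivity
  equals specificity, plus Cohen's d effect sizes;
* Spearman association tables between scores and clinical, molecular or
  genetic variables, with Benjamini-Hochberg multiplicity control;
* likelihood-ratio tests between nested Gaussian linear models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_DX_PRIORITY = {"AD": 2, "MCI": 1, "CN": 0}


def select_evaluation_scan(pheno: pd.DataFrame, seed: int = 0) -> list[str]:
    """One scan per participant for evaluation analyses.

    Within each participant, scans carrying the most advanced clinical
    label present (AD over MCI over CN) are kept, and one of those is
    drawn uniformly at random under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for _, grp in pheno.sort_values("scan_id").groupby("participant_id", sort=True):
        prio = grp["clinical_dx"].map(_DX_PRIORITY)
        best = grp[prio == prio.max()]
        out.append(best["scan_id"].iloc[rng.integers(len(best))])
    return out


def corr_pair(x, y) -> tuple[float, int]:
    """Pearson correlation on complete pairs; returns (r, n)."""
    x = pd.Series(x).astype(float)
    y = pd.Series(y).astype(float)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError(f"need at least 4 complete pairs, got {len(x)}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y)[0]), int(len(x))


def fisher_z_statistic(r1: float, n1: int, r2: float, n2: int) -> float:
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    return float((z1 - z2) ** 2 / (1.0 / (n1 - 3) + 1.0 / (n2 - 3)))


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Test the difference of two correlation coefficients.

    The statistic is the squared difference of the Fisher z-transformed
    coefficients over its variance under independence, referred to an
    F(1, inf) (equivalently chi-squared with 1 df) tail.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
        if n <= 3:
            raise ValueError("need n > 3 per sample")
    stat = fisher_z_statistic(r1, n1, r2, n2)
    return stat, float(stats.chi2.sf(stat, df=1))


def compare_dependent_correlations(
    r12: float, r13: float, r23: float, n: int
) -> tuple[float, float]:
    """Williams' test for two correlations sharing one variable (optional
    variant accounting for the dependence the z-transform test ignores)."""
    if n <= 3:
        raise ValueError("need n > 3")
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    rbar = (r12 + r13) / 2
    num = (r12 - r13) * np.sqrt((n - 1) * (1 + r23))
    den = np.sqrt(
        2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3
    )
    t = float(num / den)
    return t, float(2 * stats.t.sf(abs(t), df=n - 3))


def accuracy_sens_eq_spec(scores, labels) -> tuple[float, float]:
    """Balanced accuracy at the threshold where sensitivity = specificity.

    The crossing of the two monotone curves is found by linear
    interpolation between achievable operating points; at the crossing
    sensitivity, specificity and balanced accuracy coincide.  Returns
    ``(threshold, accuracy)`` with accuracy in [0, 1].
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    n_pos, n_neg = len(pos), len(neg)

    def sens(t: float) -> float:  # P(score > t | case), right-continuous
        return 1.0 - np.searchsorted(pos, t, side="right") / n_pos

    def spec(t: float) -> float:  # P(score <= t | control)
        return np.searchsorted(neg, t, side="right") / n_neg

    grid = np.unique(np.concatenate([pos, neg]))
    diff = np.array([sens(t) - spec(t) for t in grid])  # decreasing in t
    k = int(np.searchsorted(-diff, 0.0, side="left"))
    if k == 0:
        t_star = grid[0]
        acc = (sens(t_star) + spec(t_star)) / 2
        return float(t_star), float(acc)
    if k >= len(grid):
        t_star = grid[-1]
        acc = (sens(t_star) + spec(t_star)) / 2
        return float(t_star), float(acc)
    t0, t1 = grid[k - 1], grid[k]
    d0, d1 = diff[k - 1], diff[k]
    frac = 0.5 if d0 == d1 else d0 / (d0 - d1)
    t_star = t0 + frac * (t1 - t0)
    # interpolate the operating points themselves
    s = sens(t0) + frac * (sens(t1) - sens(t0))
    p = spec(t0) + frac * (spec(t1) - spec(t0))
    return float(t_star), float((s + p) / 2)


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference with (n-1)-weighted pooled SD."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def spearman_cell(x, y, min_n: int = 10) -> tuple[float, float, int]:
    """Spearman rho (average ranks on ties), t-approximation p, and n."""
    x = pd.Series(x).astype(float)
    y = pd.Series(y).astype(float)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    n = int(len(x))
    if n < min_n:
        raise ValueError(f"need at least {min_n} complete pairs, got {n}")
    if x.nunique() < 2 or y.nunique() < 2:
        raise ValueError("all-tied variable; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n


def spearman_table(
    scores: pd.DataFrame,
    variables: pd.DataFrame,
    subgroup: pd.Series | None = None,
    restrict_study: pd.Series | None = None,
    largest_study_only: tuple[str, ...] = (),
    min_n: int = 10,
) -> pd.DataFrame:
    """Rank-correlation table: rows = variables, columns = score names.

    Cells hold Spearman rho; raw p-values are adjusted across the whole
    table with Benjamini-Hochberg.  Variables listed in
    ``largest_study_only`` are evaluated within the single study
    contributing the most complete pairs (appropriate when assay scales
    differ across studies).  Undefined cells (too few pairs, all-tied
    values) are flagged as NaN rather than fabricated.
    """
    if subgroup is not None:
        scores = scores.loc[subgroup.reindex(scores.index, fill_value=False)]
        variables = variables.loc[scores.index]
    records = []
    for var in variables.columns:
        col = variables[var]
        for score_name in scores.columns:
            sc = scores[score_name]
            use = col.notna() & sc.notna()
            if var in largest_study_only and restrict_study is not None:
                study_counts = restrict_study.loc[use[use].index].value_counts()
                if len(study_counts):
                    keep = restrict_study == study_counts.idxmax()
                    use = use & keep.reindex(use.index, fill_value=False)
            try:
                rho, p, n = spearman_cell(col[use], sc[use], min_n=min_n)
            except ValueError:
                rho, p, n = np.nan, np.nan, int(use.sum())
            records.append(
                {"variable": var, "score": score_name, "rho": rho, "p": p, "n": n}
            )
    table = pd.DataFrame(records)
    ok = table["p"].notna()
    table["p_adj"] = np.nan
    if ok.any():
        table.loc[ok, "p_adj"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    return table


def nested_lrt(
    outcome,
    predictors_full: pd.DataFrame,
    predictors_reduced: pd.DataFrame,
) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested Gaussian linear models.

    LR = n * log(RSS_reduced / RSS_full) referred to chi-squared with
    df = difference in predictor count.  The reduced predictor set must
    be a subset of the full set.
    """
    full_cols = set(predictors_full.columns)
    red_cols = set(predictors_reduced.columns)
    if not red_cols < full_cols:
        raise ValueError("reduced predictors must be a strict subset of the full set")
    y = pd.Series(outcome).astype(float)
    ok = y.notna() & predictors_full.notna().all(axis=1)
    y = y[ok].to_numpy()
    n = len(y)
    df = len(full_cols) - len(red_cols)

    def _rss(X: pd.DataFrame) -> float:
        A = np.column_stack([np.ones(n), X.loc[ok].to_numpy(float)])
        resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        return float(resid @ resid)

    rss_full = _rss(predictors_full)
    rss_red = _rss(predictors_reduced) if red_cols else float(np.sum((y - y.mean()) ** 2))
    lr = n * np.log(rss_red / rss_full) if rss_full > 0 else np.inf
    lr = max(lr, 0.0)
    return float(lr), df, float(stats.chi2.sf(lr, df=df))


@dataclass
class EvaluationReport:
    """Container for the disentanglement evaluation of one score table."""

    evaluation_scan_ids: list[str]
    correlations: dict[str, dict] = field(default_factory=dict)
    correlation_comparisons: list[dict] = field(default_factory=list)
    separability: list[dict] = field(default_factory=list)
    spearman: pd.DataFrame | None = None
    lrt: list[dict] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        payload = {
            "evaluation_scan_ids": self.evaluation_scan_ids,
            "correlations": self.correlations,
            "correlation_comparisons": self.correlation_comparisons,
            "separability": self.separability,
            "spearman": None if self.spearman is None else self.spearman.to_dict("records"),
            "lrt": self.lrt,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def evaluate_disentanglement(
    score_table: pd.DataFrame,
    pheno: pd.DataFrame,
    groups: dict | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Assemble the core disentanglement report.

    Computes, on one randomly selected scan per participant (favouring
    AD over MCI over CN labels): the Gap/AD correlation for each model
    generation, Fisher-z tests between successive generations, and the
    separability (sensitivity-equals-specificity accuracy and Cohen's d)
    of each score on the case/control contrasts.
    """
    eval_ids = select_evaluation_scan(pheno, seed=seed)
    eval_ids = [s for s in eval_ids if s in score_table.index]
    sc = score_table.loc[eval_ids]
    ph = pheno.set_index("scan_id").loc[eval_ids]

    report = EvaluationReport(evaluation_scan_ids=eval_ids)

    pairs = [("Gap1", "AD1"), ("Gap2", "AD2"), ("Gap3", "AD2"), ("AD3", "BA3")]
    for gap, ad in pairs:
        if gap in sc.columns and ad in sc.columns:
            r, n = corr_pair(sc[gap], sc[ad])
            report.correlations[f"{gap}~{ad}"] = {"r": r, "n": n}

    comps = [("Gap1~AD1", "Gap2~AD2"), ("Gap2~AD2", "Gap3~AD2"), ("Gap1~AD1", "Gap3~AD2")]
    raw_p = []
    for a, b in comps:
        if a in report.correlations and b in report.correlations:
            ca, cb = report.correlations[a], report.correlations[b]
            stat, p = compare_correlations(ca["r"], ca["n"], cb["r"], cb["n"])
            report.correlation_comparisons.append(
                {"pair_1": a, "pair_2": b, "statistic": stat, "p": p}
            )
            raw_p.append(p)
    if raw_p:
        adj = bh_adjust(raw_p)
        for rec, pa in zip(report.correlation_comparisons, adj):
            rec["p_adj"] = float(pa)

    # separability of each score on the clinical CN vs AD contrast
    dx = ph["clinical_dx"]
    contrasts = {"CN_vs_AD": (dx == "CN", dx == "AD")}
    if groups is not None and "A-/CN" in groups and "ADContinuum" in groups:
        ctrl_ids = set(groups["A-/CN"].scan_ids)
        case_ids = set(groups["ADContinuum"].scan_ids)
        contrasts["AnegCN_vs_Continuum"] = (
            pd.Series(sc.index.isin(ctrl_ids), index=sc.index),
            pd.Series(sc.index.isin(case_ids), index=sc.index),
        )
    for cname, (ctrl_mask, case_mask) in contrasts.items():
        ctrl_mask = np.asarray(ctrl_mask, bool)
        case_mask = np.asarray(case_mask, bool)
        if ctrl_mask.sum() < 2 or case_mask.sum() < 2:
            continue
        for col in sc.columns:
            vals = sc[col].to_numpy(float)
            scores = np.concatenate([vals[ctrl_mask], vals[case_mask]])
            labels = np.concatenate(
                [np.zeros(ctrl_mask.sum(), int), np.ones(case_mask.sum(), int)]
            )
            thr, acc = accuracy_sens_eq_spec(scores, labels)
            d = cohens_d(vals[case_mask], vals[ctrl_mask])
            report.separability.append(
                {
                    "contrast": cname,
                    "score": col,
                    "accuracy": acc,
                    "threshold": thr,
                    "cohens_d": d,
                }
            )
    return report
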