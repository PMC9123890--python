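"""Per-ROI model-weight significance and score-volume correlation maps.

To judge which regions a SPARE model genuinely relies on, each model is
retrained many times with its supervised target shuffled (ages for the
regression models, group labels for the classifiers), giving a null
distribution of every ROI's weight.  Two per-ROI significance measures
are reported:

* ``p_welch`` - the two-tailed Welch t-test between the ``n_perm`` null
  weights and the 10 cross-validation weights.  This is the classical
  comparison, but the 10 CV weights are trained on 90%-overlapping data
  and are therefore strongly correlated: for a no-signal ROI the test is
  anti-conservative (see the methods note).
* ``p_perm`` - the empirical two-sided permutation p-value of the
  full-sample weight against the null distribution, which is calibrated
  for no-signal ROIs by exchangeability.

Spearman correlation maps between ROI volumes and scores, and Fisher-z
tests for per-ROI correlation changes between model versions, provide
the complementary univariate view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC, LinearSVR

from .evaluate import bh_adjust, fisher_z_statistic
from .spare import SPAREEnsemble, _control_normalizers, _ids


@dataclass
class SpareModelSpec:
    """What to retrain during permutation: task, cohorts, hyperparameters."""

    task: str  # 'regression' | 'classification'
    training_cohort: object = None  # regression: scan ids
    control_cohort: object = None
    case_cohort: object = None  # classification only
    C: float = 1.0
    epsilon: float = 0.1
    max_iter: int = 50000


def _assemble(spec: SpareModelSpec, roi: pd.DataFrame, pheno: pd.DataFrame):
    ph = pheno.set_index("scan_id")
    if spec.task == "regression":
        ids = _ids(spec.training_cohort)
        y = ph.loc[ids, "age"].to_numpy(float)
        control_ids = set(_ids(spec.control_cohort)) if spec.control_cohort is not None else set(ids)
    elif spec.task == "classification":
        ctrl, case = _ids(spec.control_cohort), _ids(spec.case_cohort)
        ids = ctrl + case
        y = np.r_[np.zeros(len(ctrl), int), np.ones(len(case), int)]
        control_ids = set(ctrl)
    else:
        raise ValueError(f"unknown task {spec.task!r}")
    X = roi.loc[ids].to_numpy(float)
    control_mask = np.array([s in control_ids for s in ids])
    return X, y, control_mask


def _fit_full_sample(
    spec: SpareModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    control_mask: np.ndarray,
    roi_names: list[str],
    seed: int,
) -> np.ndarray:
    """Single full-sample fit; returns the weight vector (unit-norm for
    classifiers, matching the CV convention)."""
    mean, sd = _control_normalizers(X, np.ones(len(X), bool), control_mask, roi_names)
    Z = (X - mean) / sd
    if spec.task == "regression":
        est = LinearSVR(
            C=spec.C, epsilon=spec.epsilon, max_iter=spec.max_iter,
            random_state=seed, tol=1e-5,
        )
        est.fit(Z, y)
        return est.coef_.copy()
    est = LinearSVC(C=spec.C, loss="hinge", max_iter=spec.max_iter, random_state=seed, tol=1e-5)
    est.fit(Z, y)
    w = est.coef_.ravel().copy()
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
        scores = Z @ w
        if scores[y == 1].mean() < scores[y == 0].mean():
            w = -w
    return w


def permutation_weight_test(
    spec: SpareModelSpec,
    roi: pd.DataFrame,
    pheno: pd.DataFrame,
    ensemble: SPAREEnsemble,
    n_perm: int = 200,
    seed: int = 0,
    force: bool = False,
) -> pd.DataFrame:
    """Per-ROI weight significance by target-shuffled retraining.

    One full-sample model is refitted per permutation with the target
    shuffled.  Returns a DataFrame indexed by ROI with the CV weight
    summary, the null summary, and Welch-t and empirical permutation
    p-values (raw and Benjamini-Hochberg adjusted).
    """
    if n_perm < 100 and not force:
        raise ValueError(
            f"n_perm={n_perm} is too small for stable null summaries; "
            "pass force=True to override"
        )
    rng = np.random.default_rng(seed)
    X, y, control_mask = _assemble(spec, roi, pheno)
    roi_names = list(roi.columns)

    observed = _fit_full_sample(spec, X, y, control_mask, roi_names, seed)
    null = np.empty((n_perm, X.shape[1]))
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        null[b] = _fit_full_sample(spec, X, y_perm, control_mask, roi_names, seed)

    cv_w = ensemble.weight_matrix  # (k, n_roi)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)

    welch = stats.ttest_ind(null, cv_w, axis=0, equal_var=False)
    p_welch = np.asarray(welch.pvalue, float)

    centered_null = np.abs(null - null_mean)
    centered_obs = np.abs(observed - null_mean)
    p_perm = (1.0 + (centered_null >= centered_obs).sum(axis=0)) / (n_perm + 1.0)

    return pd.DataFrame(
        {
            "cv_mean": cv_w.mean(axis=0),
            "cv_sd": cv_w.std(axis=0, ddof=1),
            "observed_full": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "p_welch": p_welch,
            "p_welch_adj": bh_adjust(p_welch),
            "p_perm": p_perm,
            "p_perm_adj": bh_adjust(p_perm),
        },
        index=pd.Index(roi_names, name="roi"),
    )


def roi_score_correlations(roi: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho between every ROI volume and every score.

    Negative values mean volume loss with a higher (older / more
    AD-like) score.  Constant ROIs yield NaN cells rather than a
    fabricated coefficient.
    """
    common = roi.index.intersection(scores.index)
    if len(common) < len(scores):
        missing = scores.index.difference(roi.index)
        raise ValueError(f"scores exist for scans without volumes (e.g. {missing[:3].tolist()})")
    R = roi.loc[common].to_numpy(float)
    out = {}
    for col in scores.columns:
        s = scores.loc[common, col].to_numpy(float)
        rho = np.full(R.shape[1], np.nan)
        for j in range(R.shape[1]):
            if np.unique(R[:, j]).size < 2:
                continue  # flagged as NaN
            rho[j] = stats.spearmanr(R[:, j], s)[0]
        out[col] = rho
    return pd.DataFrame(out, index=pd.Index(roi.columns, name="roi"))


def correlation_change_significance(
    map_v1: pd.Series, map_v2: pd.Series, n: int
) -> pd.DataFrame:
    """Per-ROI Fisher-z test of the change in ROI-score correlation
    between two model versions, Benjamini-Hochberg adjusted across ROIs."""
    if not map_v1.index.equals(map_v2.index):
        raise ValueError("the two correlation maps must cover the same ROI set")
    if n <= 3:
        raise ValueError("need n > 3")
    stat = np.array(
        [fisher_z_statistic(r1, n, r2, n) for r1, r2 in zip(map_v1, map_v2)]
    )
    p = stats.chi2.sf(stat, df=1)
    return pd.DataFrame(
        {
            "rho_v1": map_v1.to_numpy(float),
            "rho_v2": map_v2.to_numpy(float),
            "statistic": stat,
            "p": p,
            "p_adj": bh_adjust(p),
            "neg_log10_p_adj": -np.log10(np.maximum(bh_adjust(p), 1e-300)),
        },
        index=map_v1.index,
    )


def mean_abs_weight(ensemble: SPAREEnsemble, roi_indices: np.ndarray) -> float:
    """Mean absolute cross-validated weight over a set of ROIs."""
    return float(np.abs(ensemble.mean_weights[roi_indices]).mean())
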