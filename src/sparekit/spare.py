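"""SPARE model training: linear SVR brain age and linear SVM disease scores.

A SPARE-BA model is an epsilon-insensitive linear support-vector
regression of chronological age on the 145 z-scored ROI volumes, trained
on control scans; the predicted age is the SPARE-BA score and the "Gap"
is SPARE-BA minus chronological age.  A SPARE-AD model is a linear
max-margin classifier separating controls from AD-spectrum cases; the
score is the signed distance to the separating hyperplane, oriented so
that cases score positive.

All models are trained with 10-fold cross-validation.  Within each fold
the ROI volumes are normalized to z-scores using means/SDs estimated on
the *control-group members of that fold's training portion* only, and
the held-out predictions provide the cross-validated fit metrics.
Scans that never entered training are scored by applying all 10 fold
models (each with its own normalizers) and averaging.

The six score versions differ only in their training samples:

========  ==========================================================
BA1/AD1   clinically defined CN vs clinical AD
BA2/AD2   amyloid-negative CN vs amyloid-positive AD continuum
BA3       combined A-/CN + AD continuum (age regression), so that
          disease-affected regions lose their age signal
AD3       SPARE-AD2 with SPARE-BA3 linearly regressed out (10-fold)
========  ==========================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import LinearSVC, LinearSVR


@dataclass
class FoldModel:
    """One cross-validation fold's linear model with its normalizers."""

    fold_index: int
    norm_mean: np.ndarray  # per-ROI, from control members of the training folds
    norm_sd: np.ndarray
    weights: np.ndarray
    intercept: float

    def score(self, values: np.ndarray) -> np.ndarray:
        z = (values - self.norm_mean) / self.norm_sd
        return z @ self.weights + self.intercept


@dataclass
class SPAREEnsemble:
    """Ten per-fold linear models plus their cross-validated predictions."""

    version: str  # BA1 | BA2 | BA3 | AD1 | AD2
    task: str  # regression | classification
    roi_names: list[str]
    fold_models: list[FoldModel]
    fold_assignment: pd.Series  # scan_id -> fold index
    cv_scores: pd.Series  # held-out prediction per training scan
    targets: pd.Series  # training target (age, or 0/1 case label)
    metrics: dict[str, float]

    @property
    def training_scan_ids(self) -> set[str]:
        return set(self.fold_assignment.index)

    def to_json(self, path: str) -> None:
        payload = {
            "version": self.version,
            "task": self.task,
            "roi_names": self.roi_names,
            "metrics": self.metrics,
            "fold_assignment": {
                "scan_id": self.fold_assignment.index.tolist(),
                "fold": self.fold_assignment.tolist(),
            },
            "cv_scores": self.cv_scores.tolist(),
            "targets": self.targets.tolist(),
            "folds": [
                {
                    "fold_index": fm.fold_index,
                    "norm_mean": fm.norm_mean.tolist(),
                    "norm_sd": fm.norm_sd.tolist(),
                    "weights": fm.weights.tolist(),
                    "intercept": fm.intercept,
                }
                for fm in self.fold_models
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SPAREEnsemble":
        with open(path) as fh:
            d = json.load(fh)
        idx = pd.Index(d["fold_assignment"]["scan_id"], name="scan_id")
        return cls(
            version=d["version"],
            task=d["task"],
            roi_names=d["roi_names"],
            fold_models=[
                FoldModel(
                    fold_index=f["fold_index"],
                    norm_mean=np.asarray(f["norm_mean"], float),
                    norm_sd=np.asarray(f["norm_sd"], float),
                    weights=np.asarray(f["weights"], float),
                    intercept=float(f["intercept"]),
                )
                for f in d["folds"]
            ],
            fold_assignment=pd.Series(d["fold_assignment"]["fold"], index=idx),
            cv_scores=pd.Series(d["cv_scores"], index=idx),
            targets=pd.Series(d["targets"], index=idx),
            metrics=d["metrics"],
        )

    @property
    def mean_weights(self) -> np.ndarray:
        return np.mean([fm.weights for fm in self.fold_models], axis=0)

    @property
    def weight_matrix(self) -> np.ndarray:
        """(k folds x n ROIs) weight matrix."""
        return np.vstack([fm.weights for fm in self.fold_models])


def _ids(cohort) -> list[str]:
    return list(cohort.scan_ids) if hasattr(cohort, "scan_ids") else list(cohort)


def _age_stratified_folds(ages: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded fold assignment balanced across the age distribution: the
    sorted ages are cut into consecutive blocks of k and each block is
    dealt to the folds in a fresh random order."""
    rng = np.random.default_rng(seed)
    jitter = rng.random(len(ages))  # random tie-break within equal ages
    order = np.lexsort((jitter, ages))
    folds = np.empty(len(ages), dtype=int)
    for start in range(0, len(order), k):
        block = order[start:start + k]
        folds[block] = rng.permutation(k)[: len(block)]
    return folds


def _class_stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        folds[idx] = np.arange(len(idx)) % k
    return folds


def _control_normalizers(
    X: np.ndarray, train_mask: np.ndarray, control_mask: np.ndarray, roi_names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    ctrl = train_mask & control_mask
    if ctrl.sum() < 2:
        raise ValueError("fewer than 2 control scans in a training fold; cannot z-score")
    mean = X[ctrl].mean(axis=0)
    sd = X[ctrl].std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [roi_names[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise ValueError(f"constant ROI volume(s) in the control group: {bad}")
    return mean, sd


def train_spare_ba(
    roi: pd.DataFrame,
    pheno: pd.DataFrame,
    training_cohort,
    control_cohort=None,
    version: str = "BA",
    k: int = 10,
    C: float = 1.0,
    epsilon: float = 0.1,
    max_iter: int = 50000,
    seed: int = 0,
) -> SPAREEnsemble:
    """Cross-validated linear SVR of age on z-scored ROI volumes.

    ``control_cohort`` designates the scans anchoring the per-fold
    z-scoring; by default the whole training cohort (the usual
    controls-only brain-age setting).  For the mixed-cohort variant the
    amyloid-negative controls should be passed explicitly.
    """
    ids = _ids(training_cohort)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scan ids in the training cohort")
    ph = pheno.set_index("scan_id").loc[ids]
    X = roi.loc[ids].to_numpy(float)
    y = ph["age"].to_numpy(float)
    control_ids = set(_ids(control_cohort)) if control_cohort is not None else set(ids)
    control_mask = np.array([s in control_ids for s in ids])
    if control_mask.sum() == 0:
        raise ValueError("control cohort has no members inside the training cohort")

    folds = _age_stratified_folds(y, k, seed)
    cv_pred = np.empty(len(ids))
    fold_models: list[FoldModel] = []
    for f in range(k):
        test = folds == f
        train = ~test
        mean, sd = _control_normalizers(X, train, control_mask, list(roi.columns))
        Z = (X[train] - mean) / sd
        est = LinearSVR(
            C=C, epsilon=epsilon, max_iter=max_iter, random_state=seed, tol=1e-5
        )
        y_center = y[train].mean()  # liblinear penalizes the intercept
        est.fit(Z, y[train] - y_center)
        b = float(est.intercept_[0] if np.ndim(est.intercept_) else est.intercept_)
        fm = FoldModel(
            fold_index=f,
            norm_mean=mean,
            norm_sd=sd,
            weights=est.coef_.copy(),
            intercept=b + y_center,
        )
        fold_models.append(fm)
        cv_pred[test] = fm.score(X[test])

    metrics = regression_metrics(y, cv_pred)
    idx = pd.Index(ids, name="scan_id")
    return SPAREEnsemble(
        version=version,
        task="regression",
        roi_names=list(roi.columns),
        fold_models=fold_models,
        fold_assignment=pd.Series(folds, index=idx),
        cv_scores=pd.Series(cv_pred, index=idx),
        targets=pd.Series(y, index=idx),
        metrics=metrics,
    )


def train_spare_ad(
    roi: pd.DataFrame,
    pheno: pd.DataFrame,
    control_cohort,
    case_cohort,
    version: str = "AD",
    k: int = 10,
    C: float = 1.0,
    max_iter: int = 50000,
    seed: int = 0,
) -> SPAREEnsemble:
    """Cross-validated linear max-margin classifier; score = signed distance
    to the hyperplane, oriented so cases are positive."""
    ctrl_ids, case_ids = _ids(control_cohort), _ids(case_cohort)
    if not ctrl_ids or not case_ids:
        raise ValueError("both cohorts must be non-empty")
    ph = pheno.set_index("scan_id")
    shared = set(ph.loc[ctrl_ids, "participant_id"]) & set(ph.loc[case_ids, "participant_id"])
    if shared:
        raise ValueError(f"case and control cohorts share {len(shared)} participants")
    ids = ctrl_ids + case_ids
    X = roi.loc[ids].to_numpy(float)
    y = np.r_[np.zeros(len(ctrl_ids), dtype=int), np.ones(len(case_ids), dtype=int)]
    control_mask = y == 0

    folds = _class_stratified_folds(y, k, seed)
    cv_score = np.empty(len(ids))
    fold_models: list[FoldModel] = []
    for f in range(k):
        test = folds == f
        train = ~test
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError(f"fold {f} is single-class; use stratified folds")
        mean, sd = _control_normalizers(X, train, control_mask, list(roi.columns))
        Z = (X[train] - mean) / sd
        est = LinearSVC(
            C=C, loss="hinge", max_iter=max_iter, random_state=seed, tol=1e-5
        )
        est.fit(Z, y[train])
        w = est.coef_.ravel().copy()
        b = float(est.intercept_[0])
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("degenerate classifier: zero weight vector")
        w, b = w / norm, b / norm  # geometric signed distance
        # orient so that the case group scores positive on the training folds
        train_scores = ((X[train] - mean) / sd) @ w + b
        if train_scores[y[train] == 1].mean() < train_scores[y[train] == 0].mean():
            w, b = -w, -b
        fm = FoldModel(fold_index=f, norm_mean=mean, norm_sd=sd, weights=w, intercept=b)
        fold_models.append(fm)
        cv_score[test] = fm.score(X[test])

    metrics = classification_metrics(y, cv_score)
    idx = pd.Index(ids, name="scan_id")
    return SPAREEnsemble(
        version=version,
        task="classification",
        roi_names=list(roi.columns),
        fold_models=fold_models,
        fold_assignment=pd.Series(folds, index=idx),
        cv_scores=pd.Series(cv_score, index=idx),
        targets=pd.Series(y, index=idx),
        metrics=metrics,
    )


def score_out_of_sample(ensemble: SPAREEnsemble, roi: pd.DataFrame) -> pd.Series:
    """Average of the 10 fold-model scores, each with its own normalizers.

    Scans that entered training must use their held-out cross-validation
    score instead; passing one here raises.
    """
    if list(roi.columns) != ensemble.roi_names:
        raise ValueError("ROI columns do not match the ensemble")
    inside = ensemble.training_scan_ids.intersection(roi.index)
    if inside:
        raise ValueError(
            f"{len(inside)} scans were part of training; use their cross-validated scores"
        )
    X = roi.to_numpy(float)
    scores = np.mean([fm.score(X) for fm in ensemble.fold_models], axis=0)
    return pd.Series(scores, index=roi.index, name=ensemble.version)


def score_all(ensemble: SPAREEnsemble, roi: pd.DataFrame) -> pd.Series:
    """Score every scan: held-out CV score for training scans, ensemble
    average for everything else."""
    out = pd.Series(np.nan, index=roi.index, name=ensemble.version, dtype=float)
    train_ids = [s for s in roi.index if s in ensemble.training_scan_ids]
    rest = roi.index.difference(train_ids)
    if train_ids:
        out.loc[train_ids] = ensemble.cv_scores.loc[train_ids]
    if len(rest):
        out.loc[rest] = score_out_of_sample(ensemble, roi.loc[rest])
    return out


def residualize_ad3(
    ad2_scores: pd.Series, ba3_scores: pd.Series, k: int = 10, seed: int = 0
) -> pd.Series:
    """SPARE-AD3: SPARE-AD2 with SPARE-BA3 linearly regressed out, 10-fold.

    Per fold, an ordinary least-squares line AD2 ~ BA3 is fitted on the
    other k-1 folds and the held-out fold keeps its residual.
    """
    if not ad2_scores.index.equals(ba3_scores.index):
        ba3_scores = ba3_scores.reindex(ad2_scores.index)
        if ba3_scores.isna().any():
            raise ValueError("AD2 and BA3 scores must cover the same scans")
    n = len(ad2_scores)
    if n < k:
        raise ValueError(f"need at least {k} scans for {k}-fold residualization, got {n}")
    rng = np.random.default_rng(seed)
    folds = rng.permuted(np.arange(n) % k)
    ad2 = ad2_scores.to_numpy(float)
    ba3 = ba3_scores.to_numpy(float)
    out = np.empty(n)
    for f in range(k):
        test = folds == f
        train = ~test
        slope, intercept = np.polyfit(ba3[train], ad2[train], 1)
        out[test] = ad2[test] - (slope * ba3[test] + intercept)
    return pd.Series(out, index=ad2_scores.index, name="AD3")


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    err = y_pred - y_true
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
    }


def classification_metrics(labels: np.ndarray, scores: np.ndarray) -> dict[str, float]:
    labels = np.asarray(labels, int)
    scores = np.asarray(scores, float)
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "accuracy": float(np.mean((scores > 0).astype(int) == labels)),
    }


def compute_fit_metrics(ensemble: SPAREEnsemble) -> dict[str, float]:
    """Cross-validated fit metrics recomputed from the stored held-out
    predictions (RMSE/MAE/R^2 for regression, AUC and zero-threshold
    accuracy for classification)."""
    y = ensemble.targets.to_numpy()
    s = ensemble.cv_scores.to_numpy(float)
    if ensemble.task == "regression":
        return regression_metrics(y, s)
    return classification_metrics(y, s)
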