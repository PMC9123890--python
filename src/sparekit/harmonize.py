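"""Study-wise harmonization of ROI volumes anchored on cognitively normal scans.

Pooling scans from several studies introduces location (and possibly
scale) batch effects per region.  The correction implemented here:

1. fits, per ROI, a pooled smooth age trend (cubic B-spline basis with
   interior knots at ages 60/70/80) plus an additive sex term using
   *cognitively normal scans only*;
2. takes the study-wise means of the CN residuals about that trend as
   the study location offsets (optionally, the ratio of residual
   standard deviations as scale factors);
3. on application, removes the study offset (and scale) from every scan
   and then removes the CN-estimated sex difference, leaving the age
   trend itself untouched.

For a train/test split the protocol is leakage-safe: the training set
is harmonized on its own; the test set is harmonized with a model fitted
on the union of the two samples, leaving the training rows unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

DEFAULT_KNOTS = (60.0, 70.0, 80.0)
DEFAULT_AGE_BOUNDS = (48.0, 95.0)


def bspline_basis(
    ages: np.ndarray,
    knots: tuple[float, ...] = DEFAULT_KNOTS,
    bounds: tuple[float, float] = DEFAULT_AGE_BOUNDS,
    degree: int = 3,
) -> np.ndarray:
    """Cubic B-spline design matrix over age, clipped to the boundary knots."""
    lo, hi = bounds
    x = np.clip(np.asarray(ages, float), lo, hi)
    t = np.concatenate([[lo] * (degree + 1), np.asarray(knots, float), [hi] * (degree + 1)])
    return BSpline.design_matrix(x, t, degree).toarray()


@dataclass
class TrendModel:
    """CN-anchored age/sex trend with per-study location(-scale) offsets."""

    roi_names: list[str]
    knots: tuple[float, ...]
    age_bounds: tuple[float, float]
    #: (n_basis x n_roi) spline coefficients of the pooled CN age trend
    trend_coef: np.ndarray
    #: per-ROI additive male-female difference estimated on CN scans
    sex_offset: np.ndarray
    #: study -> per-ROI location offset (mean CN residual)
    study_offset: dict[str, np.ndarray]
    #: study -> per-ROI scale factor (1.0 when scale adjustment is off)
    study_scale: dict[str, np.ndarray]
    adjust_scale: bool = False
    n_cn_scans: int = 0
    cn_scan_ids: list[str] = field(default_factory=list)

    def predict_trend(self, ages: np.ndarray, male: np.ndarray) -> np.ndarray:
        basis = bspline_basis(ages, self.knots, self.age_bounds)
        return basis @ self.trend_coef + np.outer(male.astype(float), self.sex_offset)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str) -> None:
        payload = {
            "roi_names": self.roi_names,
            "knots": list(self.knots),
            "age_bounds": list(self.age_bounds),
            "trend_coef": self.trend_coef.tolist(),
            "sex_offset": self.sex_offset.tolist(),
            "study_offset": {k: v.tolist() for k, v in self.study_offset.items()},
            "study_scale": {k: v.tolist() for k, v in self.study_scale.items()},
            "adjust_scale": self.adjust_scale,
            "n_cn_scans": self.n_cn_scans,
            "cn_scan_ids": self.cn_scan_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "TrendModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            roi_names=d["roi_names"],
            knots=tuple(d["knots"]),
            age_bounds=tuple(d["age_bounds"]),
            trend_coef=np.asarray(d["trend_coef"], float),
            sex_offset=np.asarray(d["sex_offset"], float),
            study_offset={k: np.asarray(v, float) for k, v in d["study_offset"].items()},
            study_scale={k: np.asarray(v, float) for k, v in d["study_scale"].items()},
            adjust_scale=d["adjust_scale"],
            n_cn_scans=d["n_cn_scans"],
            cn_scan_ids=d.get("cn_scan_ids", []),
        )


def _check_aligned(roi: pd.DataFrame, pheno: pd.DataFrame) -> pd.DataFrame:
    ph = pheno.set_index("scan_id") if "scan_id" in pheno.columns else pheno
    missing = roi.index.difference(ph.index)
    if len(missing):
        raise ValueError(f"{len(missing)} scans lack phenotype rows (e.g. {missing[0]!r})")
    return ph.loc[roi.index]


def fit_harmonizer(
    roi: pd.DataFrame,
    pheno: pd.DataFrame,
    knots: tuple[float, ...] = DEFAULT_KNOTS,
    age_bounds: tuple[float, float] = DEFAULT_AGE_BOUNDS,
    adjust_scale: bool = False,
    min_cn_per_study: int = 20,
) -> TrendModel:
    """Estimate the CN-anchored trend and study offsets.

    Only scans with ``clinical_dx == "CN"`` enter any estimation step.
    Raises when a study contributes fewer than ``min_cn_per_study`` CN
    scans (it would have no anchor) or when the design is rank deficient.
    """
    ph = _check_aligned(roi, pheno)
    cn = ph["clinical_dx"] == "CN"
    studies = ph["study"].unique().tolist()
    counts = ph.loc[cn, "study"].value_counts()
    for s in studies:
        if counts.get(s, 0) < min_cn_per_study:
            raise ValueError(
                f"study {s!r} has {counts.get(s, 0)} CN scans "
                f"(fewer than the required {min_cn_per_study}); no harmonization anchor"
            )

    ages = ph.loc[cn, "age"].to_numpy(float)
    male = (ph.loc[cn, "sex"] == "M").to_numpy()
    basis = bspline_basis(ages, knots, age_bounds)
    X = np.column_stack([basis, male.astype(float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient harmonization design (rank {rank} < {X.shape[1]}); "
            "reduce the number of spline knots or widen the age coverage"
        )
    Y = roi.loc[cn.index[cn]].to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    trend_coef, sex_offset = coef[:-1], coef[-1]

    resid = Y - X @ coef
    study_arr = ph.loc[cn, "study"].to_numpy()
    offsets: dict[str, np.ndarray] = {}
    scales: dict[str, np.ndarray] = {}
    pooled_sd = resid.std(axis=0, ddof=1)
    pooled_sd[pooled_sd == 0] = 1.0
    for s in studies:
        r = resid[study_arr == s]
        offsets[s] = r.mean(axis=0)
        if adjust_scale:
            sd = r.std(axis=0, ddof=1)
            sd[sd == 0] = pooled_sd[sd == 0]
            scales[s] = sd / pooled_sd
        else:
            scales[s] = np.ones(roi.shape[1])
    return TrendModel(
        roi_names=list(roi.columns),
        knots=tuple(knots),
        age_bounds=tuple(age_bounds),
        trend_coef=trend_coef,
        sex_offset=sex_offset,
        study_offset=offsets,
        study_scale=scales,
        adjust_scale=adjust_scale,
        n_cn_scans=int(cn.sum()),
        cn_scan_ids=roi.index[cn.to_numpy()].tolist(),
    )


def apply_harmonizer(
    model: TrendModel, roi: pd.DataFrame, pheno: pd.DataFrame
) -> pd.DataFrame:
    """Remove study offsets (and scales), then the CN-estimated sex offset.

    The age trend is left in the data.  Scans from a study unknown to the
    model raise; silently passing them through would leave batch effects.
    """
    if list(roi.columns) != model.roi_names:
        raise ValueError("ROI columns do not match the harmonization model")
    ph = _check_aligned(roi, pheno)
    unseen = set(ph["study"]) - set(model.study_offset)
    if unseen:
        raise ValueError(f"studies not present in the harmonization model: {sorted(unseen)}")

    values = roi.to_numpy(float).copy()
    study_arr = ph["study"].to_numpy()
    for s in np.unique(study_arr):
        sel = study_arr == s
        values[sel] = values[sel] - model.study_offset[s]
        if model.adjust_scale:
            values[sel] = values[sel] / model.study_scale[s]
    male = (ph["sex"] == "M").to_numpy()
    values[male] = values[male] - model.sex_offset
    return pd.DataFrame(values, index=roi.index, columns=roi.columns)


def harmonize_train_then_test(
    train_roi: pd.DataFrame,
    train_pheno: pd.DataFrame,
    test_roi: pd.DataFrame,
    test_pheno: pd.DataFrame,
    **fit_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leakage-safe two-pass protocol.

    The training sample is harmonized with a model fitted on itself.  The
    test sample is then harmonized with a model fitted on the *union* of
    the two samples (test-set batch estimates borrow strength from the
    training scans), and only the test rows receive that second model.
    Training rows are returned from the first pass, untouched by the
    second.
    """
    overlap = train_roi.index.intersection(test_roi.index)
    if len(overlap):
        raise ValueError(f"train and test scan sets overlap ({len(overlap)} scans)")
    train_model = fit_harmonizer(train_roi, train_pheno, **fit_kwargs)
    train_out = apply_harmonizer(train_model, train_roi, train_pheno)
    if len(test_roi) == 0:
        return train_out, test_roi.copy()
    union_roi = pd.concat([train_roi, test_roi])
    union_pheno = pd.concat(
        [
            train_pheno.reset_index() if "scan_id" not in train_pheno.columns else train_pheno,
            test_pheno.reset_index() if "scan_id" not in test_pheno.columns else test_pheno,
        ],
        ignore_index=True,
    )
    union_model = fit_harmonizer(union_roi, union_pheno, **fit_kwargs)
    test_out = apply_harmonizer(union_model, test_roi, test_pheno)
    return train_out, test_out
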