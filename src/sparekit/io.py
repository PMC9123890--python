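"""Tab-separated input/output for ROI volume and phenotype tables.

The on-disk schema is plain TSV with a header row: the ROI table has a
``scan_id`` key column followed by one numeric column per region; the
phenotype table carries ``participant_id, scan_id, age, sex, study,
clinical_dx, scan_order`` plus optional biomarker and psychometric
columns (missing biomarkers are empty fields).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .rois import DEFAULT_ROI_NAMES

logger = logging.getLogger(__name__)

PHENO_REQUIRED = (
    "participant_id",
    "scan_id",
    "age",
    "sex",
    "study",
    "clinical_dx",
    "scan_order",
)


def write_roi(roi: pd.DataFrame, path: str) -> None:
    roi.to_csv(path, sep="\t", index=True, index_label="scan_id")


def write_pheno(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_roi(path: str, expected_rois: list[str] | None = None) -> pd.DataFrame:
    roi = pd.read_csv(path, sep="\t", index_col="scan_id")
    if roi.index.duplicated().any():
        dup = roi.index[roi.index.duplicated()][:3].tolist()
        raise ValueError(f"duplicated scan_id in ROI table: {dup}")
    if expected_rois is not None:
        missing = [c for c in expected_rois if c not in roi.columns]
        if missing:
            raise ValueError(f"ROI table is missing expected column(s): {missing[:5]}")
        extra = [c for c in roi.columns if c not in expected_rois]
        if extra:
            raise ValueError(f"ROI table has unexpected column(s): {extra[:5]}")
        roi = roi[list(expected_rois)]
    try:
        roi = roi.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric ROI volume: {exc}") from exc
    if roi.isna().any().any():
        bad = roi.columns[roi.isna().any()][:5].tolist()
        raise ValueError(f"missing ROI values are not allowed (columns {bad})")
    return roi


def read_pheno(path: str) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_REQUIRED if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table is missing required column(s): {missing}")
    if pheno["scan_id"].duplicated().any():
        dup = pheno.loc[pheno["scan_id"].duplicated(), "scan_id"][:3].tolist()
        raise ValueError(f"duplicated scan_id in phenotype table: {dup}")
    return pheno


def read_inputs(
    roi_path: str,
    pheno_path: str,
    expected_rois: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and join the two tables on ``scan_id``.

    Phenotype rows without a matching ROI row (and vice versa) are
    excluded with a logged count; ROI values may not be missing,
    biomarkers may.
    """
    if expected_rois is None:
        expected_rois = list(DEFAULT_ROI_NAMES)
    roi = read_roi(roi_path, expected_rois)
    pheno = read_pheno(pheno_path)
    in_both = pheno["scan_id"].isin(roi.index)
    if (~in_both).any():
        logger.warning(
            "excluding %d phenotype row(s) without ROI volumes", int((~in_both).sum())
        )
        pheno = pheno[in_both].reset_index(drop=True)
    keep = roi.index.isin(pheno["scan_id"])
    if (~keep).any():
        logger.warning("excluding %d ROI row(s) without phenotype", int((~keep).sum()))
        roi = roi.loc[keep]
    roi = roi.loc[pheno["scan_id"].to_numpy()]
    return roi, pheno
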