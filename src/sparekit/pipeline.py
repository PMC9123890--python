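"""End-to-end orchestration: simulate -> harmonize -> cohorts -> train ->
score -> evaluate -> weight analysis, reproducibly from one configuration.

A single master seed determines every stochastic stage; each stage draws
its own seed as a stable hash of the stage name and the master seed, so
stages can be rerun independently yet reproducibly.  A manifest capturing
the configuration, the derived seeds, group sizes and model fit metrics
is written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as skio
from .cohorts import (
    CohortDefinition,
    CutoffConfig,
    MatchReport,
    build_groups,
    call_molecular_status,
    match_groups,
)
from .evaluate import EvaluationReport, evaluate_disentanglement, nested_lrt, spearman_table
from .harmonize import harmonize_train_then_test
from .spare import (
    SPAREEnsemble,
    residualize_ad3,
    score_all,
    train_spare_ad,
    train_spare_ba,
)
from .synthetic import GeneratorConfig, GroundTruth, generate_cohort
from .weights import (
    SpareModelSpec,
    correlation_change_significance,
    permutation_weight_test,
    roi_score_correlations,
)

logger = logging.getLogger(__name__)

MOLECULAR_VARS = (
    "abeta42",
    "florbetapir_suvr",
    "pib_suvr",
    "csf_ttau",
    "csf_ptau",
    "taupet_entorhinal",
    "taupet_inferior_temporal",
)
PSYCHOMETRIC_VARS = ("mmse", "adas_cog", "logical_memory")


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed (below 2**31)."""
    digest = hashlib.sha256(f"{stage}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """One configuration object for the whole pipeline."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    roi_path: str | None = None  # when set (with pheno_path), skip simulation
    pheno_path: str | None = None
    k_folds: int = 10
    svm_C: float = 1.0
    svr_epsilon: float = 0.1
    n_perm: int = 200
    weight_versions: tuple[str, ...] = ("BA2", "BA3", "AD2")
    match_p_floor: float = 0.2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in (
            "roi_path", "pheno_path", "k_folds", "svm_C", "svr_epsilon",
            "n_perm", "match_p_floor", "seed",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "weight_versions" in raw:
            cfg.weight_versions = tuple(raw["weight_versions"])
        gen = raw.get("generator", {})
        gen_kwargs = {}
        for key in (
            "age_range", "sex_ratio", "overlap_fraction", "noise_sd_map",
            "quadratic_age", "asymptomatic_rate", "scans_per_participant", "seed",
        ):
            if key in gen:
                val = gen[key]
                if key in ("age_range", "asymptomatic_rate") and isinstance(val, list):
                    val = tuple(val)
                if key == "scans_per_participant":
                    val = {int(k): float(v) for k, v in val.items()}
                gen_kwargs[key] = val
        if "n_participants_per_study" in gen:
            studies = GeneratorConfig().studies
            for s in studies:
                s.n_participants = int(gen["n_participants_per_study"])
            gen_kwargs["studies"] = studies
        cfg.generator = GeneratorConfig(**gen_kwargs)
        cut = raw.get("cutoffs", {})
        if cut:
            from .cohorts import MeasureCutoff

            for measure, spec in cut.get("amyloid", {}).items():
                cfg.cutoffs.amyloid[measure] = MeasureCutoff(
                    positive=float(spec["positive"]),
                    negative=float(spec["negative"]),
                    high_is_positive=bool(spec.get("high_is_positive", True)),
                )
            if "conflict_policy" in cut:
                cfg.cutoffs.conflict_policy = cut["conflict_policy"]
        return cfg


@dataclass
class PipelineResult:
    """Everything the pipeline produced, in memory."""

    roi: pd.DataFrame
    pheno: pd.DataFrame
    truth: GroundTruth | None
    status: pd.DataFrame
    groups: dict[str, CohortDefinition]
    matched: dict[str, CohortDefinition]
    match_reports: dict[str, MatchReport]
    roi_harmonized: pd.DataFrame
    ensembles: dict[str, SPAREEnsemble]
    score_table: pd.DataFrame
    evaluation: EvaluationReport
    spearman: pd.DataFrame
    lrt: list[dict]
    weight_tables: dict[str, pd.DataFrame]
    roi_correlations: pd.DataFrame
    correlation_changes: dict[str, pd.DataFrame]
    manifest: dict


def build_score_table(
    ensembles: dict[str, SPAREEnsemble],
    roi_harmonized: pd.DataFrame,
    pheno: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-scan score table: SPARE-BA1..3, Gap1..3, SPARE-AD1..2, AD3.

    Training scans carry their held-out cross-validation score; all other
    scans the 10-model ensemble average.  The Gap columns satisfy
    Gap_k = BA_k - chronological age exactly.
    """
    ages = pheno.set_index("scan_id").loc[roi_harmonized.index, "age"]
    table = pd.DataFrame(index=roi_harmonized.index)
    for version in ("BA1", "BA2", "BA3"):
        table[version] = score_all(ensembles[version], roi_harmonized)
        table[version.replace("BA", "Gap")] = table[version] - ages
    for version in ("AD1", "AD2"):
        table[version] = score_all(ensembles[version], roi_harmonized)
    table["AD3"] = residualize_ad3(table["AD2"], table["BA3"], k=k, seed=seed)
    return table


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    """Run every stage; optionally write all artifacts under ``outdir``."""
    master = config.seed
    stage = "simulate"
    try:
        truth: GroundTruth | None = None
        if config.roi_path and config.pheno_path:
            roi, pheno = skio.read_inputs(config.roi_path, config.pheno_path, None)
        else:
            gen = dataclasses.replace(
                config.generator, seed=stage_seed(master, "simulate")
            )
            roi, pheno, truth = generate_cohort(gen)
        logger.info("cohort: %d scans, %d participants", len(roi), pheno["participant_id"].nunique())

        stage = "cohorts"
        status = call_molecular_status(pheno, config.cutoffs)
        groups = build_groups(pheno, status)
        matched: dict[str, CohortDefinition] = {}
        match_reports: dict[str, MatchReport] = {}
        # all four groups share one sample size: match each pair, then
        # re-match at the smaller pair's size
        pair_args = {
            "clinical": (groups["CN"], groups["ClinicalAD"], "match_clinical"),
            "molecular": (groups["A-/CN"], groups["ADContinuum"], "match_molecular"),
        }
        sizes = {}
        for name, (ga, gb, sname) in pair_args.items():
            a, b, _ = match_groups(
                ga, gb, pheno, seed=stage_seed(master, sname),
                p_floor=config.match_p_floor,
            )
            sizes[name] = len(a)
        common = min(sizes.values())
        for name, (ga, gb, sname) in pair_args.items():
            a, b, rep = match_groups(
                ga, gb, pheno, seed=stage_seed(master, sname),
                p_floor=config.match_p_floor, target_size=common,
            )
            matched[ga.name], matched[gb.name], match_reports[name] = a, b, rep
        for name, g in matched.items():
            logger.info("matched group %s: %d scans", name, len(g))

        stage = "harmonize"
        train_ids = sorted(
            set().union(*(g.scan_ids for g in matched.values()))
        )
        test_ids = [s for s in roi.index if s not in set(train_ids)]
        train_harm, test_harm = harmonize_train_then_test(
            roi.loc[train_ids], pheno[pheno["scan_id"].isin(train_ids)],
            roi.loc[test_ids], pheno[pheno["scan_id"].isin(test_ids)],
        )
        roi_harm = pd.concat([train_harm, test_harm]).loc[roi.index]

        stage = "train"
        k, C, eps = config.k_folds, config.svm_C, config.svr_epsilon
        ens: dict[str, SPAREEnsemble] = {}
        ens["BA1"] = train_spare_ba(
            roi_harm, pheno, matched["CN"], version="BA1", k=k, C=C, epsilon=eps,
            seed=stage_seed(master, "BA1"),
        )
        ens["BA2"] = train_spare_ba(
            roi_harm, pheno, matched["A-/CN"], version="BA2", k=k, C=C, epsilon=eps,
            seed=stage_seed(master, "BA2"),
        )
        ba3_ids = matched["A-/CN"].scan_ids + matched["ADContinuum"].scan_ids
        ens["BA3"] = train_spare_ba(
            roi_harm, pheno, ba3_ids, control_cohort=matched["A-/CN"], version="BA3",
            k=k, C=C, epsilon=eps, seed=stage_seed(master, "BA3"),
        )
        ens["AD1"] = train_spare_ad(
            roi_harm, pheno, matched["CN"], matched["ClinicalAD"], version="AD1",
            k=k, C=C, seed=stage_seed(master, "AD1"),
        )
        ens["AD2"] = train_spare_ad(
            roi_harm, pheno, matched["A-/CN"], matched["ADContinuum"], version="AD2",
            k=k, C=C, seed=stage_seed(master, "AD2"),
        )
        for v, e in ens.items():
            logger.info("model %s cross-validated metrics: %s", v, e.metrics)

        stage = "score"
        score_table = build_score_table(
            ens, roi_harm, pheno, k=k, seed=stage_seed(master, "AD3")
        )

        stage = "evaluate"
        evaluation = evaluate_disentanglement(
            score_table, pheno, groups=matched, seed=stage_seed(master, "evaluate")
        )
        eval_sc = score_table.loc[evaluation.evaluation_scan_ids]
        ph_idx = pheno.set_index("scan_id")
        eval_ph = ph_idx.loc[evaluation.evaluation_scan_ids]
        impaired = eval_ph["clinical_dx"].isin(["MCI", "AD"])
        var_cols = [c for c in MOLECULAR_VARS + PSYCHOMETRIC_VARS + ("apoe4_count",)
                    if c in eval_ph.columns]
        score_cols = ["BA1", "BA2", "BA3", "AD1", "AD2", "AD3"]
        spear = spearman_table(
            eval_sc[score_cols],
            eval_ph[var_cols],
            subgroup=impaired,
            restrict_study=eval_ph["study"],
            largest_study_only=tuple(c for c in MOLECULAR_VARS if c in var_cols),
        )
        evaluation.spearman = spear
        lrt_records: list[dict] = []
        full = pd.DataFrame(
            {"BA3": eval_sc["BA3"], "Gap3": eval_sc["Gap3"], "AD3": eval_sc["AD3"]},
            index=eval_sc.index,
        )
        for outcome in PSYCHOMETRIC_VARS:
            if outcome not in eval_ph.columns:
                continue
            y = eval_ph.loc[impaired, outcome]
            Xf = full.loc[impaired[impaired].index]
            for dropped in full.columns:
                lr, df, p = nested_lrt(y, Xf, Xf.drop(columns=[dropped]))
                lrt_records.append(
                    {"outcome": outcome, "dropped": dropped, "lr": lr, "df": df, "p": p}
                )
        evaluation.lrt = lrt_records

        stage = "weights"
        weight_tables: dict[str, pd.DataFrame] = {}
        if config.n_perm > 0:
            for version in config.weight_versions:
                e = ens[version]
                if e.task == "regression":
                    ctrl = matched["A-/CN"] if version == "BA3" else None
                    spec = SpareModelSpec(
                        task="regression",
                        training_cohort=list(e.training_scan_ids),
                        control_cohort=ctrl,
                        C=C, epsilon=eps,
                    )
                else:
                    ctrl_name = "CN" if version == "AD1" else "A-/CN"
                    case_name = "ClinicalAD" if version == "AD1" else "ADContinuum"
                    spec = SpareModelSpec(
                        task="classification",
                        control_cohort=matched[ctrl_name],
                        case_cohort=matched[case_name],
                        C=C,
                    )
                weight_tables[version] = permutation_weight_test(
                    spec, roi_harm, pheno, e, n_perm=config.n_perm,
                    seed=stage_seed(master, f"perm_{version}"),
                )
        roi_corr = roi_score_correlations(roi_harm.loc[eval_sc.index], eval_sc[score_cols])
        n_eval = len(eval_sc)
        corr_changes = {
            "BA2_to_BA3": correlation_change_significance(
                roi_corr["BA2"], roi_corr["BA3"], n_eval
            ),
            "AD1_to_AD2": correlation_change_significance(
                roi_corr["AD1"], roi_corr["AD2"], n_eval
            ),
        }

        manifest = {
            "config": _config_digest(config),
            "master_seed": master,
            "stage_seeds": {
                s: stage_seed(master, s)
                for s in ("simulate", "match_clinical", "match_molecular",
                          "BA1", "BA2", "BA3", "AD1", "AD2", "AD3", "evaluate")
            },
            "n_scans": int(len(roi)),
            "n_participants": int(pheno["participant_id"].nunique()),
            "group_sizes": {name: len(g) for name, g in groups.items()},
            "matched_sizes": {name: len(g) for name, g in matched.items()},
            "metrics": {v: e.metrics for v, e in ens.items()},
        }
        result = PipelineResult(
            roi=roi, pheno=pheno, truth=truth, status=status, groups=groups,
            matched=matched, match_reports=match_reports, roi_harmonized=roi_harm,
            ensembles=ens, score_table=score_table, evaluation=evaluation,
            spearman=spear, lrt=lrt_records, weight_tables=weight_tables,
            roi_correlations=roi_corr, correlation_changes=corr_changes,
            manifest=manifest,
        )
        if outdir is not None:
            stage = "write"
            _write_outputs(result, Path(outdir))
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _config_digest(config: PipelineConfig) -> dict:
    gen = config.generator
    digest = {
        "k_folds": config.k_folds,
        "svm_C": config.svm_C,
        "svr_epsilon": config.svr_epsilon,
        "n_perm": config.n_perm,
        "match_p_floor": config.match_p_floor,
        "generator": {
            "studies": [
                {"name": s.name, "n_participants": s.n_participants}
                for s in gen.studies
            ],
            "age_range": list(gen.age_range),
            "overlap_fraction": gen.overlap_fraction,
            "n_age_rois": gen.n_age_rois,
            "n_ad_rois": gen.n_ad_rois,
        },
        "cutoffs": {
            m: {"positive": c.positive, "negative": c.negative,
                "high_is_positive": c.high_is_positive}
            for m, c in config.cutoffs.amyloid.items()
            if hasattr(c, "positive")
        },
    }
    digest["sha256"] = hashlib.sha256(
        json.dumps(digest, sort_keys=True).encode()
    ).hexdigest()
    return digest


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    skio.write_roi(result.roi, str(outdir / "roi.tsv"))
    skio.write_pheno(result.pheno, str(outdir / "pheno.tsv"))
    skio.write_roi(result.roi_harmonized, str(outdir / "roi_harmonized.tsv"))
    if result.truth is not None:
        result.truth.to_json(str(outdir / "ground_truth.json"))
    result.status.to_csv(outdir / "molecular_status.tsv", sep="\t")
    membership = pd.concat(
        [
            pd.DataFrame({"scan_id": g.scan_ids, "group": name})
            for name, g in result.matched.items()
        ]
    )
    membership.to_csv(outdir / "cohorts.tsv", sep="\t", index=False)
    for name, rep in result.match_reports.items():
        rep.to_json(str(outdir / f"match_report_{name}.json"))
    for version, e in result.ensembles.items():
        e.to_json(str(outdir / f"ensemble_{version}.json"))
    result.score_table.to_csv(outdir / "score_table.tsv", sep="\t")
    result.evaluation.to_json(str(outdir / "evaluation.json"))
    result.spearman.to_csv(outdir / "spearman_table.tsv", sep="\t", index=False)
    for version, table in result.weight_tables.items():
        table.to_csv(outdir / f"weights_{version}.tsv", sep="\t")
    result.roi_correlations.to_csv(outdir / "roi_score_correlations.tsv", sep="\t")
    for name, table in result.correlation_changes.items():
        table.to_csv(outdir / f"correlation_change_{name}.tsv", sep="\t")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
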