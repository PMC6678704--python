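"""End-to-end orchestration of the discovery and validation workflows.

Discovery: alteration matrix -> recurrent-gene filter -> elastic-net Cox
panel (deviance-ratio selection) -> NAG scores and quartile groups ->
differential expression -> signature coefficients (CV elastic-net Cox) ->
risk scores and Q3 cutoff -> survival reports.

Validation: a frozen panel, signature and cutoffs are applied to a new
cohort without refitting; adds neoantigen immunogenicity classification,
the combined better/worse classifier and the three-group stratification.

Every run writes a JSON manifest recording all thresholds and seeds, so a
rerun of the same manifest reproduces outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import alterations, neoantigen, penalized_cox, signature as sig, survival
from .synthetic import CohortBundle

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_discovery", "run_validation"]


@dataclass
class PipelineConfig:
    """Parameter registry; defaults are the analysis' canonical thresholds."""

    lrr_threshold: float = 0.5
    min_patients_recurrent: int = 2
    alpha: float = 0.1
    selection: str = "deviance-ratio"   # or "cv"
    cv_folds: int = 5
    nag_quartile: float = 0.25
    nag_threshold: float | None = None  # absolute cutoff (validation style)
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    risk_quartile: float = 0.75
    risk_cutoff: float | None = None
    affinity_threshold_nm: float = 500.0
    followup_horizon: float = 5.0
    seed: int = 0

    def manifest(self) -> dict:
        return dataclasses.asdict(self)


def _survival_reports(time, event, groups, covariates=None, adjust=None):
    """KM curves, log-rank and (optionally adjusted) Cox for a grouping."""
    groups = pd.Series(groups)
    chi2, p = survival.logrank_test(time, event, groups.to_numpy())
    km = survival.km_report(time, event, groups.to_numpy())
    labels = sorted(groups.unique())
    report = {"logrank_chi2": chi2, "logrank_p": p,
              "groups": {str(g): int((groups == g).sum()) for g in labels}}
    if len(labels) == 2:
        x = (groups == labels[1]).astype(float).to_numpy()
        names = [f"{labels[1]}_vs_{labels[0]}"]
        X = x[:, None]
        if adjust:
            X = np.column_stack([x] + [covariates[c].to_numpy(dtype=float)
                                       for c in adjust])
            names = names + list(adjust)
        data = survival.SurvivalData(time=time, event=event)
        fit = survival.cox_fit(data, covariate_names=names, X=X)
        report["cox"] = json.loads(fit.to_json())
    return report, km


def _encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Reference encodings: age>65, female, smoker, adeno as 1."""
    enc = pd.DataFrame(index=clinical.index)
    enc["age_gt_65"] = (clinical["age"] > 65).astype(float)
    enc["sex_f"] = (clinical["sex"] == "F").astype(float)
    enc["smoker"] = (clinical["smoking"] == "smoker").astype(float)
    enc["adeno"] = (clinical["histology"] == "adeno").astype(float)
    return enc


def run_discovery(bundle: CohortBundle, config: PipelineConfig | None = None,
                  outdir=None) -> dict:
    """Fit panel, NAG groups, DE genes, signature and survival reports."""
    config = config or PipelineConfig()
    if bundle.expression is None or bundle.expression.empty:
        raise ValueError("discovery requires an expression matrix")

    # stage 1: alteration matrix over the cohort
    samples = list(bundle.clinical.index)
    matrix = alterations.build_alteration_matrix(
        bundle.variants, bundle.lrr, samples=samples)
    matrix = alterations.filter_recurrent_genes(
        matrix, min_patients=config.min_patients_recurrent)
    logger.info("discovery: %d recurrent genes across %d patients",
                matrix.indicator.shape[1], matrix.indicator.shape[0])

    # stage 2: survival endpoint (OS truncated at the horizon)
    endpoints = survival.make_endpoints(bundle.clinical.reset_index())
    os_data = survival.truncate_followup(endpoints["os"], config.followup_horizon)

    # stage 3: elastic-net Cox panel selection
    X = matrix.indicator.to_numpy(dtype=float)
    if config.selection == "cv":
        fit, _cv = penalized_cox.cross_validate_lambda(
            X, os_data.time, os_data.event, folds=config.cv_folds,
            alpha=config.alpha, seed=config.seed,
            feature_names=matrix.gene_universe)
    else:
        fit = penalized_cox.fit_elasticnet_cox(
            X, os_data.time, os_data.event, alpha=config.alpha,
            feature_names=matrix.gene_universe)
        penalized_cox.select_by_deviance_ratio(fit)
    panel = penalized_cox.extract_panel(fit)
    logger.info("discovery: %d panel genes with nonzero coefficients", len(panel))
    if not panel:
        raise RuntimeError("elastic-net selected an empty panel")

    # stage 4: NAG scores and quartile dichotomization
    scores = alterations.nag_score(matrix, list(panel))
    nag_groups = alterations.dichotomize_scores(
        scores, quartile_cutoff=config.nag_quartile, threshold=config.nag_threshold)

    # stage 5: expression signature
    expr = sig.ExpressionMatrix(values=bundle.expression[samples])
    de = sig.differential_expression(expr, nag_groups,
                                     fc_threshold=config.fc_threshold,
                                     p_threshold=config.p_threshold)
    coefs = sig.derive_signature(expr, os_data.time, os_data.event,
                                 list(de.index), alpha=config.alpha,
                                 folds=config.cv_folds, seed=config.seed)
    risk = sig.expression_risk_score(expr, coefs) if coefs else pd.Series(
        0.0, index=expr.values.columns, name="risk_score")
    if coefs:
        expr_groups, risk_cutoff = sig.threshold_risk_score(
            risk, cutoff=config.risk_cutoff, quartile=config.risk_quartile)
    else:
        expr_groups = pd.Series("low_risk_expr", index=risk.index, name="expr_group")
        risk_cutoff = float("nan")

    # stage 6: survival reports for NAG groups (unadjusted + adjusted)
    report, km = _survival_reports(os_data.time, os_data.event,
                                   nag_groups.loc[samples])
    enc = _encode_clinical(bundle.clinical)
    adjusted, _ = _survival_reports(os_data.time, os_data.event,
                                    nag_groups.loc[samples], covariates=enc,
                                    adjust=["age_gt_65", "sex_f", "smoker", "adeno"])

    results = {
        "matrix": matrix,
        "panel": panel,
        "nag_scores": scores,
        "nag_groups": nag_groups,
        "de_genes": de,
        "signature_coefficients": coefs,
        "risk_scores": risk,
        "expr_groups": expr_groups,
        "risk_cutoff": risk_cutoff,
        "survival_report": report,
        "survival_report_adjusted": adjusted,
        "km_curves": km,
    }
    if outdir is not None:
        _write_outputs(results, config, Path(outdir), stage="discovery",
                       extra_counts={"recurrent_genes": matrix.indicator.shape[1],
                                     "panel_genes": len(panel),
                                     "de_genes": len(de),
                                     "signature_genes": len(coefs)})
    return results


def run_validation(bundle: CohortBundle, panel: dict[str, float],
                   signature_coefs: dict[str, float],
                   config: PipelineConfig | None = None,
                   affinity_backend=None, outdir=None) -> dict:
    """Apply a frozen panel/signature/cutoffs to a cohort; no refitting."""
    config = config or PipelineConfig()
    samples = list(bundle.clinical.index)
    matrix = alterations.build_alteration_matrix(
        bundle.variants, bundle.lrr, samples=samples)
    present = set(matrix.gene_universe) & set(panel)
    if not present:
        raise ValueError("panel genes entirely absent from the cohort")

    scores = alterations.nag_score(matrix, list(panel))
    nag_groups = alterations.dichotomize_scores(
        scores, quartile_cutoff=config.nag_quartile, threshold=config.nag_threshold)

    expr = sig.ExpressionMatrix(values=bundle.expression[samples])
    risk = sig.expression_risk_score(expr, signature_coefs)
    expr_groups, risk_cutoff = sig.threshold_risk_score(
        risk, cutoff=config.risk_cutoff, quartile=config.risk_quartile)
    combined = sig.combined_classifier(nag_groups, expr_groups)

    endpoints = survival.make_endpoints(bundle.clinical.reset_index())
    os_data = survival.truncate_followup(endpoints["os"], config.followup_horizon)

    results = {
        "nag_scores": scores,
        "nag_groups": nag_groups,
        "risk_scores": risk,
        "expr_groups": expr_groups,
        "risk_cutoff": risk_cutoff,
        "combined": combined,
    }

    report, km = _survival_reports(os_data.time, os_data.event, combined)
    results["survival_report_combined"] = report
    results["km_curves_combined"] = km

    if affinity_backend is not None:
        _, patient_calls = neoantigen.classify_cohort(
            bundle.variants, bundle.proteome, bundle.hla, bundle.expression,
            affinity_backend, affinity_threshold=config.affinity_threshold_nm,
            panel=list(panel))
        immunogenic = patient_calls["is_immunogenic"].reindex(samples).fillna(False)
        results["immunogenicity"] = patient_calls
        strata = neoantigen.three_group_stratification(nag_groups, immunogenic)
        results["three_groups"] = strata
        if strata.nunique() >= 2 and os_data.event.sum() >= 1:
            rep3, km3 = _survival_reports(os_data.time, os_data.event, strata)
            results["survival_report_three_group"] = rep3
            results["km_curves_three_group"] = km3

    if outdir is not None:
        _write_outputs(results, config, Path(outdir), stage="validation",
                       extra_counts={"panel_genes_present": len(present)})
    return results


def _write_outputs(results: dict, config: PipelineConfig, outdir: Path,
                   stage: str, extra_counts: dict | None = None) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"stage": stage, "parameters": config.manifest(),
                "lrr_gain_threshold": alterations.LRR_GAIN_THRESHOLD,
                "lrr_loss_threshold": alterations.LRR_LOSS_THRESHOLD,
                "counts": extra_counts or {}}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    def _series(name):
        obj = results.get(name)
        if obj is not None and len(obj):
            pd.Series(obj).rename(name).to_csv(outdir / f"{name}.tsv", sep="\t",
                                               float_format="%.17g")
    for name in ("nag_scores", "nag_groups", "risk_scores", "expr_groups",
                 "combined", "three_groups"):
        _series(name)
    if "panel" in results:
        pd.Series(results["panel"], name="coefficient").rename_axis("gene").to_csv(
            outdir / "panel.tsv", sep="\t", float_format="%.17g")
    if "signature_coefficients" in results:
        pd.Series(results["signature_coefficients"], name="coefficient",
                  dtype=float).rename_axis("gene").to_csv(
            outdir / "signature.tsv", sep="\t", float_format="%.17g")
    if "de_genes" in results and len(results["de_genes"]):
        results["de_genes"].to_csv(outdir / "de_genes.tsv", sep="\t",
                                   float_format="%.17g")
    for key in ("km_curves", "km_curves_combined", "km_curves_three_group"):
        if key in results and len(results[key]):
            results[key].to_csv(outdir / f"{key}.tsv", sep="\t", index=False,
                                float_format="%.17g")
    for key in ("survival_report", "survival_report_adjusted",
                "survival_report_combined", "survival_report_three_group"):
        if key in results:
            with open(outdir / f"{key}.json", "w") as fh:
                json.dump(results[key], fh, indent=2, sort_keys=True)
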