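"""End-to-end orchestration: variance filter -> consensus network ->
dual-criterion module selection -> hub genes -> drug-response model
training and selection -> patient scoring with survival validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionDataset, variance_filter_common
from .network import ConsensusNetworkResult, build_consensus_network
from .modules import (
    ConcordanceResult,
    ModuleSurvivalResult,
    cox_me_association,
    eigengene_concordance,
    select_hub_genes,
    select_significant_modules,
)
from .drugmodel import (
    CvReport,
    DrugResponseModel,
    auc_from_scores,
    fit_ensemble,
    fit_rf,
    fit_ridge,
    repeated_cv,
    select_final_model,
)
from .survival import ScoreTable, SurvivalComparison, drug_resistance_score, validate_cohort
from . import survival as _surv

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tuning knobs of the full pipeline (defaults mirror the standard
    workflow: signed network at beta 12, static cut 0.999, minimum module
    size 30, dual filter at alpha 0.05, hub threshold 0.5, ridge/forest/
    ensemble candidates compared by repeated 3-fold CV)."""

    top_fraction: float = 0.5
    beta: float = 12.0
    cut_height: float = 0.999
    min_module_size: int = 30
    alpha: float = 0.05
    kme_threshold: float = 0.5
    cv_folds: int = 3
    cv_reps: int = 100
    n_trees: int = 500
    minprop: float = 0.1
    seed: int = 0
    #: "auto" compares ridge/forest/ensemble by repeated CV + AUC + log-rank;
    #: a fixed kind skips the comparison and trains only that model
    model_selection: str = "auto"


@dataclass
class PipelineResult:
    common_genes: list[str]
    network: ConsensusNetworkResult
    survival_results: list[ModuleSurvivalResult]
    concordance_results: list[ConcordanceResult]
    selected_modules: list[str]
    hub_genes: list[str]
    models: dict[str, DrugResponseModel] = field(default_factory=dict)
    cv_report: CvReport | None = None
    final_kind: str | None = None
    final_model: DrugResponseModel | None = None
    tissue_validation: SurvivalComparison | None = None
    tissue_scores: ScoreTable | None = None


def run_pipeline(
    tissue: ExpressionDataset,
    organoid_matched: ExpressionDataset,
    organoid_independent: ExpressionDataset,
    phenotype: pd.DataFrame,
    ic50: pd.Series,
    config: PipelineConfig = PipelineConfig(),
    train_models: bool = True,
) -> PipelineResult:
    """Run the full discovery pipeline on three cohorts.

    Stops after module/hub selection (``train_models=False``, or
    automatically when no module or hub gene survives the dual filter);
    otherwise trains all three candidate drug-response models on the
    drug-response organoid cohort, assembles the selection evidence
    (repeated CV error, AUC against the tissue survival-event indicator,
    maxstat log-rank p on the tissue cohort) and validates the chosen
    model on the tissue cohort.
    """
    cfg = config
    common = variance_filter_common(
        [tissue, organoid_matched, organoid_independent], cfg.top_fraction
    )
    t, o, ind = (ds.subset_genes(common) for ds in (tissue, organoid_matched, organoid_independent))
    net = build_consensus_network(
        [t, o, ind], beta=cfg.beta, cut_height=cfg.cut_height, min_size=cfg.min_module_size
    )
    result = PipelineResult(
        common_genes=common,
        network=net,
        survival_results=[],
        concordance_results=[],
        selected_modules=[],
        hub_genes=[],
    )
    if not net.assignment.modules:
        warnings.warn("no module detected; pipeline stops after network construction")
        return result

    me_tissue = net.eigengenes[t.name or "cohort0"]
    me_organoid = net.eigengenes[o.name or "cohort1"]
    result.survival_results = cox_me_association(me_tissue, phenotype)
    result.concordance_results = eigengene_concordance(me_tissue, me_organoid)
    result.selected_modules = select_significant_modules(
        result.survival_results, result.concordance_results, alpha=cfg.alpha
    )
    if not result.selected_modules:
        return result
    result.hub_genes = select_hub_genes(
        net.kme_consensus, net.assignment.labels, result.selected_modules, cfg.kme_threshold
    )
    if not result.hub_genes or not train_models:
        return result

    hub_expr = ind.subset_genes(result.hub_genes)
    samples = [s for s in hub_expr.sample_ids if s in ic50.index]
    X = hub_expr.to_frame()[samples].to_numpy().T
    y = ic50.loc[samples].to_numpy(dtype=float)

    wanted = (
        ("ridge", "rf", "ensemble")
        if cfg.model_selection == "auto"
        else (cfg.model_selection,)
    )
    if "ridge" in wanted:
        result.models["ridge"] = fit_ridge(X, y, result.hub_genes, folds=cfg.cv_folds, seed=cfg.seed)
    if "rf" in wanted:
        result.models["rf"] = fit_rf(X, y, result.hub_genes, n_trees=cfg.n_trees, seed=cfg.seed)[0]
    if "ensemble" in wanted:
        try:
            result.models["ensemble"] = fit_ensemble(
                X, y, result.hub_genes, seed=cfg.seed, n_trees=cfg.n_trees, folds=cfg.cv_folds
            )
        except ValueError as exc:
            warnings.warn(f"ensemble unavailable: {exc}")
            if cfg.model_selection == "ensemble":
                return result

    if cfg.model_selection != "auto":
        result.final_kind = cfg.model_selection
        result.final_model = result.models[cfg.model_selection]
        result.tissue_validation, result.tissue_scores = validate_cohort(
            result.final_model, t, phenotype, minprop=cfg.minprop
        )
        return result

    event = phenotype.loc[[s for s in t.sample_ids if s in phenotype.index], "os_event"]
    entries = []
    for kind, model in result.models.items():
        cv = repeated_cv(
            kind, X, y, result.hub_genes,
            folds=cfg.cv_folds, reps=cfg.cv_reps, seed=cfg.seed, n_trees=cfg.n_trees,
        )
        scores_t = drug_resistance_score(model, t).loc[event.index]
        auc = auc_from_scores(scores_t.to_numpy(), event.to_numpy(dtype=int))
        try:
            comparison, _ = validate_cohort(model, t, phenotype, minprop=cfg.minprop)
            logrank_p = comparison.p_value
        except ValueError:
            logrank_p = float("nan")
        entries.append(
            {
                "kind": kind,
                "cv_mse_mean": cv["cv_mse_mean"],
                "cv_mse_sd": cv["cv_mse_sd"],
                "auc": auc,
                "logrank_p": logrank_p,
            }
        )
    result.cv_report = CvReport(entries=entries)
    result.final_kind = select_final_model(result.cv_report, alpha=cfg.alpha)
    result.final_model = result.models[result.final_kind]
    result.tissue_validation, result.tissue_scores = validate_cohort(
        result.final_model, t, phenotype, minprop=cfg.minprop
    )
    return result
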