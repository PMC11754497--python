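"""Dual-criterion module selection and hub-gene extraction.

A module is carried forward only when (a) its tissue eigengene is
associated with survival (univariate Cox proportional-hazards fit,
overall or recurrence-free survival, Wald p below alpha) and (b) its
tissue and matched-organoid eigengenes agree (Spearman correlation p
below alpha).  Hub genes of the selected modules are those with absolute
consensus module membership at or above a threshold (default 0.5,
boundary included).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .network import GREY, EigengeneMatrix

__all__ = [
    "ModuleSurvivalResult",
    "ConcordanceResult",
    "cox_me_association",
    "eigengene_concordance",
    "select_significant_modules",
    "select_hub_genes",
]


@dataclass
class ModuleSurvivalResult:
    module: str
    outcome: str                 # "OS" or "RFS"
    hazard_ratio: float          # exp(coefficient); NaN when the fit failed
    coefficient: float
    p_value: float               # Wald p; NaN when the fit failed
    converged: bool = True


@dataclass
class ConcordanceResult:
    module: str
    spearman_rho: float
    p_value: float
    n_pairs: int


def _fit_univariate_cox(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[float, float, bool]:
    """Univariate Cox PH fit (Efron ties, lifelines); returns
    (coefficient, Wald p, converged)."""
    df = pd.DataFrame({"x": x, "time": time, "event": event})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return math.nan, math.nan, False
    coef = float(cph.params_["x"])
    p = float(cph.summary.loc["x", "p"])
    return coef, p, True


def cox_me_association(
    eigengenes_tissue: EigengeneMatrix,
    phenotype: pd.DataFrame,
    outcomes: tuple[str, ...] = ("OS", "RFS"),
) -> list[ModuleSurvivalResult]:
    """One univariate Cox fit per module eigengene per survival outcome.

    ``phenotype`` is indexed by sample id with columns ``os_time`` /
    ``os_event`` (and ``rfs_time`` / ``rfs_event`` when RFS is requested).
    Non-convergent fits are returned flagged with missing p-values rather
    than raised.
    """
    samples = [s for s in eigengenes_tissue.sample_ids if s in phenotype.index]
    if not samples:
        raise ValueError("no eigengene sample overlaps the phenotype table")
    pheno = phenotype.loc[samples]
    results: list[ModuleSurvivalResult] = []
    for outcome in outcomes:
        tcol, ecol = f"{outcome.lower()}_time", f"{outcome.lower()}_event"
        if tcol not in pheno.columns or ecol not in pheno.columns:
            continue
        keep = pheno[tcol].notna() & pheno[ecol].notna()
        time = pheno.loc[keep, tcol].to_numpy(dtype=float)
        event = pheno.loc[keep, ecol].to_numpy(dtype=float)
        if event.sum() < 1:
            raise ValueError(f"{outcome}: no events observed")
        kept_samples = list(pheno.index[keep])
        for module in eigengenes_tissue.modules:
            x = eigengenes_tissue.values.loc[module, kept_samples].to_numpy(dtype=float)
            coef, p, ok = _fit_univariate_cox(x, time, event)
            results.append(
                ModuleSurvivalResult(
                    module=module,
                    outcome=outcome,
                    hazard_ratio=math.exp(coef) if ok else math.nan,
                    coefficient=coef,
                    p_value=p,
                    converged=ok,
                )
            )
    return results


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    denom = math.sqrt(float((rx_c**2).sum()) * float(((ry - ry.mean()) ** 2).sum()))
    if denom == 0:
        return 1.0
    count = 0
    total = 0
    ry_c = ry - ry.mean()
    for perm in itertools.permutations(range(n)):
        r = float(rx_c @ ry_c[list(perm)]) / denom
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def eigengene_concordance(
    me_tissue: EigengeneMatrix,
    me_organoid: EigengeneMatrix,
) -> list[ConcordanceResult]:
    """Per-module Spearman correlation between paired tissue and organoid
    eigengenes, aligned on shared sample identifiers.  Uses the
    t-approximation p-value, or an exact permutation p for n <= 9."""
    shared = [s for s in me_tissue.sample_ids if s in set(me_organoid.sample_ids)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 paired samples, found {len(shared)}")
    results: list[ConcordanceResult] = []
    for module in me_tissue.modules:
        if module not in me_organoid.modules:
            continue
        x = me_tissue.values.loc[module, shared].to_numpy(dtype=float)
        y = me_organoid.values.loc[module, shared].to_numpy(dtype=float)
        rho, p = stats.spearmanr(x, y)
        rho = float(rho)
        if len(shared) <= 9:
            p = _exact_spearman_p(x, y, rho)
        results.append(ConcordanceResult(module=module, spearman_rho=rho, p_value=float(p), n_pairs=len(shared)))
    return results


def select_significant_modules(
    surv_results: list[ModuleSurvivalResult],
    conc_results: list[ConcordanceResult],
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[str]:
    """Modules passing both filters: minimum Cox p over outcomes < alpha
    (so either outcome suffices) AND concordance p < alpha.  "grey" is
    never selected.  ``fdr=True`` applies Benjamini-Hochberg within each
    filter before thresholding (off by default)."""
    surv_p: dict[str, float] = {}
    for r in surv_results:
        if math.isnan(r.p_value):
            continue
        surv_p[r.module] = min(surv_p.get(r.module, math.inf), r.p_value)
    conc_p = {r.module: r.p_value for r in conc_results}
    if fdr:
        from statsmodels.stats.multitest import multipletests

        if surv_p:
            keys = list(surv_p)
            surv_p = dict(zip(keys, multipletests([surv_p[k] for k in keys], method="fdr_bh")[1]))
        if conc_p:
            keys = list(conc_p)
            conc_p = dict(zip(keys, multipletests([conc_p[k] for k in keys], method="fdr_bh")[1]))
    selected = [
        m
        for m in surv_p
        if m != GREY and surv_p[m] < alpha and conc_p.get(m, math.inf) < alpha
    ]
    # keep a deterministic order: as encountered in the survival results
    seen: list[str] = []
    for r in surv_results:
        if r.module in selected and r.module not in seen:
            seen.append(r.module)
    return seen


def select_hub_genes(
    kme_table: pd.DataFrame,
    assignment_labels: pd.Series,
    modules: list[str],
    threshold: float = 0.5,
) -> list[str]:
    """Genes of the selected modules with |consensus kME| >= threshold
    (boundary included) toward their own module.  Genes with undefined
    (missing) kME are excluded.  Returns an empty list with a warning
    rather than raising when nothing passes."""
    unknown = [m for m in modules if m not in kme_table.columns]
    if unknown:
        raise KeyError(f"module(s) not in kME table: {unknown}")
    hubs: list[str] = []
    for gene in kme_table.index:
        module = assignment_labels.get(gene, GREY)
        if module not in modules:
            continue
        value = kme_table.loc[gene, module]
        if pd.notna(value) and abs(float(value)) >= threshold:
            hubs.append(gene)
    if not hubs:
        warnings.warn("no gene passes the hub-gene membership threshold")
    return hubs
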