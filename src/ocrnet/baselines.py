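"""Comparison gene-selection procedures and over-representation analysis.

Alternative selection routes against which the main dual-filter pipeline
is benchmarked:

* per-gene association tests — a covariate-adjusted Cox fit of overall
  survival on each gene, a gene-IC50 Spearman test, and a paired
  tissue-organoid Spearman test — combined by two filtering criteria
  (all p < 0.05; optionally with agreeing survival and drug effect
  signs);
* alternative network models built on subsets of the cohorts (tissue
  only; matched tissue + organoid; drug-response organoids only, with
  module relevance judged by eigengene-IC50 correlation instead of
  survival);
* hypergeometric over-representation analysis of a gene list against
  GMT gene sets with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionDataset
from .network import build_consensus_network, module_eigengene
from .modules import cox_me_association, select_hub_genes

__all__ = [
    "per_gene_cox",
    "gene_drug_spearman",
    "paired_gene_spearman",
    "filter_by_criteria",
    "alternative_wgcna_model",
    "ora",
]


def per_gene_cox(
    expr: ExpressionDataset,
    phenotype: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex"),
) -> pd.DataFrame:
    """Cox PH fit of overall survival on each gene, adjusted for the
    requested covariates.  Returns a frame (gene, test, effect, p_value)
    where effect is the gene's log hazard ratio; non-convergent fits get
    missing effect/p and are logged via a warning."""
    samples = [s for s in expr.sample_ids if s in phenotype.index]
    if not samples:
        raise ValueError("no expression sample has phenotype data")
    missing = [c for c in covariates if c not in phenotype.columns]
    if missing:
        raise ValueError(f"requested covariate(s) absent from phenotype: {missing}")
    pheno = phenotype.loc[samples]
    base = pheno[list(covariates)].astype(float) if covariates else pd.DataFrame(index=pheno.index)
    time = pheno["os_time"].astype(float)
    event = pheno["os_event"].astype(int)
    df_expr = expr.to_frame()[samples]
    rows = []
    failed = 0
    for gene in expr.gene_ids:
        df = base.copy()
        df["gene"] = df_expr.loc[gene].to_numpy()
        df["time"] = time.to_numpy()
        df["event"] = event.to_numpy()
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            rows.append((gene, "cox_os", float(cph.params_["gene"]), float(cph.summary.loc["gene", "p"])))
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            failed += 1
            rows.append((gene, "cox_os", math.nan, math.nan))
    if failed:
        warnings.warn(f"{failed} per-gene Cox fit(s) did not converge")
    return pd.DataFrame(rows, columns=["gene", "test", "effect", "p_value"])


def _per_gene_spearman(
    expr_a: pd.DataFrame, target: pd.DataFrame | pd.Series, test_name: str
) -> pd.DataFrame:
    rows = []
    for gene in expr_a.index:
        x = expr_a.loc[gene].to_numpy(dtype=float)
        y = (target.loc[gene] if isinstance(target, pd.DataFrame) else target).to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((gene, test_name, math.nan, math.nan))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append((gene, test_name, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "test", "effect", "p_value"])
    n_bad = out["p_value"].isna().sum()
    if n_bad:
        warnings.warn(f"{test_name}: {n_bad} constant gene(s) skipped")
    return out


def gene_drug_spearman(expr: ExpressionDataset, ic50: pd.Series) -> pd.DataFrame:
    """Per-gene Spearman correlation between expression and IC50."""
    samples = [s for s in expr.sample_ids if s in ic50.index]
    if len(samples) < 4:
        raise ValueError("need >= 4 samples with drug response")
    return _per_gene_spearman(expr.to_frame()[samples], ic50.loc[samples], "spearman_drug")


def paired_gene_spearman(tissue: ExpressionDataset, organoid: ExpressionDataset) -> pd.DataFrame:
    """Per-gene Spearman correlation between paired tissue and organoid
    expression, aligned on shared sample ids and gene ids."""
    samples = [s for s in tissue.sample_ids if s in set(organoid.sample_ids)]
    if len(samples) < 4:
        raise ValueError("need >= 4 paired samples")
    genes = [g for g in tissue.gene_ids if g in set(organoid.gene_ids)]
    t = tissue.to_frame().loc[genes, samples]
    o = organoid.to_frame().loc[genes, samples]
    return _per_gene_spearman(t, o, "spearman_paired")


def filter_by_criteria(
    tables: Mapping[str, pd.DataFrame],
    criterion: int = 1,
    alpha: float = 0.05,
) -> list[str]:
    """Combine the three association tables.

    Criterion 1: genes with all three p-values < alpha.  Criterion 2:
    criterion 1 and agreeing signs of the survival log hazard ratio and
    the drug-response correlation.  ``tables`` must hold keys
    ``cox_os``, ``spearman_drug`` and ``spearman_paired``."""
    required = {"cox_os", "spearman_drug", "spearman_paired"}
    if not required.issubset(tables):
        raise KeyError(f"tables must contain {sorted(required)}")
    if criterion not in (1, 2):
        raise ValueError("criterion must be 1 or 2")
    indexed = {k: t.set_index("gene") for k, t in tables.items()}
    genes = indexed["cox_os"].index
    out = []
    for gene in genes:
        ps = [indexed[k].loc[gene, "p_value"] for k in ("cox_os", "spearman_drug", "spearman_paired")]
        if any(pd.isna(p) or p >= alpha for p in ps):
            continue
        if criterion == 2:
            hr_sign = np.sign(indexed["cox_os"].loc[gene, "effect"])
            drug_sign = np.sign(indexed["spearman_drug"].loc[gene, "effect"])
            if hr_sign != drug_sign:
                continue
        out.append(gene)
    return out


def alternative_wgcna_model(
    variant: int,
    tissue: ExpressionDataset,
    organoid_matched: ExpressionDataset,
    organoid_independent: ExpressionDataset,
    phenotype: pd.DataFrame,
    ic50: pd.Series,
    beta: float = 12.0,
    cut_height: float = 0.999,
    min_size: int = 30,
    alpha: float = 0.05,
    kme_threshold: float = 0.5,
) -> list[str]:
    """Comparison network models over cohort subsets.

    Variant 1: network on tissue only, module relevance by Cox on OS.
    Variant 2: consensus network on matched organoid + tissue, relevance
    by Cox on OS.  Variant 3: network on the drug-response organoid
    cohort only, relevance by Spearman correlation of each eigengene with
    IC50.  All variants filter hubs at |consensus kME| >= threshold and
    apply no concordance filter."""
    if variant not in (1, 2, 3):
        raise ValueError("variant must be 1, 2 or 3")
    if variant == 1:
        datasets = [tissue]
    elif variant == 2:
        datasets = [organoid_matched, tissue]
    else:
        datasets = [organoid_independent]
    net = build_consensus_network(datasets, beta=beta, cut_height=cut_height, min_size=min_size)
    if not net.assignment.modules:
        return []
    if variant in (1, 2):
        tissue_name = tissue.name or ("cohort0" if variant == 1 else "cohort1")
        mes = net.eigengenes[tissue_name]
        surv = cox_me_association(mes, phenotype, outcomes=("OS",))
        selected = sorted(
            {r.module for r in surv if not math.isnan(r.p_value) and r.p_value < alpha}
        )
    else:
        mes = next(iter(net.eigengenes.values()))
        samples = [s for s in mes.sample_ids if s in ic50.index]
        if len(samples) < 4:
            raise ValueError("need >= 4 organoid samples with drug response")
        selected = []
        for module in mes.modules:
            rho, p = stats.spearmanr(
                mes.values.loc[module, samples].to_numpy(),
                ic50.loc[samples].to_numpy(),
            )
            if p < alpha:
                selected.append(module)
    if not selected:
        return []
    return select_hub_genes(
        net.kme_consensus, net.assignment.labels, selected, threshold=kme_threshold
    )


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    overlap: int
    p_value: float
    fdr: float


def ora(
    query_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis.

    Each gene set is intersected with the universe; sets whose intersected
    size falls outside [min_size, max_size] are dropped.  The reported
    p-value is the upper-tail hypergeometric probability of observing at
    least the achieved overlap between query and set within the universe
    (overlap 0 gives p = 1); FDR is Benjamini-Hochberg across the
    retained sets."""
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query = set(query_genes) & universe_set
    stray = set(query_genes) - universe_set
    if stray:
        warnings.warn(f"{len(stray)} query gene(s) outside the universe ignored")
    n_universe = len(universe_set)
    n_query = len(query)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe_set
        k_set = len(in_universe)
        if not (min_size <= k_set <= max_size):
            continue
        overlap = len(query & in_universe)
        # P(X >= overlap), X ~ Hypergeom(universe, set, draws=query)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, k_set, n_query))
        rows.append((name, k_set, overlap, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(columns=["set_name", "set_size", "overlap", "p_value", "fdr"])
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
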