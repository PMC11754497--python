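"""Signed weighted co-expression networks and their multi-cohort consensus.

Per cohort: a signed similarity s_ij = (1 + cor(x_i, x_j)) / 2 raised to a
soft-thresholding power beta gives the adjacency a_ij = s_ij**beta; the
adjacency is converted to a topological overlap matrix (TOM), a robust
connection measure that rewards shared neighborhoods.  Per-cohort TOMs are
put on a common scale by full quantile normalization of their off-diagonal
entries and combined component-wise (mean by default) into a consensus
TOM.  Modules are the clusters of an average-linkage tree over 1 - TOM cut
at a fixed height, with undersized clusters relegated to the reserved
"grey" label; each module is summarized by its eigengene (first principal
component of the standardized module expression), and gene-module
membership (kME) is the correlation of a gene with an eigengene,
averaged across cohorts for the consensus kME.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .io import ExpressionDataset

__all__ = [
    "GREY",
    "MODULE_COLORS",
    "AdjacencyMatrix",
    "TomMatrix",
    "ModuleAssignment",
    "EigengeneMatrix",
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "topological_overlap",
    "calibrate_toms",
    "consensus_tom",
    "detect_modules",
    "module_eigengene",
    "kme",
    "consensus_kme",
    "ConsensusNetworkResult",
    "build_consensus_network",
]

GREY = "grey"

#: canonical module color sequence, assigned to clusters by decreasing size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


def _check_square(values: np.ndarray, gene_ids: Sequence[str], what: str) -> None:
    n = len(gene_ids)
    if values.shape != (n, n):
        raise ValueError(f"{what}: matrix shape {values.shape} != ({n}, {n})")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError(f"{what}: matrix not symmetric")
    if values.min() < -1e-12 or values.max() > 1 + 1e-12:
        raise ValueError(f"{what}: entries outside [0, 1]")


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    values: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_square(self.values, self.gene_ids, "adjacency")


@dataclass
class TomMatrix:
    gene_ids: list[str]
    values: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_square(self.values, self.gene_ids, "TOM")


@dataclass
class ModuleAssignment:
    """gene -> module label; "grey" marks unassigned genes."""

    labels: pd.Series  # index: gene ids, values: module labels

    @property
    def modules(self) -> list[str]:
        """Non-grey module labels, largest module first."""
        counts = self.labels[self.labels != GREY].value_counts()
        return list(counts.index)

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


@dataclass
class EigengeneMatrix:
    """Module eigengenes (rows) by samples (columns), plus per-module
    explained-variance fractions."""

    values: pd.DataFrame
    var_explained: pd.Series

    @property
    def modules(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _pearson_matrix(expr: ExpressionDataset) -> np.ndarray:
    sd = expr.values.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [expr.gene_ids[i] for i in constant[:5]]
        raise ValueError(f"constant gene(s) with undefined correlation: {names}")
    r = np.corrcoef(expr.values)
    return np.clip(r, -1.0, 1.0)


def signed_adjacency(expr: ExpressionDataset, beta: float = 12.0) -> AdjacencyMatrix:
    """Signed-network adjacency a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta."""
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r = _pearson_matrix(expr)
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    return AdjacencyMatrix(gene_ids=list(expr.gene_ids), values=a, beta=beta)


def scale_free_fit(adjacency: AdjacencyMatrix, n_bins: int = 10) -> tuple[float, float]:
    """Goodness of scale-free topology: R^2 and slope of log10(freq) on
    log10(mean connectivity) over equal-width connectivity bins.

    Connectivity of gene i is the sum of its off-diagonal adjacencies.
    A warning is raised when only two bins are occupied (the fit is then
    trivially perfect).
    """
    n = len(adjacency.gene_ids)
    if n < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} genes for {n_bins} bins")
    k = adjacency.values.sum(axis=0) - np.diag(adjacency.values)
    if np.ptp(k) == 0:
        raise ValueError("all connectivities equal; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    mean_k = np.array([k[idx == b].mean() if freq[b] else np.nan for b in range(n_bins)])
    keep = (freq > 0) & (mean_k > 0)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable bins; scale-free fit undefined")
    if keep.sum() == 2:
        warnings.warn("only 2 occupied connectivity bins: R^2 = 1 by construction")
    x = np.log10(mean_k[keep])
    y = np.log10(freq[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / float(ss_tot)
    return float(r2), float(slope)


def pick_soft_threshold(
    expr: ExpressionDataset,
    beta_grid: Sequence[float] | None = None,
    r2_target: float = 0.75,
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Scan soft-threshold powers; return the smallest beta whose network
    reaches the scale-free fit target with negative slope, plus the scan
    table.  Falls back (with a warning) to the best-fitting beta when none
    reaches the target.

    The pipeline default keeps beta fixed at 12; this scan is diagnostic.
    """
    if beta_grid is None:
        beta_grid = list(range(1, 21))
    if not len(beta_grid):
        raise ValueError("empty beta grid")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    r = _pearson_matrix(expr)
    s = (1.0 + r) / 2.0
    rows = []
    for beta in beta_grid:
        a = s**beta
        np.fill_diagonal(a, 1.0)
        adj = AdjacencyMatrix(gene_ids=list(expr.gene_ids), values=a, beta=beta)
        r2, slope = scale_free_fit(adj, n_bins=n_bins)
        rows.append({"beta": beta, "r_squared": r2, "slope": slope})
    scan = pd.DataFrame(rows)
    ok = scan[(scan.r_squared >= r2_target) & (scan.slope < 0)]
    if len(ok):
        return float(ok.beta.iloc[0]), scan
    warnings.warn(
        f"no beta reaches scale-free R^2 >= {r2_target}; "
        "returning the best-fitting beta"
    )
    return float(scan.beta.iloc[int(scan.r_squared.idxmax())]), scan


def topological_overlap(adjacency: AdjacencyMatrix) -> TomMatrix:
    """Unsigned topological overlap:
    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, with
    l_ij = sum_u a_iu * a_uj (u != i, j) and k_i the connectivity; diag 1.
    """
    a = adjacency.values.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # diag(a)=0 makes u=i and u=j terms vanish
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TomMatrix(gene_ids=list(adjacency.gene_ids), values=tom, calibrated=False)


def _upper(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu], iu


def _quantile_normalize_columns(mat: np.ndarray) -> np.ndarray:
    """Full quantile normalization of columns; tied entries within a column
    receive the average of the target values their positions span."""
    n, m = mat.shape
    order = np.argsort(mat, axis=0, kind="stable")
    target = np.mean(np.take_along_axis(mat, order, axis=0), axis=1)
    out = np.empty_like(mat)
    for j in range(m):
        col_sorted_target = np.empty(n)
        col_sorted_target[order[:, j]] = target
        # average target values over ties in the source column
        x = mat[:, j]
        uniq, inv = np.unique(x, return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=col_sorted_target)
            counts = np.bincount(inv)
            col_sorted_target = (sums / counts)[inv]
        out[:, j] = col_sorted_target
    return out


def calibrate_toms(toms: Sequence[TomMatrix]) -> list[TomMatrix]:
    """Full quantile normalization of the off-diagonal upper-triangle
    entries across cohorts, so all TOMs share the same distribution
    (the mean of the per-cohort order statistics).  Symmetry and the unit
    diagonal are restored; ties map to the average of their would-be
    target values.
    """
    if len(toms) < 2:
        raise ValueError("need at least 2 TOMs to calibrate")
    genes = toms[0].gene_ids
    for t in toms[1:]:
        if t.gene_ids != genes:
            raise ValueError("TOMs must share an identical gene set and order")
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    stacked = np.column_stack([t.values[iu] for t in toms])
    normed = _quantile_normalize_columns(stacked)
    out = []
    for j, t in enumerate(toms):
        v = np.eye(n)
        v[iu] = normed[:, j]
        v = v + np.triu(v, k=1).T
        out.append(TomMatrix(gene_ids=list(genes), values=np.clip(v, 0.0, 1.0), calibrated=True))
    return out


def consensus_tom(
    toms: Sequence[TomMatrix], operator: Literal["mean", "min"] = "mean"
) -> TomMatrix:
    """Component-wise consensus of calibrated TOMs (mean by default; the
    conservative component-wise minimum is available via ``operator``)."""
    if not len(toms):
        raise ValueError("empty TOM list")
    genes = toms[0].gene_ids
    for t in toms[1:]:
        if t.gene_ids != genes:
            raise ValueError("TOMs must share an identical gene set and order")
    stack = np.stack([t.values for t in toms])
    values = stack.mean(axis=0) if operator == "mean" else stack.min(axis=0)
    return TomMatrix(gene_ids=list(genes), values=values, calibrated=all(t.calibrated for t in toms))


def _adaptive_cut_height(linkage: np.ndarray, ceiling: float, min_size: int) -> float:
    """Data-adaptive cut height below ``ceiling``: the number of clusters
    of size >= ``min_size`` is tracked along the merge sequence, and the
    cut is placed in the middle of the height interval over which that
    count is maximal (the most stable rich module structure).

    Quantile calibration piles TOM dissimilarities up just below 1, so a
    fixed cut very close to 1 is scale-sensitive; scanning the merge
    sequence instead is scale-free.  The scan is a single union-find pass
    over the merges (heights are non-decreasing for average linkage); a
    partition is realizable only when the next merge sits strictly higher.
    """
    n = linkage.shape[0] + 1
    heights = linkage[:, 2]
    sizes = np.ones(2 * n - 1, dtype=int)
    big = 0
    candidates: list[tuple[float, int]] = []  # (cut height, big-cluster count)
    for i in range(n - 1):
        a, b = int(linkage[i, 0]), int(linkage[i, 1])
        merged = sizes[a] + sizes[b]
        sizes[n + i] = merged
        big += int(merged >= min_size) - int(sizes[a] >= min_size) - int(sizes[b] >= min_size)
        h = heights[i]
        if h >= ceiling:
            break
        next_h = heights[i + 1] if i + 1 < n - 1 else ceiling
        if next_h <= h:  # tied heights: this intermediate partition is not cut-realizable
            continue
        candidates.append(((h + min(next_h, ceiling)) / 2.0, big))
    if not candidates:
        return ceiling
    best = max(c for _, c in candidates)
    if best == 0:
        return ceiling
    plateau = [cut for cut, c in candidates if c == best]
    target = (plateau[0] + plateau[-1]) / 2.0
    return min(plateau, key=lambda cut: (abs(cut - target), cut))


def detect_modules(
    tom: TomMatrix,
    cut_height: float = 0.999,
    min_size: int = 30,
    method: Literal["adaptive", "static"] = "adaptive",
) -> tuple[ModuleAssignment, np.ndarray]:
    """Average-linkage clustering of 1 - TOM with min-size-to-grey
    relabeling; surviving clusters are named by decreasing size along the
    canonical color sequence.  Returns the assignment and the scipy
    linkage matrix (the dendrogram).

    ``method="static"`` cuts the tree at exactly ``cut_height``.  The
    default ``"adaptive"`` treats ``cut_height`` as a ceiling (its role
    in dynamic tree-cutting) and places the cut at the lowest height that
    maximizes the number of clusters of size >= ``min_size`` — a fixed
    cut near 1 degenerates to a single cluster on calibrated consensus
    TOMs, whose dissimilarities concentrate just below 1.
    """
    d = 1.0 - tom.values
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    linkage = average(squareform(d, checks=False))
    if method == "static":
        cut = cut_height
    else:
        cut = _adaptive_cut_height(linkage, cut_height, min_size)
    raw = fcluster(linkage, t=cut, criterion="distance")
    labels = pd.Series(GREY, index=pd.Index(tom.gene_ids, name="gene"), dtype=object)
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_size]
    # deterministic naming: by decreasing size, ties by smallest cluster id
    ranked = sorted(big.items(), key=lambda kv: (-kv[1], kv[0]))
    for rank, (cluster_id, _size) in enumerate(ranked):
        name = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.iloc[np.flatnonzero(raw == cluster_id)] = name
    return ModuleAssignment(labels=labels), linkage


def module_eigengene(expr: ExpressionDataset, assignment: ModuleAssignment) -> EigengeneMatrix:
    """Per-module eigengene: the first right singular vector (unit norm)
    of the module's standardized gene-by-sample block, sign-aligned so the
    mean correlation with the module's genes is positive.  Also reports
    the fraction of variance the eigengene explains."""
    df = expr.to_frame()
    rows: dict[str, np.ndarray] = {}
    ve: dict[str, float] = {}
    for module in assignment.modules:
        genes = [g for g in assignment.genes_in(module) if g in df.index]
        block = df.loc[genes].to_numpy()
        sd = block.std(axis=1)
        if (sd == 0).any():
            dropped = [genes[i] for i in np.flatnonzero(sd == 0)]
            warnings.warn(f"module {module}: dropping zero-variance gene(s) {dropped[:5]}")
            keep = sd > 0
            block, sd, genes = block[keep], sd[keep], [g for g, k in zip(genes, keep) if k]
        if len(genes) < 2:
            raise ValueError(f"module {module}: fewer than 2 usable genes")
        z = (block - block.mean(axis=1, keepdims=True)) / sd[:, None]
        _u, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        corr_sign = np.sign(np.mean(z @ me))
        if corr_sign < 0:
            me = -me
        rows[module] = me
        ve[module] = float(s[0] ** 2 / np.sum(s**2))
    values = pd.DataFrame(rows, index=expr.sample_ids).T
    return EigengeneMatrix(values=values, var_explained=pd.Series(ve))


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def kme(expr: ExpressionDataset, eigengenes: EigengeneMatrix) -> pd.DataFrame:
    """Module membership per cohort: Pearson correlation of each gene's
    profile with each module eigengene.  Constant genes yield NaN."""
    df = expr.to_frame()[eigengenes.sample_ids]
    out = pd.DataFrame(index=df.index, columns=eigengenes.modules, dtype=float)
    for module in eigengenes.modules:
        me = eigengenes.values.loc[module].to_numpy()
        me_c = me - me.mean()
        denom_me = np.sqrt((me_c**2).sum())
        x = df.to_numpy()
        x_c = x - x.mean(axis=1, keepdims=True)
        denom_x = np.sqrt((x_c**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (x_c @ me_c) / (denom_x * denom_me)
        r[denom_x == 0] = np.nan
        out[module] = np.clip(r, -1.0, 1.0)
    return out


def consensus_kme(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted mean of per-cohort kME tables (aligned on genes/modules)."""
    if not len(tables):
        raise ValueError("no kME tables")
    aligned = [t.reindex(index=tables[0].index, columns=tables[0].columns) for t in tables]
    return sum(aligned) / len(aligned)


@dataclass
class ConsensusNetworkResult:
    """Full output of the consensus network construction."""

    gene_ids: list[str]
    beta: float
    toms: list[TomMatrix]                      # calibrated per-cohort TOMs
    consensus: TomMatrix
    assignment: ModuleAssignment
    linkage: np.ndarray
    eigengenes: dict[str, EigengeneMatrix]     # cohort name -> MEs
    kme_per_cohort: dict[str, pd.DataFrame]
    kme_consensus: pd.DataFrame


def build_consensus_network(
    datasets: Sequence[ExpressionDataset],
    beta: float = 12.0,
    cut_height: float = 0.999,
    min_size: int = 30,
    consensus_operator: Literal["mean", "min"] = "mean",
    cut_method: Literal["adaptive", "static"] = "adaptive",
    keep_toms: bool = False,
) -> ConsensusNetworkResult:
    """End-to-end consensus network: adjacency -> TOM per cohort, quantile
    calibration (skipped for a single cohort), component-wise consensus,
    module detection, eigengenes and kME per cohort plus consensus kME.

    All datasets must share an identical gene list (use
    :func:`ocrnet.io.variance_filter_common` plus ``subset_genes`` first).
    """
    if not datasets:
        raise ValueError("no datasets")
    genes = datasets[0].gene_ids
    for ds in datasets[1:]:
        if ds.gene_ids != genes:
            raise ValueError("datasets must share an identical gene list and order")
    toms = [topological_overlap(signed_adjacency(ds, beta)) for ds in datasets]
    if len(toms) > 1:
        toms = calibrate_toms(toms)
    cons = consensus_tom(toms, operator=consensus_operator)
    assignment, linkage = detect_modules(
        cons, cut_height=cut_height, min_size=min_size, method=cut_method
    )
    eigengenes = {ds.name or f"cohort{i}": module_eigengene(ds, assignment) for i, ds in enumerate(datasets)}
    kme_tables = {
        name: kme(ds, mes) for (name, mes), ds in zip(eigengenes.items(), datasets)
    }
    kcons = consensus_kme(list(kme_tables.values()))
    return ConsensusNetworkResult(
        gene_ids=list(genes),
        beta=beta,
        toms=toms if keep_toms else [],
        consensus=cons,
        assignment=assignment,
        linkage=linkage,
        eigengenes=eigengenes,
        kme_per_cohort=kme_tables,
        kme_consensus=kcons,
    )
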