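"""Reading, writing and preprocessing of expression, phenotype, drug-response
and gene-set tables.

Expression matrices follow the series-matrix convention: genes in rows,
samples in columns, tab-delimited, first column holds gene identifiers
(the first header cell is ignored).  All loaders validate their input and
raise :class:`ParseError` with the offending row/column named.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "read_drug_response",
    "write_drug_response",
    "read_gmt",
    "write_gmt",
    "collapse_probes",
    "log2_transform",
    "variance_filter_common",
]


class ParseError(ValueError):
    """Raised when a tabular input violates the format contract."""


@dataclass
class ExpressionDataset:
    """A gene-by-sample real-valued expression matrix.

    Values are assumed to be on a normalized (typically log) scale already;
    no normalization is performed here.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    name: str = ""
    platform: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ParseError(f"duplicate gene ids: {sorted(dup)[:5]}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ParseError(f"duplicate sample ids: {sorted(dup)[:5]}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            g, s = bad[0]
            raise ParseError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r} ({len(bad)} cells total)"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "", platform: str = "") -> "ExpressionDataset":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            name=name,
            platform=platform,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        """Return a dataset restricted to ``genes`` in the given order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in dataset {self.name!r}: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionDataset(
            gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            name=self.name,
            platform=self.platform,
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sep_for(path: Path, csv: bool) -> str:
    if csv or path.suffix.lower() == ".csv":
        return ","
    return "\t"


def read_expression(
    path: str | Path,
    *,
    csv: bool = False,
    drop_na_genes: bool = False,
    name: str | None = None,
    platform: str = "",
) -> ExpressionDataset:
    """Read a gene-by-sample expression matrix from TSV (or CSV with ``csv=True``).

    Rows with missing values are rejected unless ``drop_na_genes`` is set,
    in which case they are dropped and logged.  Duplicate gene or sample
    identifiers raise :class:`ParseError` naming the identifier.
    """
    path = Path(path)
    sep = _sep_for(path, csv)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found (malformed header?)")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    dup = _duplicates(list(df.columns))
    if dup:
        raise ParseError(f"{path}: duplicate sample id(s): {sorted(dup)}")
    dup = _duplicates(list(df.index))
    if dup:
        raise ParseError(
            f"{path}: duplicate gene id(s): {sorted(dup)[:5]}; "
            "collapse probes first if this is a probe-level matrix"
        )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
    if df.isna().any().any():
        if drop_na_genes:
            n0 = len(df)
            df = df.dropna(axis=0)
            logger.warning("%s: dropped %d gene rows with missing values", path, n0 - len(df))
        else:
            gene = df.index[df.isna().any(axis=1)][0]
            raise ParseError(
                f"{path}: missing value in gene row {gene!r} "
                "(use drop_na_genes to drop such rows)"
            )
    return ExpressionDataset.from_frame(df, name=name if name is not None else path.stem, platform=platform)


def write_expression(dataset: ExpressionDataset, path: str | Path, *, csv: bool = False) -> None:
    path = Path(path)
    sep = _sep_for(path, csv)
    df = dataset.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep)  # default repr formatting round-trips exactly


_PHENO_REQUIRED = ["sample_id", "os_time", "os_event"]
_PHENO_OPTIONAL = ["rfs_time", "rfs_event", "age", "sex"]


def read_phenotype(path: str | Path, *, csv: bool = False) -> pd.DataFrame:
    """Read a per-sample phenotype table (survival outcomes plus covariates).

    Required columns: ``sample_id``, ``os_time``, ``os_event``; optional:
    ``rfs_time``, ``rfs_event``, ``age``, ``sex``.  Times must be positive,
    events binary, sample ids unique.  Returns a frame indexed by sample_id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, csv))
    missing = [c for c in _PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    dup = _duplicates(list(df["sample_id"]))
    if dup:
        raise ParseError(f"{path}: duplicate sample id(s): {sorted(dup)}")
    df = df.set_index("sample_id")
    validate_phenotype(df, source=str(path))
    return df


def validate_phenotype(df: pd.DataFrame, source: str = "phenotype") -> None:
    for prefix in ("os", "rfs"):
        tcol, ecol = f"{prefix}_time", f"{prefix}_event"
        if tcol not in df.columns:
            continue
        times = df[tcol].dropna()
        if (times <= 0).any():
            raise ParseError(f"{source}: {tcol} must be positive")
        events = df[ecol].dropna()
        if not set(np.unique(events)).issubset({0, 1}):
            raise ParseError(f"{source}: {ecol} must be binary 0/1")


def write_phenotype(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index() if df.index.name == "sample_id" else df
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_drug_response(path: str | Path, *, csv: bool = False) -> pd.Series:
    """Read a (sample_id, ic50) table; returns a Series indexed by sample_id.

    IC50 values are used as provided; whether they are on a raw or log
    concentration scale is the caller's concern (``log_ic50`` flags upstream).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, csv))
    for col in ("sample_id", "ic50"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    dup = _duplicates(list(df["sample_id"]))
    if dup:
        raise ParseError(f"{path}: duplicate sample id(s): {sorted(dup)}")
    vals = pd.to_numeric(df["ic50"], errors="coerce")
    if vals.isna().any():
        bad = df.loc[vals.isna(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: non-finite ic50 for sample {bad!r}")
    return pd.Series(vals.to_numpy(dtype=float), index=df["sample_id"], name="ic50")


def write_drug_response(ic50: pd.Series, path: str | Path) -> None:
    out = ic50.rename("ic50").rename_axis("sample_id").reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def _iqr(row: np.ndarray) -> float:
    # type-7 (linear interpolation) quantiles, the numpy default
    q3, q1 = np.percentile(row, [75, 25])
    return float(q3 - q1)


def collapse_probes(
    probe_dataset: ExpressionDataset,
    probe_to_gene: Mapping[str, str],
) -> ExpressionDataset:
    """Collapse a probe-level matrix to one row per gene.

    Each gene is represented by the row of its probe with the largest
    interquartile range across samples; IQR ties are broken by the
    lexicographically smallest probe id.  Probes absent from the map are
    dropped.  Output gene order follows first appearance of each gene
    among the mapped probes.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene map")
    best: dict[str, tuple[float, str, int]] = {}  # gene -> (iqr, probe, row index)
    order: list[str] = []
    for i, probe in enumerate(probe_dataset.gene_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        iqr = _iqr(probe_dataset.values[i])
        cur = best.get(gene)
        if cur is None:
            order.append(gene)
            best[gene] = (iqr, probe, i)
        elif iqr > cur[0] or (iqr == cur[0] and probe < cur[1]):
            best[gene] = (iqr, probe, i)
    if not best:
        raise ValueError("no probe in the matrix maps to a gene")
    rows = [best[g][2] for g in order]
    return ExpressionDataset(
        gene_ids=order,
        sample_ids=list(probe_dataset.sample_ids),
        values=probe_dataset.values[rows, :],
        name=probe_dataset.name,
        platform=probe_dataset.platform,
    )


def log2_transform(dataset: ExpressionDataset, offset: float = 1.0) -> ExpressionDataset:
    """Elementwise log2(value + offset); offset defaults to 1."""
    shifted = dataset.values + offset
    if (shifted <= 0).any():
        bad = np.argwhere(shifted <= 0)
        cells = [
            f"({dataset.gene_ids[g]}, {dataset.sample_ids[s]})" for g, s in bad[:5]
        ]
        raise ValueError(
            f"log2 undefined for {len(bad)} cell(s) with value + offset <= 0: "
            + ", ".join(cells)
        )
    return ExpressionDataset(
        gene_ids=list(dataset.gene_ids),
        sample_ids=list(dataset.sample_ids),
        values=np.log2(shifted),
        name=dataset.name,
        platform=dataset.platform,
    )


def variance_filter_common(
    datasets: Sequence[ExpressionDataset],
    top_fraction: float = 0.5,
) -> list[str]:
    """Intersect the per-dataset top-variance gene sets across cohorts.

    In each dataset, genes are ranked by variance (descending, stable order
    for ties) and the top ``ceil(top_fraction * n_genes)`` retained; the
    returned list is the intersection of those sets across all datasets,
    ordered as in the first dataset.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    kept_sets: list[set[str]] = []
    for ds in datasets:
        var = ds.values.var(axis=1, ddof=1) if ds.n_samples > 1 else np.zeros(ds.n_genes)
        k = math.ceil(top_fraction * ds.n_genes)
        order = np.argsort(-var, kind="stable")[:k]
        kept_sets.append({ds.gene_ids[i] for i in order})
    common = set.intersection(*kept_sets)
    if not common:
        raise ValueError(
            "no gene passes the variance filter in every dataset; "
            "try a larger top_fraction"
        )
    return [g for g in datasets[0].gene_ids if g in common]
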