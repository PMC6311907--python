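"""Readers/writers and the expression preprocessing recipe.

The preprocessing operations mirror the standard pipeline for integrating
microarray cohorts against an interaction network: collapse probes to
genes by mean, drop genes absent from the network, keep the top-k
most-variable genes per cohort and intersect across cohorts, then impute
missing values by the gene mean and standardize each gene per cohort.

File dialects: expression TSV/CSV with samples as rows (first column =
sample name, header = feature names; ``transpose=True`` accepts the
genes-as-rows dialect), two- or three-column edge lists, and the SIF
dialect ``nodeA relation nodeB``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("intlognet")


@dataclass
class ExpressionTable:
    """Samples x features expression values with optional probe->gene map."""

    values: pd.DataFrame  # index = sample names, columns = feature names
    probe_gene_map: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("sample names must be unique")

    @property
    def sample_names(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=np.float64)


# ---------------------------------------------------------------- readers

def read_expression(path, sep: str = "\t", transpose: bool = False) -> ExpressionTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionTable(values=df)


def write_expression(table: ExpressionTable, path, sep: str = "\t") -> None:
    out = table.values.copy()
    out.index.name = out.index.name or "sample"
    out.to_csv(path, sep=sep, float_format="%.12g")


def read_labels(path, sep: str = "\t") -> pd.DataFrame:
    """Labels TSV with columns sample, dataset_id, Y."""
    df = pd.read_csv(path, sep=sep)
    required = {"sample", "dataset_id", "Y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"labels file is missing columns: {sorted(missing)}")
    df["sample"] = df["sample"].astype(str)
    return df


def read_network_edges(path) -> list[tuple]:
    """Edge list from a 2/3-column TSV or a SIF file (by extension).

    SIF lines are ``nodeA relation nodeB [nodeC ...]``; other files are
    ``nodeA<TAB>nodeB[<TAB>weight]`` with an optional header line.
    """
    path = Path(path)
    edges: list[tuple] = []
    if path.suffix.lower() == ".sif":
        for line in path.read_text().splitlines():
            parts = line.split()
            if len(parts) >= 3:
                a, targets = parts[0], parts[2:]
                edges.extend((a, b) for b in targets)
        return edges
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            if i == 0:
                # tolerate a header row: third column non-numeric, or
                # conventional column names
                try:
                    float(parts[2]) if len(parts) > 2 else None
                except ValueError:
                    continue
                if parts[0].lower() in ("nodea", "source", "from", "gene1"):
                    continue
            if len(parts) >= 3 and parts[2]:
                edges.append((parts[0], parts[1], float(parts[2])))
            else:
                edges.append((parts[0], parts[1]))
    return edges


# ---------------------------------------------------- preprocessing recipe

def collapse_probes_mean(
    table: ExpressionTable, probe_gene_map: Optional[dict] = None
) -> ExpressionTable:
    """Average probe columns mapping to the same gene; drop unmapped probes."""
    mapping = probe_gene_map or table.probe_gene_map
    if not mapping:
        raise ValueError("a probe->gene map is required")
    mapped = [p for p in table.feature_names if p in mapping]
    if not mapped:
        raise ValueError("no probes overlap the probe->gene map")
    n_dropped = len(table.feature_names) - len(mapped)
    if n_dropped:
        logger.warning("dropping %d probes missing from the probe->gene map", n_dropped)
    sub = table.values[mapped]
    collapsed = sub.T.groupby([mapping[p] for p in mapped]).mean().T
    collapsed.columns = [str(c) for c in collapsed.columns]
    return ExpressionTable(values=collapsed)


def filter_to_network_genes(
    table: ExpressionTable, network_nodes: Sequence[str]
) -> ExpressionTable:
    """Keep only features present in the network, preserving column order."""
    nodes = set(str(n) for n in network_nodes)
    keep = [g for g in table.feature_names if g in nodes]
    if not keep:
        raise ValueError("no features remain after filtering to network genes")
    return ExpressionTable(values=table.values[keep])


def top_variance_then_intersect(
    tables: Sequence[ExpressionTable], k: int = 2000
) -> list[str]:
    """Top-k by-variance genes per table, intersected across tables.

    Variance uses the unbiased (n-1) estimator; ranking ties break by gene
    name so the result is order-deterministic.  Returns the intersection
    stable-sorted by name.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to intersect")
    chosen = []
    for t in tables:
        var = t.values.var(axis=0, ddof=1)
        kk = k
        if kk > len(var):
            logger.warning(
                "k=%d exceeds the %d available genes; using all", k, len(var)
            )
            kk = len(var)
        ranked = sorted(var.items(), key=lambda gv: (-gv[1], str(gv[0])))
        chosen.append({str(g) for g, _ in ranked[:kk]})
    inter = set.intersection(*chosen)
    if not inter:
        logger.warning("top-%d variance gene sets have an empty intersection", k)
    return sorted(inter)


def impute_and_normalize(table: ExpressionTable) -> ExpressionTable:
    """Mean-impute missing values per gene, then standardize each gene.

    Standardization is to mean 0 and unit sd (n-1 denominator) within the
    table — i.e. per cohort when applied cohort by cohort.  Constant genes
    become all-zero columns with a warning.
    """
    df = table.values.copy()
    all_missing = df.columns[df.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"gene(s) with all values missing: {list(map(str, all_missing))}"
        )
    df = df.fillna(df.mean(axis=0))
    sd = df.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant gene(s) standardized to all-zero columns",
            int(constant.sum()),
        )
    sd = sd.mask(constant, 1.0)
    out = (df - df.mean(axis=0)) / sd
    out.loc[:, constant] = 0.0
    return ExpressionTable(values=out)


# ----------------------------------------------------------- fit-ready IO

def assemble_design(
    tables: Sequence[ExpressionTable], labels: Sequence[pd.DataFrame]
):
    """Stack cohort tables + label frames into (datasets, feature_names).

    Returns a list of (X, Y) pairs in cohort order; every table must share
    the same feature columns (order included).
    """
    if len(tables) != len(labels):
        raise ValueError("one labels frame per expression table is required")
    names = tables[0].feature_names
    datasets = []
    for i, (t, lab) in enumerate(zip(tables, labels), start=1):
        if t.feature_names != names:
            raise ValueError(f"table {i} feature columns disagree with table 1")
        lab = lab.set_index("sample").loc[t.sample_names]
        datasets.append((t.matrix, lab["Y"].to_numpy(dtype=np.float64)))
    return datasets, names
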