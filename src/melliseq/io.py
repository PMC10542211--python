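"""Reading and writing the file formats the pipeline touches.

Count data travel as 10x-style bundles: a Matrix Market sparse matrix
(genes x cells, coordinate format, integer field), a two-column feature
table and a one-column barcode list.  Graphs are written as edge-list TSV
or GraphML, cluster assignments as TSV.  All writers round-trip exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import anndata as ad
import igraph
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountBundle",
    "read_count_bundle",
    "write_count_bundle",
    "merge_stages",
    "write_graph",
    "read_graph",
    "write_cluster_table",
    "read_cluster_table",
    "flag_mitochondrial",
]


@dataclass(frozen=True)
class CountBundle:
    """One stage's UMI counts on disk: matrix + features + barcodes.

    The matrix is Matrix Market coordinate format, genes x cells, 1-based
    indices, integer entries (the 10x convention); plain or gzipped files
    are both accepted.  ``features_path`` is a TSV with columns
    ``gene_id`` and ``gene_name`` (no header); ``barcodes_path`` holds one
    barcode per line.
    """

    matrix_path: Path
    features_path: Path
    barcodes_path: Path
    stage_label: str

    def __post_init__(self) -> None:
        for attr in ("matrix_path", "features_path", "barcodes_path"):
            object.__setattr__(self, attr, Path(getattr(self, attr)))


def _read_table(path: Path, n_cols: int) -> pd.DataFrame:
    # pandas transparently decompresses .gz
    return pd.read_csv(path, sep="\t", header=None, dtype=str).iloc[:, :n_cols]


def flag_mitochondrial(
    adata: ad.AnnData,
    pattern: str | None = None,
    gene_ids: Iterable[str] | None = None,
) -> None:
    """Set ``var['mito']`` from a regex on gene names/IDs and/or an explicit ID list.

    Honey bee mitochondrial genes do not follow the vertebrate ``MT-``
    prefix, so there is no default pattern: with both arguments ``None``
    every gene is flagged ``False``.
    """
    mito = np.zeros(adata.n_vars, dtype=bool)
    if pattern is not None:
        rx = re.compile(pattern)
        names = adata.var.get("gene_name", pd.Series(adata.var_names, index=adata.var_names))
        mito |= np.array(
            [bool(rx.search(str(n))) or bool(rx.search(str(i))) for n, i in zip(names, adata.var_names)]
        )
    if gene_ids is not None:
        wanted = set(gene_ids)
        mito |= adata.var_names.isin(wanted)
    adata.var["mito"] = mito


def read_count_bundle(
    bundle: CountBundle,
    mito_pattern: str | None = None,
    mito_gene_ids: Iterable[str] | None = None,
) -> ad.AnnData:
    """Load one count bundle into an AnnData (cells x genes).

    Validates that the Matrix Market header dimensions match the feature
    and barcode files and that all entries are non-negative integers.
    ``obs['stage']`` carries the bundle's stage label; mitochondrial genes
    are flagged in ``var['mito']``.
    """
    for p in (bundle.matrix_path, bundle.features_path, bundle.barcodes_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"count bundle file not found: {p}")

    mat = sp.coo_matrix(scipy.io.mmread(str(bundle.matrix_path)))
    features = _read_table(bundle.features_path, 2)
    barcodes = _read_table(bundle.barcodes_path, 1)

    if mat.shape[0] != len(features):
        raise ValueError(
            f"{bundle.features_path}: {len(features)} features but matrix declares "
            f"{mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"{bundle.barcodes_path}: {len(barcodes)} barcodes but matrix declares "
            f"{mat.shape[1]} columns"
        )
    if mat.nnz and mat.data.min() < 0:
        raise ValueError(f"{bundle.matrix_path}: negative count entries")
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError(f"{bundle.matrix_path}: non-integer count entries")

    var = pd.DataFrame(
        {"gene_name": features.iloc[:, 1].values if features.shape[1] > 1 else features.iloc[:, 0].values},
        index=pd.Index(features.iloc[:, 0].values, name="gene_id"),
    )
    obs = pd.DataFrame(
        {"stage": pd.Categorical([bundle.stage_label] * len(barcodes))},
        index=pd.Index(barcodes.iloc[:, 0].values, name="barcode"),
    )
    adata = ad.AnnData(X=sp.csr_matrix(mat.T, dtype=np.int64), obs=obs, var=var)
    flag_mitochondrial(adata, mito_pattern, mito_gene_ids)
    return adata


def write_count_bundle(adata: ad.AnnData, outdir: Path, stage_label: str | None = None) -> CountBundle:
    """Write an AnnData back to a 10x-style bundle (genes x cells on disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix_path = outdir / "matrix.mtx"
    features_path = outdir / "features.tsv"
    barcodes_path = outdir / "barcodes.tsv"

    X = sp.coo_matrix(adata.X).T  # genes x cells on disk
    scipy.io.mmwrite(str(matrix_path), X, field="integer")
    gene_names = adata.var.get("gene_name", pd.Series(adata.var_names, index=adata.var_names))
    pd.DataFrame({0: adata.var_names, 1: gene_names.values}).to_csv(
        features_path, sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(barcodes_path, sep="\t", header=False, index=False)
    if stage_label is None:
        stages = adata.obs["stage"].unique()
        if len(stages) != 1:
            raise ValueError("bundle must be single-stage; pass stage_label explicitly")
        stage_label = str(stages[0])
    return CountBundle(matrix_path, features_path, barcodes_path, stage_label)


def merge_stages(matrices: Sequence[ad.AnnData]) -> ad.AnnData:
    """Concatenate per-stage count matrices into one.

    The gene set is the union with missing entries zero-filled, stage
    labels are preserved per cell, and barcodes are made unique by
    suffixing the stage tag.  Total UMI count is preserved.
    """
    if len(matrices) == 0:
        raise ValueError("merge_stages requires at least one matrix")
    suffixed = []
    for m in matrices:
        m = m.copy()
        stage = m.obs["stage"].astype(str)
        m.obs_names = [f"{bc}-{st}" for bc, st in zip(m.obs_names, stage)]
        suffixed.append(m)
    merged = ad.concat(suffixed, join="outer", fill_value=0, merge="first", index_unique=None)
    if merged.obs_names.has_duplicates:
        dup = merged.obs_names[merged.obs_names.duplicated()][0]
        raise ValueError(f"duplicate barcode after stage suffixing: {dup!r}")
    merged.X = sp.csr_matrix(merged.X)
    return merged


# ---------------------------------------------------------------------------
# graphs

_GRAPH_FORMATS = ("edgelist", "graphml")


def write_graph(graph: igraph.Graph, path: Path, fmt: str = "edgelist") -> None:
    """Write a weighted graph as edge-list TSV or GraphML.

    Edge-list columns are source, target, weight (weights printed with 10
    significant digits so a read-back reproduces the graph exactly);
    isolated nodes are listed after the edges with an empty target.
    """
    path = Path(path)
    if fmt == "graphml":
        graph.write_graphml(str(path))
        return
    if fmt != "edgelist":
        raise ValueError(f"unknown graph format {fmt!r}; expected one of {_GRAPH_FORMATS}")
    names = graph.vs["name"] if "name" in graph.vs.attributes() else [str(i) for i in range(graph.vcount())]
    rows = []
    for e in graph.es:
        rows.append((names[e.source], names[e.target], f"{e['weight']:.10g}"))
    connected = {names[e.source] for e in graph.es} | {names[e.target] for e in graph.es}
    for n in names:
        if n not in connected:
            rows.append((n, "", ""))
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, sep="\t", index=False)


def read_graph(path: Path, fmt: str = "edgelist") -> igraph.Graph:
    """Read a graph written by :func:`write_graph`."""
    path = Path(path)
    if fmt == "graphml":
        return igraph.Graph.Read_GraphML(str(path))
    if fmt != "edgelist":
        raise ValueError(f"unknown graph format {fmt!r}; expected one of {_GRAPH_FORMATS}")
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    isolated = df["target"].isna() | (df["target"] == "")
    edges_df = df.loc[~isolated]
    nodes: list[str] = []
    seen: set[str] = set()
    for n in pd.concat([edges_df["source"], edges_df["target"], df.loc[isolated, "source"]]):
        if n not in seen:
            seen.add(n)
            nodes.append(n)
    g = igraph.Graph()
    g.add_vertices(nodes)
    g.add_edges(list(zip(edges_df["source"], edges_df["target"])))
    g.es["weight"] = edges_df["weight"].astype(float).tolist()
    return g


# ---------------------------------------------------------------------------
# cluster tables


def write_cluster_table(assignment: pd.DataFrame | dict, path: Path) -> None:
    """Write a cell clustering as TSV with columns barcode, stage, cluster_id.

    ``assignment`` is a DataFrame indexed by barcode with columns ``stage``
    and ``cluster_id`` (or a dict barcode -> (stage, cluster_id)).  Rows are
    sorted lexicographically by barcode so output is deterministic.
    """
    if isinstance(assignment, dict):
        assignment = pd.DataFrame.from_dict(assignment, orient="index", columns=["stage", "cluster_id"])
    df = assignment.loc[:, ["stage", "cluster_id"]].copy()
    df.index.name = "barcode"
    df.sort_index(kind="mergesort").to_csv(path, sep="\t")


def read_cluster_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="barcode", dtype={"stage": str})
    df["cluster_id"] = df["cluster_id"].astype(int)
    return df
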