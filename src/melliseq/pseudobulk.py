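"""Artifact-filtered pseudobulk: collapse cells to per-cluster, per-stage profiles.

Averaging single cells of a cluster into one pseudobulk column amplifies
biological between-cluster signal, but naive averages are distorted by
dropouts (false zeros) and by expression spikes in single cells.  Before
averaging, three zeroing rules therefore silence a gene within a cluster
when the evidence for its expression is too thin, and per-gene expression
is capped at the cluster's 95th percentile to tame outliers.  Clusters
containing cells from both developmental stages contribute one column per
stage ("stage-differentiated clusters").
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PseudobulkMatrix",
    "apply_expression_filters",
    "cap_at_percentile",
    "aggregate_by_cluster_stage",
]


@dataclass
class PseudobulkMatrix:
    """Genes x stage-cluster average expression with per-column metadata."""

    values: pd.DataFrame  # genes x columns
    meta: pd.DataFrame  # per column: cluster_id, stage, n_cells

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        header = self.meta.copy()
        header.index.name = "column"
        out = self.values.copy()
        out.index.name = "gene_id"
        header.T.to_csv(str(path) + ".meta", sep="\t")
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PseudobulkMatrix":
        values = pd.read_csv(path, sep="\t", index_col="gene_id")
        meta = pd.read_csv(str(path) + ".meta", sep="\t", index_col=0).T
        meta.index.name = "column"
        meta["cluster_id"] = meta["cluster_id"].astype(int)
        meta["n_cells"] = meta["n_cells"].astype(int)
        return cls(values, meta)


def apply_expression_filters(
    values: np.ndarray,
    min_cells: int = 3,
    min_max: float = 0.5,
    min_frac: float = 0.05,
) -> np.ndarray:
    """Zero out unreliably detected genes within one cluster.

    ``values`` is cells x genes (log-normalized) for the cells of a single
    cluster.  A gene is zeroed across all cells of the cluster if ANY of
    the three conditions holds: (1) fewer than ``min_cells`` cells express
    it, (2) its maximum expression is below ``min_max``, (3) fewer than
    ``min_frac`` of the cluster's cells express it.  "Expressed" means a
    strictly positive value; conditions are evaluated on the unfiltered
    input.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 1:
        raise ValueError("need a cells x genes matrix with at least one cell")
    n_cells = values.shape[0]
    n_expr = (values > 0).sum(axis=0)
    gene_max = values.max(axis=0)
    kill = (n_expr < min_cells) | (gene_max < min_max) | (n_expr / n_cells < min_frac)
    out = values.copy()
    out[:, kill] = 0.0
    return out


def cap_at_percentile(values: np.ndarray, q: float = 95.0, method: str = "linear") -> np.ndarray:
    """Cap each gene's expression at the q-th percentile over the cluster's cells.

    The percentile is computed over all cells (zeros included) with linear
    interpolation between order statistics; values above the cap are
    replaced by the cap.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot cap an empty array")
    cap = np.percentile(values, q, axis=0, method=method)
    return np.minimum(values, cap)


def aggregate_by_cluster_stage(
    nm: ad.AnnData,
    assignment: pd.Series,
    min_cells: int = 3,
    min_max: float = 0.5,
    min_frac: float = 0.05,
    percentile: float = 95.0,
    per_stage_filters: bool = False,
) -> PseudobulkMatrix:
    """Filtered, capped, stage-split cluster averages.

    For each cluster the zeroing rules and the percentile cap are applied
    over all its cells pooled across stages (set ``per_stage_filters`` to
    evaluate them per stage instead), then the arithmetic mean is taken
    separately for each stage present in the cluster.  Mixed-stage
    clusters thus yield one column per stage; column names are
    ``C<cluster>_<stage>``.
    """
    cells = assignment.index
    missing = set(cells) - set(nm.obs_names)
    if missing:
        raise KeyError(f"clustered cells missing from matrix: {sorted(missing)[:5]} ...")
    cols: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for cid in sorted(assignment.unique()):
        members = assignment.index[assignment == cid]
        sub = nm[members]
        X = np.asarray(sub.X.todense()) if sp.issparse(sub.X) else np.asarray(sub.X, dtype=float)
        stages = sub.obs["stage"].astype(str).values
        if per_stage_filters:
            for stage in sorted(set(stages)):
                Xs = X[stages == stage]
                Y = cap_at_percentile(
                    apply_expression_filters(Xs, min_cells, min_max, min_frac), percentile
                )
                name = f"C{cid}_{stage}"
                cols[name] = Y.mean(axis=0)
                meta_rows.append({"column": name, "cluster_id": int(cid), "stage": stage, "n_cells": int(Xs.shape[0])})
        else:
            Y = cap_at_percentile(
                apply_expression_filters(X, min_cells, min_max, min_frac), percentile
            )
            for stage in sorted(set(stages)):
                mask = stages == stage
                name = f"C{cid}_{stage}"
                cols[name] = Y[mask].mean(axis=0)
                meta_rows.append({"column": name, "cluster_id": int(cid), "stage": stage, "n_cells": int(mask.sum())})
    values = pd.DataFrame(cols, index=nm.var_names)
    meta = pd.DataFrame(meta_rows).set_index("column")
    return PseudobulkMatrix(values, meta)
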