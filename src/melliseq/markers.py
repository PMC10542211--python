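"""Marker detection (one-vs-rest Wilcoxon) and gene-set over-representation.

Marker genes of a cell cluster are found by the rank-sum (Wilcoxon /
Mann-Whitney) test of the gene's log-normalized expression in the cluster
against all other cells, after the usual detection-rate and fold-change
pre-filters, with Bonferroni adjustment per cluster.  Over-representation
of a query gene set in annotated gene sets (e.g. GO terms mapped through a
homolog table) uses the upper-tail hypergeometric test with
Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_markers",
    "ora_enrichment",
    "read_gmt",
    "apply_homolog_map",
]

MARKER_COLUMNS = ["gene", "cluster", "log2_fc", "pct_in", "pct_out", "p_value", "adj_p_value"]


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided rank-sum p-value: exact enumeration for small tie-free
    groups, normal approximation with tie correction otherwise."""
    exact = len(x) <= exact_max_n and len(y) <= exact_max_n and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    res = mannwhitneyu(x, y, alternative="two-sided", method="exact" if exact else "asymptotic")
    return float(res.pvalue)


def _fold_change(x_in: np.ndarray, x_out: np.ndarray) -> float:
    # fold change on de-logged expression with unit pseudocount, reported base 2
    return float(np.log2((np.expm1(x_in).mean() + 1) / (np.expm1(x_out).mean() + 1)))


def wilcoxon_markers(
    nm: ad.AnnData,
    assignment: pd.Series,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    groups: str = "cluster",
) -> pd.DataFrame:
    """One-vs-rest differential expression per cluster.

    For each cluster (or (cluster, stage) group when ``groups`` is
    ``"cluster_stage"``), genes pass a pre-filter — detected in at least
    ``min_pct`` of cells on one side and absolute log2 fold change at
    least ``logfc_min`` — then the two-sided Wilcoxon rank-sum test
    compares in-cluster against all other cells.  P-values are
    Bonferroni-adjusted over the genes tested within the cluster.
    Clusters of a single cell are skipped with a warning.
    """
    if assignment.nunique() < 2:
        raise ValueError("need at least 2 clusters for one-vs-rest testing")
    nm = nm[assignment.index]
    X = np.asarray(nm.X.todense()) if sp.issparse(nm.X) else np.asarray(nm.X, dtype=float)

    if groups == "cluster":
        labels = assignment.astype(str)
    elif groups == "cluster_stage":
        labels = assignment.astype(str) + "_" + nm.obs["stage"].astype(str).values
    else:
        raise ValueError(f"unknown grouping {groups!r}")

    records: list[dict] = []
    for group in sorted(labels.unique()):
        mask = (labels == group).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"cluster {group} has fewer than 2 cells; skipped")
            continue
        Xin, Xout = X[mask], X[~mask]
        pct_in = (Xin > 0).mean(axis=0)
        pct_out = (Xout > 0).mean(axis=0)
        lfc = np.log2((np.expm1(Xin).mean(axis=0) + 1) / (np.expm1(Xout).mean(axis=0) + 1))
        testable = np.flatnonzero(
            (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(lfc) >= logfc_min)
        )
        n_tested = len(testable)
        for gi in testable:
            p = rank_sum_test(Xin[:, gi], Xout[:, gi])
            records.append(
                {
                    "gene": nm.var_names[gi],
                    "cluster": group,
                    "log2_fc": float(lfc[gi]),
                    "pct_in": float(pct_in[gi]),
                    "pct_out": float(pct_out[gi]),
                    "p_value": p,
                    "adj_p_value": min(1.0, p * n_tested),
                }
            )
    return pd.DataFrame(records, columns=MARKER_COLUMNS)


def read_gmt(path: Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: set_id <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def apply_homolog_map(genes: list[str] | set[str], mapping: pd.DataFrame | Path) -> set[str]:
    """Translate gene IDs through a two-column homolog table (source, target).

    Genes without a mapping are dropped; used to express bee genes in the
    namespace of an external annotation before set intersection.
    """
    if not isinstance(mapping, pd.DataFrame):
        mapping = pd.read_csv(mapping, sep="\t", header=None, dtype=str)
    lut: dict[str, str] = dict(zip(mapping.iloc[:, 0], mapping.iloc[:, 1]))
    return {lut[g] for g in genes if g in lut}


def ora_enrichment(
    query: set[str] | list[str],
    sets: dict[str, list[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    With universe size N, set size K (after intersecting with the
    universe), query size n and overlap k, the p-value is the upper tail
    P(X >= k) of Hypergeom(N, K, n).  Benjamini-Hochberg adjustment is
    applied across sets; the result is sorted by adjusted p-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    rows = []
    for set_id, members in sets.items():
        K = len(set(members) & universe)
        if K == 0:
            continue
        k = len(query & set(members))
        p = float(hypergeom.sf(k - 1, len(universe), K, len(query)))
        rows.append({"set_id": set_id, "set_size": K, "overlap": k, "p_value": min(1.0, p)})
    df = pd.DataFrame(rows, columns=["set_id", "set_size", "overlap", "p_value"])
    if len(df):
        df["adj_p_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values(["adj_p_value", "p_value", "set_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["adj_p_value"] = []
    return df
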