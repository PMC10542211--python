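"""QC, normalization, variable genes, covariate regression, PCA, JackStraw.

The stages mirror the standard droplet scRNA-seq workflow: cells are
filtered on library size and mitochondrial UMI fraction, genes on the
number of cells expressing them; counts are log-normalized per cell;
highly variable genes are picked by binned standardized dispersion;
technical covariates (library size, mitochondrial fraction) are regressed
out gene-wise and residuals standardized; PCA reduces the scaled matrix;
and JackStraw permutations assign each principal component a significance
p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy.stats import binomtest

__all__ = [
    "PCSpace",
    "filter_cells",
    "filter_genes",
    "log_normalize",
    "find_variable_genes",
    "regress_and_scale",
    "run_pca",
    "jackstraw",
]


def _totals(adata: ad.AnnData) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell total UMI count and mitochondrial fraction from raw counts."""
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    if "mito" not in adata.var:
        raise ValueError("mitochondrial flags missing: run flag_mitochondrial first")
    mito_mask = adata.var["mito"].values.astype(bool)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return total, frac


def filter_cells(adata: ad.AnnData, min_umi: int = 700, max_mito: float = 0.10) -> ad.AnnData:
    """Remove low-complexity and mitochondria-dominated cells.

    A cell is kept iff its total UMI count is strictly greater than
    ``min_umi`` AND its mitochondrial UMI fraction is strictly below
    ``max_mito`` (so a cell at exactly 700 UMIs, or exactly 10% mito, is
    removed).  Per-stage removal counts per rule are recorded in
    ``uns['qc_cells']``.
    """
    total, frac = _totals(adata)
    low_umi = total <= min_umi
    high_mito = frac >= max_mito
    keep = ~(low_umi | high_mito)

    report = []
    for stage in pd.unique(adata.obs["stage"].astype(str)):
        m = (adata.obs["stage"].astype(str) == stage).values
        report.append(
            {
                "stage": stage,
                "n_cells_raw": int(m.sum()),
                "removed_low_umi": int((m & low_umi).sum()),
                "removed_high_mito": int((m & high_mito).sum()),
                "n_cells_removed": int((m & ~keep).sum()),
                "n_cells_kept": int((m & keep).sum()),
            }
        )
    out = adata[keep].copy()
    out.uns["qc_cells"] = pd.DataFrame(report)
    if out.n_obs == 0:
        warnings.warn("all cells removed by QC filters")
    return out


def filter_genes(adata: ad.AnnData, min_cells: int = 4) -> ad.AnnData:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells.

    The default of 4 removes genes expressed in 3 or fewer cells.
    """
    X = sp.csc_matrix(adata.X)
    n_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = n_cells >= min_cells
    out = adata[:, keep].copy()
    out.uns["qc_genes"] = {
        "n_genes_raw": int(adata.n_vars),
        "removed_low_detection": int((~keep).sum()),
        "n_genes_kept": int(keep.sum()),
    }
    return out


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size normalize and log-transform: ln(1 + count/total * scale_factor).

    Raw counts are preserved in ``layers['counts']``; per-cell totals and
    mitochondrial fractions (from raw counts) go to ``obs['total_counts']``
    and ``obs['mito_frac']`` for later covariate regression.
    """
    total, frac = _totals(adata)
    if (total == 0).any():
        bad = adata.obs_names[total == 0][0]
        raise ValueError(f"cell {bad!r} has zero total count; run filter_cells first")
    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    out.obs["total_counts"] = total
    out.obs["mito_frac"] = frac
    out.X = out.X.astype(np.float64)
    sc.pp.normalize_total(out, target_sum=scale_factor)
    sc.pp.log1p(out)
    return out


def find_variable_genes(
    nm: ad.AnnData,
    mean_low: float = 0.0125,
    mean_high: float = 3.0,
    disp_cutoff: float = 0.5,
    method: str = "dispersion",
    n_bins: int = 20,
) -> list[str]:
    """Select highly variable genes, sorted by descending variability.

    ``method='dispersion'`` (default) is the binned standardized dispersion
    statistic: genes are binned (20 equal-count bins) on log mean
    expression and the log variance-to-mean ratio is z-scored within each
    bin; genes with normalized dispersion above ``disp_cutoff`` and mean in
    (``mean_low``, ``mean_high``) are returned.  ``method='sd'`` is the
    literal reading — standard deviation of log expression above the
    cutoff — exposed for reproduction purposes.
    """
    if nm.n_obs < 2:
        raise ValueError("need at least 2 cells to estimate dispersion")
    if method == "dispersion":
        tmp = nm.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(
                tmp,
                flavor="seurat",
                min_mean=mean_low,
                max_mean=mean_high,
                min_disp=disp_cutoff,
                n_bins=n_bins,
            )
        stat = tmp.var["dispersions_norm"]
        hv = tmp.var["highly_variable"]
    elif method == "sd":
        X = np.asarray(nm.X.todense()) if sp.issparse(nm.X) else np.asarray(nm.X)
        mean = X.mean(axis=0)
        stat = pd.Series(X.std(axis=0, ddof=1), index=nm.var_names)
        hv = pd.Series((stat > disp_cutoff) & (mean > mean_low) & (mean < mean_high), index=nm.var_names)
    else:
        raise ValueError(f"unknown variable-gene method {method!r}")
    selected = stat[hv].sort_values(ascending=False)
    if selected.empty:
        warnings.warn("no variable genes passed the cutoffs")
    return list(selected.index)


def regress_and_scale(
    nm: ad.AnnData,
    genes: list[str],
    covariates: tuple[str, ...] = ("total_counts", "mito_frac"),
    clip: float = 10.0,
) -> ad.AnnData:
    """Regress technical covariates out of each gene and standardize residuals.

    Per gene, ordinary least squares of log expression on an intercept plus
    the covariate columns of ``obs``; residuals are scaled to unit variance
    (ddof=1) and clipped to ``[-clip, clip]``.  Zero-variance covariates
    are dropped with a warning; zero-variance residual rows become all
    zeros.  Returns a dense cells x genes AnnData restricted to ``genes``.
    """
    missing = set(genes) - set(nm.var_names)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)[:5]} ...")
    sub = nm[:, genes]
    Y = np.asarray(sub.X.todense()) if sp.issparse(sub.X) else np.asarray(sub.X, dtype=float)

    cols = [np.ones(nm.n_obs)]
    for cov in covariates:
        v = nm.obs[cov].to_numpy(dtype=float)
        if np.std(v) == 0:
            warnings.warn(f"covariate {cov!r} has zero variance; dropped")
            continue
        cols.append(v)
    C = np.column_stack(cols)

    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    resid = Y - C @ beta
    sd = resid.std(axis=0, ddof=1)
    scaled = np.divide(resid, sd, out=np.zeros_like(resid), where=sd > 1e-12)
    np.clip(scaled, -clip, clip, out=scaled)

    out = ad.AnnData(
        X=scaled,
        obs=nm.obs.copy(),
        var=nm.var.loc[genes].copy(),
    )
    return out


@dataclass
class PCSpace:
    """Cells x PCs scores plus gene loadings and JackStraw significance."""

    scores: np.ndarray  # cells x n_pcs
    loadings: np.ndarray  # genes x n_pcs
    explained_variance_ratio: np.ndarray
    cell_names: pd.Index
    gene_names: pd.Index
    p_values: np.ndarray | None = None  # per PC
    selected_pcs: list[int] | None = None  # 0-based indices into columns

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]

    def selected_scores(self) -> np.ndarray:
        if self.selected_pcs is None:
            return self.scores
        return self.scores[:, self.selected_pcs]


def _svd_topk(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Top-k singular triplets of X (cells x genes) via the smaller Gram matrix.

    Returns (U, S, V, total_ss) with U cells x k, V genes x k and
    ``total_ss`` the total sum of squares (for explained-variance ratios).
    """
    n, p = X.shape
    if n <= p:
        G = X @ X.T
        w, U = np.linalg.eigh(G)
        order = np.argsort(w)[::-1][:k]
        w = np.clip(w[order], 0, None)
        U = U[:, order]
        S = np.sqrt(w)
        with np.errstate(divide="ignore", invalid="ignore"):
            V = np.where(S > 1e-12, (X.T @ U) / S, 0.0)
        total = float(np.trace(G))
    else:
        G = X.T @ X
        w, V = np.linalg.eigh(G)
        order = np.argsort(w)[::-1][:k]
        w = np.clip(w[order], 0, None)
        V = V[:, order]
        S = np.sqrt(w)
        with np.errstate(divide="ignore", invalid="ignore"):
            U = np.where(S > 1e-12, (X @ V) / S, 0.0)
        total = float(np.trace(G))
    return U, S, V, total


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sign convention: largest-magnitude loading per PC is positive
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    return U, V


def run_pca(sm: ad.AnnData, n_pcs: int = 20) -> PCSpace:
    """PCA of the scaled matrix: scores on the top right singular directions.

    The scaled matrix is already centered gene-wise, so scores are taken
    directly from the SVD of the cells x genes matrix.  Component signs are
    fixed so the largest-magnitude gene loading of each PC is positive.
    """
    X = np.asarray(sm.X, dtype=float)
    # gene rows are centered across cells, so one cell dimension is lost
    max_pcs = min(X.shape[0] - 1, X.shape[1])
    if n_pcs > max_pcs:
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n_cells - 1, n_genes) = {max_pcs}")
    U, S, V, total = _svd_topk(X, n_pcs)
    U, V = _fix_signs(U, V)
    scores = U * S
    evr = (S**2) / total if total > 0 else np.zeros_like(S)
    return PCSpace(
        scores=scores,
        loadings=V,
        explained_variance_ratio=evr,
        cell_names=sm.obs_names.copy(),
        gene_names=sm.var_names.copy(),
    )


def jackstraw(
    sm: ad.AnnData,
    pcs: PCSpace,
    n_reps: int = 100,
    prop: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
) -> PCSpace:
    """Permutation significance of principal components.

    In each replicate a random ``prop`` fraction of gene columns is
    permuted across cells, the PCA is recomputed, and the permuted genes'
    squared loadings are pooled into a per-PC null.  Each PC's p-value is
    a one-sided proportion test: the fraction of observed squared gene
    loadings exceeding the null's 95th percentile is compared against the
    5% expected under the null (upper-tail binomial).  This aggregation
    stays powerful when only a small subset of genes carries a component.
    PCs with p < ``alpha`` are selected.
    """
    if n_reps < 20:
        raise ValueError("n_reps must be at least 20")
    X = np.asarray(sm.X, dtype=float)
    n_cells, n_genes = X.shape
    n_perm = int(round(prop * n_genes))
    if prop * n_genes < 1:
        raise ValueError(f"prop*n_genes = {prop * n_genes:.3f} < 1: no genes to permute")

    rng = np.random.default_rng(seed)
    k = pcs.n_pcs
    null_sq: list[np.ndarray] = []
    Xp = X.copy()
    for _ in range(n_reps):
        idx = rng.choice(n_genes, size=n_perm, replace=False)
        saved = Xp[:, idx].copy()
        for j, g in enumerate(idx):
            Xp[:, g] = saved[rng.permutation(n_cells), j]
        _, _, Vp, _ = _svd_topk(Xp, k)
        null_sq.append(Vp[idx, :] ** 2)
        Xp[:, idx] = saved
    null = np.vstack(null_sq)  # (n_reps*n_perm) x k

    obs = pcs.loadings**2
    q = 0.95
    p_values = np.empty(k)
    for j in range(k):
        thresh = np.quantile(null[:, j], q)
        exceed = int((obs[:, j] > thresh).sum())
        p_values[j] = binomtest(exceed, n_genes, 1 - q, alternative="greater").pvalue
    selected = [int(j) for j in range(k) if p_values[j] < alpha]
    return replace(pcs, p_values=p_values, selected_pcs=selected)
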