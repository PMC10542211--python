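"""Shared fixtures: hand-built matrices and cached synthetic runs."""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from melliseq.evaluate import (
    run_analysis_core,
    score_cell_recovery,
    score_module_recovery,
)
from melliseq.simulate import CellType, SyntheticSpec, with_seed

N_RECOVERY_SEEDS = 20


def make_counts(X: np.ndarray, stages=None, mito=None, gene_ids=None) -> ad.AnnData:
    """Build a cells x genes count AnnData from a dense array."""
    X = np.asarray(X)
    n_cells, n_genes = X.shape
    gene_ids = list(gene_ids) if gene_ids is not None else [f"g{j + 1}" for j in range(n_genes)]
    stages = list(stages) if stages is not None else ["S1"] * n_cells
    mito = np.asarray(mito, dtype=bool) if mito is not None else np.zeros(n_genes, dtype=bool)
    obs = pd.DataFrame(
        {"stage": pd.Categorical(stages)},
        index=pd.Index([f"c{i + 1}" for i in range(n_cells)], name="barcode"),
    )
    var = pd.DataFrame(
        {"gene_name": gene_ids, "mito": mito}, index=pd.Index(gene_ids, name="gene_id")
    )
    return ad.AnnData(X=sp.csr_matrix(X.astype(np.int64)), obs=obs, var=var)


@pytest.fixture
def tiny_spec() -> SyntheticSpec:
    """A fast, QC-survivable spec: 4 types, 600 genes, ~240 cells.

    The baseline mean is raised so per-cell library sizes clear the
    700-UMI QC threshold despite the small gene count.
    """
    return SyntheticSpec(
        n_genes=600,
        cell_types=[
            CellType("A", 60, 0),
            CellType("B", 0, 60),
            CellType("C", 30, 30),
            CellType("D", 0, 60),
        ],
        n_markers_per_type=15,
        base_mean_log_mu=0.3,
        n_modules=2,
        module_size=20,
        n_background_programs=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def recovery_runs() -> list[dict]:
    """Default-spec end-to-end runs over many seeds, scored against truth.

    Session-cached: the cluster- and module-recovery checks share these.
    """
    out = []
    for seed in range(N_RECOVERY_SEEDS):
        res = run_analysis_core(with_seed(SyntheticSpec(), seed))
        out.append({**score_cell_recovery(res), **score_module_recovery(res)})
    return out
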