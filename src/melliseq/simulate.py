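"""Synthetic UMI-count generator with planted structure and full ground truth.

The generative model is a gamma-Poisson (negative binomial) count model

    count[c, g] ~ NB(mean = s_c * b_g * f_marker * f_module * f_program)

with a per-cell size factor ``s_c`` (log-normal), a per-gene baseline
``b_g`` (log-normal), and three layers of multiplicative structure:

* **markers** — each planted cell type has a disjoint set of marker genes
  whose mean is ``marker_fold`` times higher in cells of that type;
* **planted modules** — coexpressed gene sets to be recovered by the gene
  network analysis.  Each module is active in a random half of the cell
  types (mean ratio ``module_fold`` between active and inactive types) and
  carries an additional per-cell log-normal activity jitter, so module
  genes covary across cells as well as across cell-type aggregates.  The
  subset-of-types design keeps modules identifiable: a module whose
  activity peaks in a single type would be statistically indistinguishable
  from that type's marker set;
* **background programs** — every remaining (non-marker, non-module,
  non-mitochondrial) gene belongs to one of a small number of broad
  coexpression programs with log-normal per-type activity.  Real
  transcriptomes have essentially no "free" genes — organ-level programs
  span most of the genome — and without this layer background genes have
  no strong correlation partners of their own, so their chance
  correlations with planted modules (inevitable across a dozen pseudobulk
  columns) would dominate the coexpression graph.

Dropout (false zeros) arises naturally from low negative-binomial means;
no explicit zero-inflation term is used.  A fixed seed gives bit-identical
output (one numpy Generator stream with a fixed draw order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CellType",
    "SyntheticSpec",
    "GroundTruth",
    "default_cell_types",
    "generate_dataset",
    "generate_qc_outliers",
    "with_seed",
]

STAGE1 = "S1"
STAGE2 = "S2"


@dataclass(frozen=True)
class CellType:
    """A planted cell type and how many cells it has at each stage."""

    type_id: str
    n_cells_stage1: int
    n_cells_stage2: int


def default_cell_types() -> list[CellType]:
    """Desk-scale default: 10 types — 3 stage-1-only, 5 stage-2-only, 2 shared.

    ~400 cells per stage, mirroring the expanding cellular diversity of a
    metamorphosing pupa (more distinct types at the later stage).
    """
    types: list[CellType] = []
    for i in range(3):
        types.append(CellType(f"T{i + 1:02d}", 100, 0))
    for i in range(5):
        types.append(CellType(f"T{i + 4:02d}", 0, 60))
    for i in range(2):
        types.append(CellType(f"T{i + 9:02d}", 50, 50))
    return types


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic dataset.

    Defaults give two stage-labelled samples of ~400 cells each over 2,000
    genes with 10 planted cell types, 20 markers per type at 8-fold
    enrichment, 10 mitochondrial genes at a 5% expected UMI fraction,
    4 planted coexpression modules of 30 genes, and 8 broad background
    programs covering all remaining genes.
    """

    n_genes: int = 2000
    cell_types: Sequence[CellType] = field(default_factory=default_cell_types)
    n_markers_per_type: int = 20
    marker_fold: float = 8.0
    base_mean_log_mu: float = -0.5
    base_mean_log_sigma: float = 1.2
    dispersion: float = 0.5
    libsize_sigma: float = 0.35
    mito_genes: int = 10
    mito_mean_frac: float = 0.05
    n_modules: int = 4
    module_size: int = 30
    module_fold: float = 4.0
    module_active_frac: float = 0.5
    module_within_sigma: float = 0.5
    n_background_programs: int = 8
    background_program_sigma: float = 0.6
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted assignments emitted alongside the synthetic counts."""

    cell_type_of: dict[str, str]
    module_of: dict[str, int]
    marker_genes: dict[str, list[str]]
    program_of: dict[str, int] = field(default_factory=dict)
    qc_outlier: dict[str, str] = field(default_factory=dict)

    def cell_type_series(self) -> pd.Series:
        return pd.Series(self.cell_type_of, name="cell_type")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(cell table, gene table) for TSV export."""
        cells = pd.DataFrame(
            {
                "cell_type": pd.Series(self.cell_type_of),
                "qc_outlier": pd.Series(self.qc_outlier).reindex(self.cell_type_of.keys()).fillna(""),
            }
        )
        cells.index.name = "barcode"
        genes = pd.DataFrame(
            {
                "module": pd.Series(self.module_of, dtype="Int64"),
                "program": pd.Series(self.program_of, dtype="Int64"),
            }
        )
        genes.index.name = "gene_id"
        return cells, genes


def _validate(spec: SyntheticSpec) -> None:
    if len(spec.cell_types) == 0:
        raise ValueError("spec must define at least one cell type")
    need = (
        spec.mito_genes
        + len(spec.cell_types) * spec.n_markers_per_type
        + spec.n_modules * spec.module_size
    )
    if need > spec.n_genes:
        raise ValueError(
            f"mito + marker + module genes ({need}) exceed n_genes ({spec.n_genes})"
        )
    if spec.marker_fold <= 1:
        raise ValueError("marker_fold must exceed 1")
    if spec.module_fold <= 1:
        raise ValueError("module_fold must exceed 1")


def _gene_ids(spec: SyntheticSpec) -> list[str]:
    ids = [f"mt-G{i + 1:02d}" for i in range(spec.mito_genes)]
    ids += [f"GENE{i + 1:05d}" for i in range(spec.n_genes - spec.mito_genes)]
    return ids


def _layout(spec: SyntheticSpec, rng: np.random.Generator):
    """Baselines and planted gene roles; fixed draw order for determinism."""
    gene_ids = _gene_ids(spec)
    b = rng.lognormal(spec.base_mean_log_mu, spec.base_mean_log_sigma, spec.n_genes)

    mito_idx = np.arange(spec.mito_genes)
    is_mito = np.zeros(spec.n_genes, dtype=bool)
    is_mito[mito_idx] = True
    if spec.mito_genes and 0 < spec.mito_mean_frac < 1:
        target = spec.mito_mean_frac / (1 - spec.mito_mean_frac) * b[~is_mito].sum()
        b[mito_idx] *= target / b[mito_idx].sum()

    free = np.flatnonzero(~is_mito)
    perm = rng.permutation(free)
    cursor = 0
    marker_idx: dict[str, np.ndarray] = {}
    for ct in spec.cell_types:
        marker_idx[ct.type_id] = np.sort(perm[cursor : cursor + spec.n_markers_per_type])
        cursor += spec.n_markers_per_type
    module_idx: list[np.ndarray] = []
    for _ in range(spec.n_modules):
        module_idx.append(np.sort(perm[cursor : cursor + spec.module_size]))
        cursor += spec.module_size
    # every remaining non-mitochondrial gene joins a background program
    plain = np.sort(perm[cursor:])
    program_of = np.full(spec.n_genes, -1)
    if spec.n_background_programs > 0 and plain.size:
        program_of[plain] = rng.integers(0, spec.n_background_programs, plain.size)
    return gene_ids, b, is_mito, marker_idx, module_idx, program_of


def _activities(spec: SyntheticSpec, rng: np.random.Generator):
    """Per-(cell type, module/program) activity levels."""
    n_types = len(spec.cell_types)
    # module active in a random subset of types; mean ratio module_fold,
    # symmetric on the log scale so the global mean stays near baseline
    hi, lo = np.sqrt(spec.module_fold), 1.0 / np.sqrt(spec.module_fold)
    module_level = np.full((n_types, spec.n_modules), lo)
    n_active = max(1, int(round(spec.module_active_frac * n_types)))
    for m in range(spec.n_modules):
        act = rng.choice(n_types, size=n_active, replace=False)
        module_level[act, m] = hi
    ps = spec.background_program_sigma
    program_level = rng.lognormal(
        -ps * ps / 2, ps, size=(n_types, max(spec.n_background_programs, 1))
    )
    return module_level, program_level


def _make_anndata(
    counts: np.ndarray, barcodes: list[str], stage: str, gene_ids: list[str], is_mito: np.ndarray
) -> ad.AnnData:
    var = pd.DataFrame(
        {"gene_name": gene_ids, "mito": is_mito},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    obs = pd.DataFrame(
        {"stage": pd.Categorical([stage] * len(barcodes))},
        index=pd.Index(barcodes, name="barcode"),
    )
    return ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def generate_dataset(spec: SyntheticSpec) -> tuple[dict[str, ad.AnnData], GroundTruth]:
    """Generate per-stage count matrices and the planted ground truth.

    Returns a dict mapping stage label (``"S1"``, ``"S2"``) to an AnnData
    of UMI counts (cells x genes) and the :class:`GroundTruth`.  Stages
    with zero cells are omitted from the dict.
    """
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    gene_ids, b, is_mito, marker_idx, module_idx, program_of = _layout(spec, rng)
    module_level, program_level = _activities(spec, rng)
    sw = spec.module_within_sigma
    n_prog = spec.n_background_programs

    cell_type_of: dict[str, str] = {}
    module_map = {gene_ids[g]: m + 1 for m, idx in enumerate(module_idx) for g in idx}
    program_map = {
        gene_ids[g]: int(program_of[g]) + 1 for g in np.flatnonzero(program_of >= 0)
    }
    marker_genes = {t: [gene_ids[g] for g in idx] for t, idx in marker_idx.items()}
    program_genes = [np.flatnonzero(program_of == p) for p in range(n_prog)]

    stage_counts: dict[str, list[np.ndarray]] = {STAGE1: [], STAGE2: []}
    stage_barcodes: dict[str, list[str]] = {STAGE1: [], STAGE2: []}
    counter = {STAGE1: 0, STAGE2: 0}

    for ti, ct in enumerate(spec.cell_types):
        for stage, n_cells in ((STAGE1, ct.n_cells_stage1), (STAGE2, ct.n_cells_stage2)):
            if n_cells == 0:
                continue
            s = rng.lognormal(-spec.libsize_sigma**2 / 2, spec.libsize_sigma, n_cells)
            mean = s[:, None] * b[None, :]
            mean[:, marker_idx[ct.type_id]] *= spec.marker_fold
            if spec.n_modules:
                jitter = rng.lognormal(-sw * sw / 2, sw, size=(n_cells, spec.n_modules))
                act = module_level[ti][None, :] * jitter
                for m, idx in enumerate(module_idx):
                    mean[:, idx] *= act[:, m][:, None]
            if n_prog:
                pjitter = rng.lognormal(-sw * sw / 2, sw, size=(n_cells, n_prog))
                pact = program_level[ti, :n_prog][None, :] * pjitter
                for p, idx in enumerate(program_genes):
                    if idx.size:
                        mean[:, idx] *= pact[:, p][:, None]
            counts = _nb_counts(mean, spec.dispersion, rng)
            barcodes = [f"{stage}_C{counter[stage] + i + 1:05d}" for i in range(n_cells)]
            counter[stage] += n_cells
            stage_counts[stage].append(counts)
            stage_barcodes[stage].extend(barcodes)
            for bc in barcodes:
                cell_type_of[bc] = ct.type_id

    out: dict[str, ad.AnnData] = {}
    for stage in (STAGE1, STAGE2):
        if not stage_counts[stage]:
            continue
        counts = np.vstack(stage_counts[stage])
        out[stage] = _make_anndata(counts, stage_barcodes[stage], stage, gene_ids, is_mito)

    return out, GroundTruth(cell_type_of, module_map, marker_genes, program_map)


def generate_qc_outliers(
    spec: SyntheticSpec,
    n_low_umi: int = 0,
    n_high_mito: int = 0,
    max_umi_low: int = 700,
    mito_frac_high: float = 0.30,
) -> tuple[dict[str, ad.AnnData], GroundTruth]:
    """Generate a dataset plus engineered QC-failing cells.

    Appends to the first stage ``n_low_umi`` cells whose total UMI count is
    at most ``max_umi_low`` (but normal mitochondrial content) and
    ``n_high_mito`` cells with a mitochondrial UMI fraction around
    ``mito_frac_high`` (but a normal library size), each violating exactly
    one QC rule.  Outliers are flagged in ``GroundTruth.qc_outlier``; with
    both counts zero the dataset is returned unchanged.
    """
    data, gt = generate_dataset(spec)
    if n_low_umi == 0 and n_high_mito == 0:
        return data, gt
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 9151]))
    layout_rng = np.random.default_rng(spec.seed)
    gene_ids, b, is_mito, *_ = _layout(spec, layout_rng)

    stage = next(iter(data))
    adata = data[stage]
    p_base = b / b.sum()

    extra_rows: list[np.ndarray] = []
    extra_bc: list[str] = []

    for i in range(n_low_umi):
        total = int(rng.integers(200, max_umi_low + 1))
        for _ in range(100):
            row = rng.multinomial(total, p_base)
            if row[is_mito].sum() / max(total, 1) < 0.10:
                break
        bc = f"{stage}_LOWUMI{i + 1:03d}"
        extra_rows.append(row)
        extra_bc.append(bc)
        gt.qc_outlier[bc] = "low_umi"
        gt.cell_type_of[bc] = "qc_outlier"

    p_mito = p_base.copy()
    if is_mito.any():
        p_mito[is_mito] *= mito_frac_high / p_mito[is_mito].sum()
        p_mito[~is_mito] *= (1 - mito_frac_high) / p_mito[~is_mito].sum()
    for i in range(n_high_mito):
        total = int(rng.integers(1500, 3000))
        for _ in range(100):
            row = rng.multinomial(total, p_mito)
            if row[is_mito].sum() / total >= 0.10:
                break
        bc = f"{stage}_HIMITO{i + 1:03d}"
        extra_rows.append(row)
        extra_bc.append(bc)
        gt.qc_outlier[bc] = "high_mito"
        gt.cell_type_of[bc] = "qc_outlier"

    extra = _make_anndata(np.vstack(extra_rows), extra_bc, stage, gene_ids, is_mito)
    merged = ad.concat([adata, extra], join="outer", merge="first", index_unique=None)
    merged.var = adata.var
    merged.X = sp.csr_matrix(merged.X)
    data[stage] = merged
    return data, gt


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    """Copy of ``spec`` with a different seed."""
    return replace(spec, seed=seed)
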