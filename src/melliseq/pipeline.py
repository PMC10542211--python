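"""Pipeline orchestration: config schema, staged execution, run manifest.

``run_pipeline`` executes the full workflow — QC, normalization, variable
genes, scaling, PCA, JackStraw, cell graph, MCL, small-cluster merging,
pseudobulk, gene coexpression network, Louvain, markers, enrichment — from
a validated config, writing every intermediate artifact plus a
machine-readable manifest of per-stage counts into a run directory.
Identical config and seed give byte-identical manifests and tables.  Each
stage reads only on-disk artifacts of earlier stages, so a run can be
resumed from any intermediate.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import cellnet, gcn, io, markers, preprocess, pseudobulk, simulate

__all__ = ["PipelineConfig", "PipelineError", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("melliseq")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BundleConfig(_Strict):
    matrix: Path
    features: Path
    barcodes: Path
    stage: str


class SyntheticConfig(_Strict):
    n_genes: int = Field(2000, gt=0)
    cell_types: Optional[list[tuple[str, int, int]]] = None
    n_markers_per_type: int = Field(20, ge=0)
    marker_fold: float = Field(8.0, gt=1)
    base_mean_log_mu: float = -0.5
    base_mean_log_sigma: float = Field(1.2, gt=0)
    dispersion: float = Field(0.5, ge=0)
    libsize_sigma: float = Field(0.35, ge=0)
    mito_genes: int = Field(10, ge=0)
    mito_mean_frac: float = Field(0.05, ge=0, lt=1)
    n_modules: int = Field(4, ge=0)
    module_size: int = Field(30, gt=0)
    module_fold: float = Field(4.0, gt=1)
    module_active_frac: float = Field(0.5, gt=0, le=1)
    module_within_sigma: float = Field(0.5, ge=0)
    n_background_programs: int = Field(8, ge=0)
    background_program_sigma: float = Field(0.6, ge=0)
    n_low_umi_outliers: int = Field(0, ge=0)
    n_high_mito_outliers: int = Field(0, ge=0)

    def to_spec(self, seed: int) -> simulate.SyntheticSpec:
        cts = (
            [simulate.CellType(*t) for t in self.cell_types]
            if self.cell_types is not None
            else simulate.default_cell_types()
        )
        return simulate.SyntheticSpec(
            n_genes=self.n_genes,
            cell_types=cts,
            n_markers_per_type=self.n_markers_per_type,
            marker_fold=self.marker_fold,
            base_mean_log_mu=self.base_mean_log_mu,
            base_mean_log_sigma=self.base_mean_log_sigma,
            dispersion=self.dispersion,
            libsize_sigma=self.libsize_sigma,
            mito_genes=self.mito_genes,
            mito_mean_frac=self.mito_mean_frac,
            n_modules=self.n_modules,
            module_size=self.module_size,
            module_fold=self.module_fold,
            module_active_frac=self.module_active_frac,
            module_within_sigma=self.module_within_sigma,
            n_background_programs=self.n_background_programs,
            background_program_sigma=self.background_program_sigma,
            seed=seed,
        )


class InputConfig(_Strict):
    bundles: Optional[list[BundleConfig]] = None
    synthetic: Optional[SyntheticConfig] = None
    mito_pattern: Optional[str] = "^mt-"
    mito_gene_ids: Optional[list[str]] = None


class QCConfig(_Strict):
    min_umi: int = Field(700, gt=0)
    max_mito: float = Field(0.10, gt=0, le=1)
    min_cells_per_gene: int = Field(4, ge=1)


class NormConfig(_Strict):
    scale_factor: float = Field(10000.0, gt=0)


class HVGConfig(_Strict):
    mean_low: float = Field(0.0125, ge=0)
    mean_high: float = Field(3.0, gt=0)
    disp_cutoff: float = 0.5
    method: Literal["dispersion", "sd"] = "dispersion"


class PCAConfig(_Strict):
    n_pcs: int = Field(20, gt=0)


class JackStrawConfig(_Strict):
    enabled: bool = True
    n_reps: int = Field(100, ge=20)
    prop: float = Field(0.01, gt=0, le=1)
    alpha: float = Field(0.05, ge=0, le=1)


class CellNetConfig(_Strict):
    k: int = Field(20, ge=1)
    r_min: float = Field(0.77, gt=0, le=1)
    min_degree: int = Field(3, ge=0)


class MCLConfig(_Strict):
    inflation: float = Field(1.6, gt=1)
    expansion: int = Field(2, ge=2)
    tol: float = Field(1e-6, gt=0)
    prune: float = Field(1e-5, ge=0)
    max_iter: int = Field(200, ge=1)


class MergeConfig(_Strict):
    min_size: int = Field(10, ge=1)


class PseudobulkConfig(_Strict):
    min_cells: int = Field(3, ge=0)
    min_max: float = Field(0.5, ge=0)
    min_frac: float = Field(0.05, ge=0, le=1)
    percentile: float = Field(95.0, gt=0, le=100)
    per_stage_filters: bool = False


class GCNConfig(_Strict):
    min_max: float = Field(0.2, ge=0)
    k: int = Field(4, ge=1)
    r_min: float = Field(0.7, gt=0, le=1)
    resolution: float = Field(0.65, gt=0)


class MarkerConfig(_Strict):
    enabled: bool = True
    min_pct: float = Field(0.1, ge=0, le=1)
    logfc_min: float = Field(0.25, ge=0)
    groups: Literal["cluster", "cluster_stage"] = "cluster"


class EnrichConfig(_Strict):
    gene_sets: Optional[Path] = None  # GMT file
    homolog_map: Optional[Path] = None  # 2-column TSV: bee gene -> external gene


class PipelineConfig(_Strict):
    seed: int = 0
    input: InputConfig = Field(default_factory=lambda: InputConfig(synthetic=SyntheticConfig()))
    qc: QCConfig = Field(default_factory=QCConfig)
    norm: NormConfig = Field(default_factory=NormConfig)
    hvg: HVGConfig = Field(default_factory=HVGConfig)
    pca: PCAConfig = Field(default_factory=PCAConfig)
    jackstraw: JackStrawConfig = Field(default_factory=JackStrawConfig)
    cellnet: CellNetConfig = Field(default_factory=CellNetConfig)
    mcl: MCLConfig = Field(default_factory=MCLConfig)
    merge: MergeConfig = Field(default_factory=MergeConfig)
    pseudobulk: PseudobulkConfig = Field(default_factory=PseudobulkConfig)
    gcn: GCNConfig = Field(default_factory=GCNConfig)
    markers: MarkerConfig = Field(default_factory=MarkerConfig)
    enrich: EnrichConfig = Field(default_factory=EnrichConfig)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fanned out from the global seed."""
        offsets = {"synthetic": 0, "jackstraw": 1, "louvain": 2}
        state = np.random.SeedSequence([self.seed, offsets[stage]]).generate_state(1)[0]
        return int(state % (2**31))


def load_config(path: Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update(overrides)
    return PipelineConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# stages — each reads artifacts of earlier stages from the run directory


def _write_fragment(outdir: Path, stage: str, fragment: dict) -> None:
    frag_dir = outdir / "manifest"
    frag_dir.mkdir(parents=True, exist_ok=True)
    with open(frag_dir / f"{stage}.json", "w") as fh:
        json.dump(fragment, fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    """Generate synthetic bundles + ground truth into the run directory."""
    if cfg.input.synthetic is None:
        raise PipelineError("simulate: config has no synthetic input section")
    spec = cfg.input.synthetic.to_spec(cfg.child_seed("synthetic"))
    sc_cfg = cfg.input.synthetic
    if sc_cfg.n_low_umi_outliers or sc_cfg.n_high_mito_outliers:
        data, gt = simulate.generate_qc_outliers(
            spec, sc_cfg.n_low_umi_outliers, sc_cfg.n_high_mito_outliers
        )
    else:
        data, gt = simulate.generate_dataset(spec)
    for stage_label, adata in data.items():
        io.write_count_bundle(adata, outdir / "bundles" / stage_label, stage_label)
    cells, genes = gt.to_frames()
    cells.to_csv(outdir / "truth_cells.tsv", sep="\t")
    genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
    _write_fragment(
        outdir,
        "simulate",
        {
            "stages": {s: int(a.n_obs) for s, a in data.items()},
            "n_genes": int(next(iter(data.values())).n_vars),
            "n_modules": spec.n_modules,
            "n_cell_types": len(spec.cell_types),
        },
    )


def _load_bundles(cfg: PipelineConfig, outdir: Path) -> list[ad.AnnData]:
    if cfg.input.bundles:
        bundles = [
            io.CountBundle(b.matrix, b.features, b.barcodes, b.stage) for b in cfg.input.bundles
        ]
    else:
        bdir = outdir / "bundles"
        if not bdir.exists():
            raise PipelineError("qc: no input bundles configured and none found in run directory")
        bundles = [
            io.CountBundle(d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv", d.name)
            for d in sorted(bdir.iterdir())
            if d.is_dir()
        ]
    return [
        io.read_count_bundle(b, cfg.input.mito_pattern, cfg.input.mito_gene_ids) for b in bundles
    ]


def stage_qc(cfg: PipelineConfig, outdir: Path) -> None:
    """Merge stages, filter cells and genes, log-normalize; write normalized matrix."""
    mats = _load_bundles(cfg, outdir)
    raw_counts = {str(m.obs["stage"].iloc[0]): int(m.n_obs) for m in mats}
    merged = io.merge_stages(mats)
    filtered = preprocess.filter_cells(merged, cfg.qc.min_umi, cfg.qc.max_mito)
    qc_cells = filtered.uns["qc_cells"]
    filtered = preprocess.filter_genes(filtered, cfg.qc.min_cells_per_gene)
    qc_genes = filtered.uns["qc_genes"]
    if filtered.n_obs == 0:
        raise PipelineError("cell-graph: no cells remain after QC filtering")
    nm = preprocess.log_normalize(filtered, cfg.norm.scale_factor)
    nm.write_h5ad(outdir / "normalized.h5ad")
    _write_fragment(
        outdir,
        "qc",
        {
            "cells_raw_per_stage": raw_counts,
            "cell_filter": qc_cells.to_dict(orient="records"),
            "gene_filter": qc_genes,
        },
    )


def stage_cluster_cells(cfg: PipelineConfig, outdir: Path) -> None:
    """HVG -> scale -> PCA (-> JackStraw) -> cell graph -> MCL -> merge."""
    nm = ad.read_h5ad(outdir / "normalized.h5ad")
    hvg = preprocess.find_variable_genes(
        nm, cfg.hvg.mean_low, cfg.hvg.mean_high, cfg.hvg.disp_cutoff, cfg.hvg.method
    )
    if len(hvg) < 2:
        raise PipelineError("cluster-cells: fewer than 2 variable genes")
    scaled = preprocess.regress_and_scale(nm, hvg)
    n_pcs = min(cfg.pca.n_pcs, min(scaled.shape) - 1)
    pcs = preprocess.run_pca(scaled, n_pcs)
    if cfg.jackstraw.enabled:
        pcs = preprocess.jackstraw(
            scaled,
            pcs,
            cfg.jackstraw.n_reps,
            cfg.jackstraw.prop,
            cfg.jackstraw.alpha,
            seed=cfg.child_seed("jackstraw"),
        )
        if not pcs.selected_pcs:
            raise PipelineError("cluster-cells: JackStraw selected no significant PCs")
        pd.DataFrame(
            {"pc": np.arange(1, pcs.n_pcs + 1), "p_value": pcs.p_values,
             "selected": [int(j in pcs.selected_pcs) for j in range(pcs.n_pcs)]}
        ).to_csv(outdir / "pc_significance.tsv", sep="\t", index=False)
    sim = cellnet.pairwise_pearson(pcs.selected_scores())
    graph = cellnet.build_knn_graph(sim, list(pcs.cell_names), cfg.cellnet.k, cfg.cellnet.r_min)
    graph = cellnet.prune_low_degree(graph, cfg.cellnet.min_degree)
    if graph.vcount() == 0:
        raise PipelineError("cluster-cells: no cells remain after degree pruning")
    io.write_graph(graph, outdir / "cell_graph.tsv")
    clusters = cellnet.mcl_cluster(
        graph,
        inflation=cfg.mcl.inflation,
        expansion=cfg.mcl.expansion,
        max_iter=cfg.mcl.max_iter,
        tol=cfg.mcl.tol,
        prune=cfg.mcl.prune,
    )
    n_mcl = int(clusters.nunique())
    merged_clusters = cellnet.merge_small_clusters(clusters, graph, cfg.merge.min_size)
    stage_of = nm.obs["stage"].astype(str)
    table = pd.DataFrame(
        {"stage": stage_of.reindex(merged_clusters.index), "cluster_id": merged_clusters}
    )
    io.write_cluster_table(table, outdir / "cell_clusters.tsv")
    _write_fragment(
        outdir,
        "cluster_cells",
        {
            "n_variable_genes": len(hvg),
            "n_pcs_computed": int(pcs.n_pcs),
            "n_pcs_used": len(pcs.selected_pcs) if pcs.selected_pcs is not None else int(pcs.n_pcs),
            "graph_nodes": int(graph.vcount()),
            "graph_edges": int(graph.ecount()),
            "cells_pruned_low_degree": int(nm.n_obs - graph.vcount()),
            "n_clusters_mcl": n_mcl,
            "n_clusters_merged": int(merged_clusters.nunique()),
        },
    )


def stage_pseudobulk(cfg: PipelineConfig, outdir: Path) -> None:
    nm = ad.read_h5ad(outdir / "normalized.h5ad")
    table = io.read_cluster_table(outdir / "cell_clusters.tsv")
    pb = pseudobulk.aggregate_by_cluster_stage(
        nm,
        table["cluster_id"],
        min_cells=cfg.pseudobulk.min_cells,
        min_max=cfg.pseudobulk.min_max,
        min_frac=cfg.pseudobulk.min_frac,
        percentile=cfg.pseudobulk.percentile,
        per_stage_filters=cfg.pseudobulk.per_stage_filters,
    )
    pb.to_tsv(outdir / "pseudobulk.tsv")
    n_clusters = int(table["cluster_id"].nunique())
    _write_fragment(
        outdir,
        "pseudobulk",
        {
            "n_clusters": n_clusters,
            "n_stage_clusters": int(pb.n_columns),
            "n_mixed_stage_clusters": int(pb.n_columns - n_clusters),
        },
    )


def stage_gcn(cfg: PipelineConfig, outdir: Path) -> None:
    pb = pseudobulk.PseudobulkMatrix.from_tsv(outdir / "pseudobulk.tsv")
    pb = gcn.filter_low_expression_genes(pb, cfg.gcn.min_max)
    graph = gcn.build_gene_knn_graph(pb, cfg.gcn.k, cfg.gcn.r_min)
    io.write_graph(graph, outdir / "gene_graph.tsv")
    clustering = gcn.louvain_cluster(graph, cfg.gcn.resolution, seed=cfg.child_seed("louvain"))
    clustering.to_tsv(outdir / "gene_clusters.tsv")
    # mean profile per gene cluster (heatmap-ready)
    prof = pb.values.groupby(clustering.assignment).mean()
    prof.index.name = "gene_cluster"
    prof.to_csv(outdir / "gene_cluster_profiles.tsv", sep="\t")
    _write_fragment(
        outdir,
        "gcn",
        {
            "n_genes_networked": int(graph.vcount()),
            "n_edges": int(graph.ecount()),
            "n_gene_clusters": int(clustering.n_clusters),
            "modularity": round(float(clustering.modularity), 10),
            "resolution": cfg.gcn.resolution,
        },
    )


def stage_markers(cfg: PipelineConfig, outdir: Path) -> None:
    if not cfg.markers.enabled:
        return
    nm = ad.read_h5ad(outdir / "normalized.h5ad")
    table = io.read_cluster_table(outdir / "cell_clusters.tsv")
    result = markers.wilcoxon_markers(
        nm, table["cluster_id"], cfg.markers.min_pct, cfg.markers.logfc_min, cfg.markers.groups
    )
    result.to_csv(outdir / "markers.tsv", sep="\t", index=False, float_format="%.8g")
    _write_fragment(outdir, "markers", {"n_marker_records": int(len(result))})


def stage_enrich(cfg: PipelineConfig, outdir: Path) -> None:
    if cfg.enrich.gene_sets is None:
        return
    sets = markers.read_gmt(cfg.enrich.gene_sets)
    assignment = pd.read_csv(outdir / "gene_clusters.tsv", sep="\t", index_col="gene_id")[
        "gene_cluster"
    ]
    universe = set(assignment.index)
    if cfg.enrich.homolog_map is not None:
        mapping = pd.read_csv(cfg.enrich.homolog_map, sep="\t", header=None, dtype=str)
        universe = markers.apply_homolog_map(universe, mapping)
    rows = []
    for gc in sorted(assignment.unique()):
        query = set(assignment.index[assignment == gc])
        if cfg.enrich.homolog_map is not None:
            query = markers.apply_homolog_map(query, mapping)
        res = markers.ora_enrichment(query, sets, universe)
        res.insert(0, "gene_cluster", gc)
        rows.append(res)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    out.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.8g")
    _write_fragment(outdir, "enrich", {"n_tests": int(len(out))})


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "cluster-cells": stage_cluster_cells,
    "pseudobulk": stage_pseudobulk,
    "gcn": stage_gcn,
    "markers": stage_markers,
    "enrich": stage_enrich,
}


def run_stage(name: str, cfg: PipelineConfig, outdir: Path) -> None:
    log.info("stage %s: starting", name)
    try:
        STAGES[name](cfg, outdir)
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the stage name
        raise PipelineError(f"{name}: {exc}") from exc
    log.info("stage %s: done", name)


def run_pipeline(cfg: PipelineConfig, outdir: Path) -> Path:
    """Execute all stages in order and assemble the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(json.loads(cfg.model_dump_json()), fh, sort_keys=True)
        names = list(STAGES)
        if cfg.input.bundles:
            names.remove("simulate")
        for name in names:
            run_stage(name, cfg, outdir)
        manifest: dict = {"seed": cfg.seed}
        for frag in sorted((outdir / "manifest").glob("*.json")):
            with open(frag) as fh:
                manifest[frag.stem] = json.load(fh)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
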