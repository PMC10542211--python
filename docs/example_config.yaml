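# Full parameter reference with the default thresholds.
# Override any subset; unknown keys are rejected.
seed: 1
input:
  # either point at real 10x-style bundles ...
  # bundles:
  #   - {matrix: data/S1/matrix.mtx, features: data/S1/features.tsv,
  #      barcodes: data/S1/barcodes.tsv, stage: S1}
  # ... or generate synthetic data with planted ground truth:
  synthetic:
    n_genes: 2000
    n_markers_per_type: 20
    marker_fold: 8.0
    mito_genes: 10
    mito_mean_frac: 0.05
    n_modules: 4
    module_size: 30
  mito_pattern: "^mt-"
qc: {min_umi: 700, max_mito: 0.10, min_cells_per_gene: 4}
norm: {scale_factor: 10000}
hvg: {mean_low: 0.0125, mean_high: 3.0, disp_cutoff: 0.5, method: dispersion}
pca: {n_pcs: 20}
jackstraw: {enabled: true, n_reps: 100, prop: 0.01, alpha: 0.05}
cellnet: {k: 20, r_min: 0.77, min_degree: 3}
mcl: {inflation: 1.6, expansion: 2, tol: 1.0e-6, prune: 1.0e-5, max_iter: 200}
merge: {min_size: 10}
pseudobulk: {min_cells: 3, min_max: 0.5, min_frac: 0.05, percentile: 95, per_stage_filters: false}
gcn: {min_max: 0.2, k: 4, r_min: 0.7, resolution: 0.65}
markers: {enabled: true, min_pct: 0.1, logfc_min: 0.25, groups: cluster}
enrich: {gene_sets: null, homolog_map: null}
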