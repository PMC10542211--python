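"""QC boundaries, normalization formula, dispersion statistic, OLS scaling, PCA, JackStraw."""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from melliseq import preprocess
from melliseq.simulate import CellType, SyntheticSpec, generate_dataset
from tests.conftest import make_counts


class TestFilterCells:
    def qc_matrix(self):
        # 3 genes, last is mitochondrial; rows are crafted per cell
        X = np.array(
            [
                [700, 0, 0],  # total exactly 700 -> removed
                [631, 0, 70],  # total 701, mito 70/701 ~ 0.0999 -> kept
                [900, 0, 100],  # mito exactly 10% -> removed
                [5000, 3000, 100],  # healthy
            ]
        )
        return make_counts(X, mito=[False, False, True])

    def test_boundary_cells_removed_and_interior_kept(self):
        out = preprocess.filter_cells(self.qc_matrix())
        assert list(out.obs_names) == ["c2", "c4"]

    def test_removal_counts_reported_per_rule(self):
        out = preprocess.filter_cells(self.qc_matrix())
        rep = out.uns["qc_cells"].iloc[0]
        assert rep["removed_low_umi"] == 1
        assert rep["removed_high_mito"] == 1
        assert rep["n_cells_raw"] == rep["n_cells_kept"] + rep["n_cells_removed"]

    def test_empty_result_allowed_with_warning(self):
        with pytest.warns(UserWarning, match="all cells removed"):
            out = preprocess.filter_cells(self.qc_matrix(), min_umi=10**9)
        assert out.n_obs == 0


class TestFilterGenes:
    def test_detection_count_boundary(self):
        # gene detected in 3 cells -> removed; in 4 cells -> kept; all-zero -> removed
        X = np.array(
            [
                [1, 1, 0],
                [1, 1, 0],
                [1, 1, 0],
                [0, 1, 0],
            ]
        )
        out = preprocess.filter_genes(make_counts(X))
        assert list(out.var_names) == ["g2"]
        assert out.uns["qc_genes"]["removed_low_detection"] == 2


class TestLogNormalize:
    def test_formula_on_known_counts(self):
        X = np.zeros((1, 3))
        X[0] = [1, 9999, 0]
        nm = preprocess.log_normalize(make_counts(X))
        # count 1 in a cell of total 10,000 at scale 10,000 -> ln(2)
        assert nm.X[0, 0] == pytest.approx(np.log(2), abs=1e-12)
        assert nm.X[0, 2] == 0.0

    def test_scale_invariance_within_cell(self):
        X = np.array([[2, 5, 13]])
        a = preprocess.log_normalize(make_counts(X)).X
        b = preprocess.log_normalize(make_counts(2 * X)).X
        np.testing.assert_allclose(a.toarray(), b.toarray(), atol=1e-12)

    def test_monotone_in_counts_within_cell(self):
        X = np.array([[0, 1, 2, 5, 50]])
        vals = np.asarray(preprocess.log_normalize(make_counts(X)).X).ravel()
        assert (np.diff(vals) > 0).all()

    def test_zero_total_cell_is_an_error(self):
        with pytest.raises(ValueError, match="zero total"):
            preprocess.log_normalize(make_counts(np.zeros((1, 3))))


def brute_force_binned_dispersion(nm: ad.AnnData, n_bins=20):
    """Independent reimplementation of the binned dispersion statistic:
    mean/dispersion on de-logged values, log-transformed, z-scored within
    equal-width bins of mean."""
    X = np.asarray(nm.X.todense()) if hasattr(nm.X, "todense") else np.asarray(nm.X)
    E = np.expm1(X)
    mean = E.mean(axis=0)
    var = E.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    disp[disp == 0] = np.nan
    log_disp = np.log(disp)
    log_mean = np.log1p(mean)
    df = pd.DataFrame({"m": log_mean, "d": log_disp})
    df["bin"] = pd.cut(df["m"], bins=n_bins)
    grouped = df.groupby("bin", observed=True)["d"]
    bmean = grouped.transform("mean")
    bstd = grouped.transform(lambda s: s.std(ddof=1))
    # a bin holding a single gene has no spread: by convention that gene's
    # z-score is taken against mean 0 and std equal to its own dispersion
    single = grouped.transform("count") == 1
    z = (df["d"] - np.where(single, 0.0, bmean)) / np.where(single, df["d"], bstd)
    return log_mean, z.to_numpy()


class TestFindVariableGenes:
    def setup_method(self):
        spec = SyntheticSpec(
            n_genes=600, cell_types=[CellType("A", 150, 150)], seed=9, base_mean_log_mu=0.3
        )
        data, _ = generate_dataset(spec)
        from melliseq.io import merge_stages

        merged = merge_stages(list(data.values()))
        self.nm = preprocess.log_normalize(preprocess.filter_genes(merged))

    def test_low_mean_gene_excluded_regardless_of_dispersion(self):
        X = np.asarray(self.nm.X.todense())
        mean = np.log1p(np.expm1(X).mean(axis=0))
        hv = preprocess.find_variable_genes(self.nm)
        low = set(self.nm.var_names[mean <= 0.0125])
        assert not (set(hv) & low)

    def test_constant_gene_excluded(self):
        X = np.asarray(self.nm.X.todense())
        X[:, 0] = 1.0  # constant, mean in range
        nm = ad.AnnData(X=X, obs=self.nm.obs.copy(), var=self.nm.var.copy())
        hv = preprocess.find_variable_genes(nm)
        assert nm.var_names[0] not in hv

    def test_membership_matches_brute_force_recomputation(self):
        hv = set(preprocess.find_variable_genes(self.nm))
        log_mean, z = brute_force_binned_dispersion(self.nm)
        expected = {
            g
            for g, m, zz in zip(self.nm.var_names, log_mean, z)
            if 0.0125 < m < 3 and zz > 0.5
        }
        assert hv == expected

    def test_sd_mode_uses_plain_standard_deviation(self):
        hv = set(preprocess.find_variable_genes(self.nm, method="sd"))
        X = np.asarray(self.nm.X.todense())
        sd = X.std(axis=0, ddof=1)
        mean = X.mean(axis=0)
        expected = {
            g for g, s, m in zip(self.nm.var_names, sd, mean) if s > 0.5 and 0.0125 < m < 3
        }
        assert hv == expected


class TestRegressAndScale:
    def make_nm(self, Y, covs):
        nm = make_counts(np.ones_like(Y))
        nm = preprocess.log_normalize(nm)
        nm.X = np.asarray(Y, dtype=float)
        for k, v in covs.items():
            nm.obs[k] = v
        return nm

    def test_uncorrelated_gene_row_standardized(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(50, 3))
        covs = {"total_counts": rng.normal(size=50), "mito_frac": rng.normal(size=50)}
        sm = preprocess.regress_and_scale(self.make_nm(Y, covs), ["g1", "g2", "g3"])
        assert np.allclose(np.asarray(sm.X).mean(axis=0), 0, atol=1e-8)
        assert np.allclose(np.asarray(sm.X).std(axis=0, ddof=1), 1, atol=1e-8)

    def test_gene_equal_to_covariate_becomes_all_zero(self):
        lib = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        Y = np.column_stack([3 * lib + 1, np.array([1.0, 0, 2, 0, 1])])
        covs = {"total_counts": lib, "mito_frac": np.zeros(5) + 0.01}
        with pytest.warns(UserWarning, match="zero variance"):
            sm = preprocess.regress_and_scale(self.make_nm(Y, covs), ["g1", "g2"])
        assert np.allclose(np.asarray(sm.X)[:, 0], 0)

    def test_residuals_match_normal_equation_oracle(self):
        # hand-built 5-cell example checked against the closed-form solution
        lib = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mito = np.array([0.01, 0.05, 0.02, 0.08, 0.03])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        C = np.column_stack([np.ones(5), lib, mito])
        beta = np.linalg.inv(C.T @ C) @ C.T @ y
        resid = y - C @ beta
        expected = np.clip(resid / resid.std(ddof=1), -10, 10)
        sm = preprocess.regress_and_scale(
            self.make_nm(y[:, None], {"total_counts": lib, "mito_frac": mito}), ["g1"]
        )
        np.testing.assert_allclose(np.asarray(sm.X).ravel(), expected, atol=1e-10)


def scaled_from(X):
    nm = make_counts(np.ones(X.shape))
    sm = ad.AnnData(X=np.asarray(X, dtype=float), obs=nm.obs, var=nm.var)
    return sm


class TestRunPCA:
    def test_single_direction_dominates(self):
        t = np.linspace(-1, 1, 30)
        X = np.column_stack([t, 1e-8 * np.sin(7 * t), np.zeros(30)])
        pcs = preprocess.run_pca(scaled_from(X), 2)
        assert pcs.explained_variance_ratio[0] > 0.999

    def test_analytic_two_gene_eigenvalues(self):
        # second-moment matrix [[2,1],[1,2]] has eigenvalues 3 and 1
        a, b = np.sqrt(3.0), 1.0
        X = np.array([[a, a], [-a, -a], [b, -b], [-b, b]]) / np.sqrt(2)
        pcs = preprocess.run_pca(scaled_from(X), 2)
        np.testing.assert_allclose(pcs.explained_variance_ratio, [0.75, 0.25], atol=1e-12)

    def test_scores_equivariant_to_cell_permutation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        perm = rng.permutation(20)
        pcs = preprocess.run_pca(scaled_from(X), 3)
        pcs_p = preprocess.run_pca(scaled_from(X[perm]), 3)
        np.testing.assert_allclose(pcs_p.scores, pcs.scores[perm], atol=1e-8)

    def test_reconstruction_error_nonincreasing_in_n_pcs(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 10))
        errs = []
        for k in range(1, 9):
            pcs = preprocess.run_pca(scaled_from(X), k)
            recon = pcs.scores @ pcs.loadings.T
            errs.append(np.linalg.norm(X - recon))
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errs, errs[1:]))

    def test_too_many_pcs_rejected(self):
        with pytest.raises(ValueError, match="n_pcs"):
            preprocess.run_pca(scaled_from(np.zeros((4, 3))), 4)


class TestJackStraw:
    def planted(self, seed=0, n_cells=150, n_genes=100):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n_cells, n_genes))
        factor = rng.normal(size=n_cells)
        X[:, :20] += 2.0 * factor[:, None]  # one strong planted factor
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        return scaled_from(X)

    def test_planted_factor_pc_is_selected(self):
        sm = self.planted()
        pcs = preprocess.run_pca(sm, 10)
        js = preprocess.jackstraw(sm, pcs, n_reps=50, prop=0.05, seed=1)
        assert 0 in js.selected_pcs
        assert js.p_values[0] == js.p_values.min()

    def test_alpha_zero_selects_nothing(self):
        sm = self.planted()
        pcs = preprocess.run_pca(sm, 5)
        js = preprocess.jackstraw(sm, pcs, n_reps=20, prop=0.05, alpha=0.0, seed=1)
        assert js.selected_pcs == []

    def test_too_few_permuted_genes_rejected(self):
        sm = self.planted()
        pcs = preprocess.run_pca(sm, 5)
        with pytest.raises(ValueError, match="prop"):
            preprocess.jackstraw(sm, pcs, n_reps=20, prop=0.001, seed=1)


class TestFilterIdempotence:
    def test_refiltering_changes_nothing_after_gene_reevaluation(self):
        spec = SyntheticSpec(
            n_genes=500, cell_types=[CellType("A", 80, 0)], seed=11, base_mean_log_mu=0.3
        )
        data, _ = generate_dataset(spec)
        once = preprocess.filter_genes(preprocess.filter_cells(data["S1"]))
        twice = preprocess.filter_genes(preprocess.filter_cells(once))
        # cell filter is idempotent; gene filter re-evaluated on the reduced
        # cell set can only drop further genes, and then stabilizes
        thrice = preprocess.filter_genes(preprocess.filter_cells(twice))
        assert list(twice.obs_names) == list(once.obs_names)
        assert set(twice.var_names) <= set(once.var_names)
        assert list(thrice.var_names) == list(twice.var_names)
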