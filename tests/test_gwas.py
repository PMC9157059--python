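"""Variant filtering, centered GRM, variance-component fit, association scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modscreen import (
    compute_centered_grm,
    filter_variants,
    fit_null_lmm,
    lmm_association,
    simulate_genotypes,
    simulate_phenotypes,
    strain_means,
    top_variants,
)
from modscreen.datatypes import GenotypeMatrix, KinshipMatrix
from modscreen.gwas import _profiled_loglik
from modscreen.simulate import SimConfig


def _matrix(dosages, chroms=None, positions=None, ref=None, alt=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "chrom": chroms or ["2L"] * m,
        "pos": positions or list(range(100, 100 + m)),
        "ref": ref or ["A"] * m,
        "alt": alt or ["T"] * m,
    })
    return GenotypeMatrix(line_ids=[f"l{i}" for i in range(n)],
                          variants=variants, dosages=dosages)


class TestFilterVariants:
    def test_monomorphic_removed(self):
        G = _matrix([[0, 0], [2, 0], [2, 0]])
        Gf, rep = filter_variants(G)
        assert Gf.n_variants == 1
        assert rep.n_monomorphic == 1

    def test_maf_threshold_counts(self):
        # 10 variants, 3 with MAF 0.02 (1 alt line of 50): min_maf=0.05 keeps 7
        rng = np.random.default_rng(0)
        dos = 2.0 * (rng.random((50, 10)) < 0.4)
        dos[:, :3] = 0.0
        dos[0, :3] = 2.0  # MAF = 1/50 = 0.02
        G = _matrix(dos)
        Gf, rep = filter_variants(G, min_maf=0.05)
        assert Gf.n_variants == 7
        assert rep.n_low_maf == 3

    def test_nonbiallelic_removed(self):
        G = _matrix([[0, 2], [2, 0], [2, 2]], alt=["T", "T,G"])
        Gf, rep = filter_variants(G)
        assert rep.n_nonbiallelic == 1
        assert Gf.n_variants == 1

    def test_chromosome_exclusion(self):
        # X-linked variants are dropped (F1 males carry the donor X)
        G = _matrix([[0, 2], [2, 0], [0, 2]], chroms=["X", "2L"])
        Gf, rep = filter_variants(G, exclude_chromosomes={"X"})
        assert rep.n_excluded_chrom == 1
        assert list(Gf.variants["chrom"]) == ["2L"]

    def test_no_maf_filter_by_default_keeps_rare(self):
        dos = np.zeros((50, 1))
        dos[0, 0] = 2.0
        Gf, _ = filter_variants(_matrix(dos))
        assert Gf.n_variants == 1

    def test_empty_result_warns_not_raises(self):
        with pytest.warns(UserWarning, match="all variants removed"):
            Gf, _ = filter_variants(_matrix([[0], [0], [0]]))
        assert Gf.n_variants == 0


class TestCenteredGRM:
    def test_hand_computed_three_lines_two_variants(self):
        # centered cross-product of [[0,2],[2,0],[2,2]] divided by m=2
        G = _matrix([[0, 2], [2, 0], [2, 2]])
        K = compute_centered_grm(G).values
        expected = np.array([[10, -8, -2], [-8, 10, -2], [-2, -2, 4]]) / 9.0
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_identical_lines_give_zero_matrix(self):
        G = _matrix([[0, 2, 2], [0, 2, 2], [0, 2, 2]])
        np.testing.assert_allclose(compute_centered_grm(G).values, 0.0, atol=1e-14)

    def test_duplicated_line_matches_diagonal(self):
        rng = np.random.default_rng(1)
        dos = 2.0 * (rng.random((5, 40)) < 0.4)
        dos[4] = dos[0]  # line 4 duplicates line 0
        K = compute_centered_grm(_matrix(dos)).values
        assert K[0, 4] == pytest.approx(K[0, 0])

    def test_symmetric_psd_zero_row_sums(self, small_genotypes):
        K = compute_centered_grm(small_genotypes).values
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-9)
        evals = np.linalg.eigvalsh(K)
        assert evals.min() > -1e-8 * max(1.0, evals.max())

    def test_mean_imputation_neutral_in_grm(self):
        # an imputed entry equals the column mean, so it adds nothing after centering
        dos = np.array([[0, 2.0], [2, 0.0], [2, np.nan], [0, 2.0]])
        K = compute_centered_grm(_matrix(dos)).values
        dos2 = dos.copy()
        dos2[2, 1] = np.nanmean(dos[:, 1])
        K2 = compute_centered_grm(_matrix(dos2)).values
        np.testing.assert_allclose(K, K2)


class TestNullFit:
    def test_likelihood_at_optimum_beats_grid(self, small_screen):
        _, _, y, K = small_screen
        model = fit_null_lmm(y, K)
        d, U = model.eigenvalues, model.eigenvectors
        yr = U.T @ y.loc[K.line_ids].to_numpy()
        Xr = U.T @ np.ones((len(yr), 1))
        for log_lam in np.linspace(-5, 5, 21):
            ll, _, _ = _profiled_loglik(log_lam, yr, Xr, d, "reml")
            assert model.log_likelihood >= ll - 1e-8

    def test_null_lambda_indistinguishable_from_zero(self):
        # under no polygenic signal the REML LRT for lambda>0 stays below
        # the 95th percentile of the boundary chi2 mixture in >=90% of seeds
        ok = 0
        for seed in range(20):
            cfg = SimConfig(n_lines=150, n_variants=800, seed=seed)
            G = simulate_genotypes(cfg)
            ph = simulate_phenotypes(G, cfg)
            y = strain_means(ph, cfg.condition)
            K = compute_centered_grm(G)
            model = fit_null_lmm(y, K)
            d, U = model.eigenvalues, model.eigenvectors
            yr = U.T @ y.loc[K.line_ids].to_numpy()
            Xr = U.T @ np.ones((len(yr), 1))
            ll0 = _profiled_loglik(-12.0, yr, Xr, d, "reml")[0]
            lrt = 2 * (model.log_likelihood - ll0)
            ok += lrt < 2.706
        assert ok >= 18

    def test_non_finite_phenotype_rejected(self, small_screen):
        _, _, y, K = small_screen
        bad = y.copy()
        bad.iloc[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_null_lmm(bad, K)

    def test_non_psd_kinship_rejected(self):
        n = 12
        vals = -np.eye(n)
        K = KinshipMatrix(line_ids=[f"l{i}" for i in range(n)], values=vals)
        y = pd.Series(np.random.default_rng(0).normal(size=n),
                      index=[f"l{i}" for i in range(n)])
        with pytest.raises(ValueError, match="PSD"):
            fit_null_lmm(y, K)

    def test_ml_and_reml_both_supported(self, small_screen):
        _, _, y, K = small_screen
        for method in ("reml", "ml"):
            model = fit_null_lmm(y, K, method=method)
            assert model.lambda_hat >= 0
            assert model.tau_inv > 0


class TestAssociation:
    def test_constant_variant_flagged_na(self, small_screen):
        G, _, y, K = small_screen
        dos = G.dosages.copy()
        dos[:, 0] = 2.0
        Gc = GenotypeMatrix(line_ids=G.line_ids, variants=G.variants.copy(), dosages=dos)
        res = lmm_association(y, Gc, K)
        assert np.isnan(res["p"].iloc[0])
        # exactly the constant-after-imputation columns are NA
        constant = np.ptp(Gc.imputed_dosages(), axis=0) == 0.0
        np.testing.assert_array_equal(res["p"].isna().to_numpy(), constant)

    def test_p_monotone_in_statistic(self, small_screen):
        G, _, y, K = small_screen
        res = lmm_association(y, G, K).dropna(subset=["p"])
        order = res.sort_values("p")
        assert (np.diff(np.abs(order["stat"])) <= 1e-12).all()

    def test_affine_rescaling_of_y_preserves_p(self, small_screen):
        G, _, y, K = small_screen
        res0 = lmm_association(y, G, K)
        res1 = lmm_association(2.5 * y + 3.0, G, K)
        np.testing.assert_allclose(res0["p"], res1["p"], rtol=1e-6)

    def test_rotation_commuting_with_k_preserves_p(self, small_screen):
        # Householder reflection across an eigenvector of K commutes with K
        # and fixes the constant vector (1 is in K's null space because row
        # sums vanish), so rotating y and the dosages leaves the scan intact.
        G, _, y, K = small_screen
        res0 = lmm_association(y, G, K, lambda_override=0.7)
        d, U = np.linalg.eigh(K.values)
        v = U[:, -1]  # top eigenvector, orthogonal to 1
        Q = np.eye(len(v)) - 2.0 * np.outer(v, v)
        np.testing.assert_allclose(Q @ K.values @ Q.T, K.values, atol=1e-10)
        yr = pd.Series(Q @ y.loc[K.line_ids].to_numpy(), index=K.line_ids)
        Gr = GenotypeMatrix(line_ids=G.line_ids, variants=G.variants.copy(),
                            dosages=Q @ G.imputed_dosages())
        res1 = lmm_association(yr, Gr, K, lambda_override=0.7)
        np.testing.assert_allclose(res0["p"], res1["p"], rtol=1e-6, atol=1e-12)

    def test_isotropic_kinship_reduces_to_ols(self, small_screen):
        # K = cI: lambda and residual variance are confounded; p equals OLS
        G, _, y, _ = small_screen
        ols = lmm_association(y, G, compute_centered_grm(G), lambda_override=0.0)
        for c in (0.5, 2.0):
            Kc = KinshipMatrix(line_ids=G.line_ids, values=c * np.eye(G.n_lines))
            res = lmm_association(y, G, Kc)
            np.testing.assert_allclose(res["p"], ols["p"], rtol=1e-5)

    def test_per_variant_lambda_matches_fixed_when_lambda_forced(self, small_cfg):
        cfg = SimConfig(n_lines=40, n_variants=30, seed=17)
        G = simulate_genotypes(cfg)
        ph = simulate_phenotypes(G, cfg)
        y = strain_means(ph, cfg.condition)
        K = compute_centered_grm(G)
        a = lmm_association(y, G, K, mode="null_lambda_reused", lambda_override=0.3)
        b = lmm_association(y, G, K, mode="per_variant_lambda", lambda_override=0.3)
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-8)

    def test_structured_panel_inflation_controlled(self):
        # confounded polygenic background: LMM inflation nearer 1 than OLS
        cfg = SimConfig(n_lines=150, n_variants=2000, seed=101, fst=0.25,
                        n_clusters=3, h2_polygenic=0.6)
        G = simulate_genotypes(cfg)
        ph = simulate_phenotypes(G, cfg)
        y = strain_means(ph, cfg.condition)
        K = compute_centered_grm(G)
        med_chi2 = stats.chi2.ppf(0.5, 1)
        infl_lmm = np.nanmedian(lmm_association(y, G, K)["stat"] ** 2) / med_chi2
        infl_ols = np.nanmedian(lmm_association(y, G, K, lambda_override=0.0)["stat"] ** 2) / med_chi2
        assert abs(np.log(infl_lmm)) < abs(np.log(infl_ols))

    def test_benjamini_hochberg_column(self, small_screen):
        G, _, y, K = small_screen
        res = lmm_association(y, G, K, add_bh=True)
        ok = res.dropna(subset=["p"])
        assert (ok["p_bh"] >= ok["p"] - 1e-12).all()
        assert (ok["p_bh"] <= 1.0).all()


class TestTopVariants:
    def test_threshold_one_keeps_all(self, small_screen):
        G, _, y, K = small_screen
        res = lmm_association(y, G, K).dropna(subset=["p"])
        assert len(top_variants(res, 1.01)) == len(res)

    def test_threshold_below_min_empty(self, small_screen):
        G, _, y, K = small_screen
        res = lmm_association(y, G, K)
        assert len(top_variants(res, res["p"].min() / 2)) == 0

    def test_sorted_ascending_with_positional_tie_break(self):
        res = pd.DataFrame({
            "chrom": ["3R", "2L", "2L"], "pos": [5, 9, 2],
            "ref": ["A"] * 3, "alt": ["T"] * 3,
            "p": [0.01, 0.001, 0.01],
        })
        out = top_variants(res, 0.5)
        assert list(out["pos"]) == [9, 2, 5]
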