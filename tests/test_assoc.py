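"""Kinship, PCA, GLM/MLM scans, inflation factor and genotype summaries."""

import numpy as np
import pytest

from rohscan import (
    bonferroni_threshold,
    compute_kinship,
    compute_pcs,
    genotype_trait_summary,
    glm_scan,
    lambda_gc,
    mlm_scan,
)
from rohscan.assoc import P_FLOOR, reml_null
from rohscan.simdata import QTLSpec, SimConfig, simulate_dataset, simulate_phenotype

from conftest import make_matrix


def random_genotypes(n, m, seed, p=None):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, m) if p is None else np.full(m, p)
    return make_matrix(rng.binomial(2, p, size=(n, m)).astype(np.int8))


class TestKinship:
    def test_duplicated_samples_share_diagonal(self):
        g0 = random_genotypes(1, 100, seed=0)
        g = make_matrix(np.vstack([g0.dosage, g0.dosage, g0.dosage]))
        K = compute_kinship(g).values
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[1, 2] == pytest.approx(K[1, 1])

    def test_opposite_homozygotes_direct_formula(self):
        # two samples opposite at every marker: p_hat = 0.5, z = (-1, +1),
        # G_off = (-1)(+1) m / (2 m p(1-p)) = -1 / (2 * 0.25) = -2
        m = 50
        g = make_matrix(np.vstack([np.zeros(m), np.full(m, 2)]).astype(np.int8))
        K = compute_kinship(g).values
        assert K[0, 1] == pytest.approx(-2.0)
        assert K[0, 0] == pytest.approx(2.0)

    def test_unrelated_off_diagonals_near_structural_mean(self):
        # centering by sample allele frequencies forces zero row sums, so the
        # off-diagonal mean sits at -mean(diag)/(n-1); entries stay small
        n = 40
        g = random_genotypes(n, 4000, seed=1)
        K = compute_kinship(g).values
        off = K[~np.eye(n, dtype=bool)]
        expected_mean = -np.diag(K).mean() / (n - 1)
        assert off.mean() == pytest.approx(expected_mean, abs=1e-6)
        assert np.abs(off - expected_mean).max() < 0.12

    def test_monomorphic_only_rejected(self):
        g = make_matrix(np.zeros((4, 5), dtype=np.int8))
        with pytest.raises(ValueError, match="polymorphic"):
            compute_kinship(g)


class TestPCs:
    def test_two_subpopulations_separate_on_pc1(self):
        rng = np.random.default_rng(2)
        m = 500
        p1, p2 = rng.uniform(0.1, 0.9, m), rng.uniform(0.1, 0.9, m)
        pop1 = rng.binomial(2, p1, size=(30, m))
        pop2 = rng.binomial(2, p2, size=(30, m))
        g = make_matrix(np.vstack([pop1, pop2]).astype(np.int8))
        pcs = compute_pcs(g, 3)
        pc1 = pcs[:, 0]
        gap = abs(pc1[:30].mean() - pc1[30:].mean())
        spread = pc1[:30].std() + pc1[30:].std()
        assert gap > spread  # clean separation

    def test_duplicated_samples_identical_scores(self):
        g0 = random_genotypes(10, 200, seed=3)
        g = make_matrix(np.vstack([g0.dosage, g0.dosage[:1]]))
        pcs = compute_pcs(g, 2)
        np.testing.assert_allclose(pcs[0], pcs[-1], atol=1e-8)

    def test_k_bounds(self):
        g = random_genotypes(5, 50, seed=4)
        with pytest.raises(ValueError):
            compute_pcs(g, 5)
        assert compute_pcs(g, 0).shape == (5, 0)


class TestGLM:
    def test_perfect_fit_closed_form(self):
        g = make_matrix(np.array([[0], [0], [1], [1], [2], [2]], dtype=np.int8))
        y = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        res = glm_scan(g, y)
        row = res.table.iloc[0]
        assert row["beta"] == pytest.approx(1.0)
        assert row["p"] <= 1e-12  # reported at/near the positive floor
        assert row["p"] >= P_FLOOR

    def test_constant_dosage_untestable(self):
        g = make_matrix(np.ones((6, 1), dtype=np.int8))
        y = np.arange(6, dtype=float)
        res = glm_scan(g, y)
        row = res.table.iloc[0]
        assert row["p"] == 1.0 and row["beta"] == 0.0 and not row["testable"]

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        g = random_genotypes(50, 20, seed=5)
        y = rng.normal(size=50)
        cov = rng.normal(size=(50, 2))
        res = glm_scan(g, y, covariates=cov)
        for j in [0, 7, 19]:
            X = sm.add_constant(np.column_stack([cov, g.dosage[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert res.table["beta"][j] == pytest.approx(fit.params[-1], rel=1e-8)
            assert res.table["se"][j] == pytest.approx(fit.bse[-1], rel=1e-8)
            assert res.table["p"][j] == pytest.approx(fit.pvalues[-1], rel=1e-6)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(6)
        g = random_genotypes(80, 10_000, seed=6)
        y = rng.normal(size=80)
        res = glm_scan(g, y)
        frac = (res.table["p"] < 0.05).mean()
        # within 3 binomial SDs of 0.05 over 10k tests
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 10_000)

    def test_collinear_covariates_rejected(self):
        g = random_genotypes(20, 5, seed=7)
        cov = np.ones((20, 1))  # duplicates the intercept
        with pytest.raises(ValueError, match="collinear"):
            glm_scan(g, np.random.default_rng(0).normal(size=20), covariates=cov)

    def test_missing_phenotypes_dropped(self):
        g = random_genotypes(30, 10, seed=8)
        y = np.random.default_rng(1).normal(size=30)
        y[:5] = np.nan
        res = glm_scan(g, y)
        assert len(res.table) == 10  # scan completes on the 25 remaining


class TestThresholdAndLambda:
    @pytest.mark.parametrize(
        "m, alpha, expected",
        [(29_503, 0.01, 0.01 / 29_503), (1, 0.01, 0.01), (10, 0.05, 0.005)],
    )
    def test_bonferroni(self, m, alpha, expected):
        assert bonferroni_threshold(m, alpha) == pytest.approx(expected)

    def test_bonferroni_zero_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)

    def test_lambda_all_half_is_exactly_one(self):
        assert lambda_gc(np.full(1000, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_lambda_uniform_near_one(self):
        rng = np.random.default_rng(9)
        assert lambda_gc(rng.uniform(size=200_000)) == pytest.approx(1.0, abs=0.02)

    def test_lambda_inflated_when_p_halved(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=10_000)
        assert lambda_gc(p / 2) > 1.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            lambda_gc([np.nan])


class TestREMLOracle:
    def brute_force_reml(self, y, K, X, deltas):
        """Direct REML log-likelihood over a delta grid (no eigen shortcut)."""
        n, q = X.shape
        best, best_ll = None, -np.inf
        for delta in deltas:
            V = K + delta * np.eye(n)
            Vi = np.linalg.inv(V)
            XViX = X.T @ Vi @ X
            beta = np.linalg.solve(XViX, X.T @ Vi @ y)
            r = y - X @ beta
            sigma_g2 = float(r @ Vi @ r) / (n - q)
            ll = -0.5 * (
                (n - q) * np.log(2 * np.pi * sigma_g2)
                + (n - q)
                + np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XViX)[1]
                - np.linalg.slogdet(X.T @ X)[1]
            )
            if ll > best_ll:
                best, best_ll = (sigma_g2, sigma_g2 * delta), ll
        return best

    def test_variance_components_match_grid_search(self):
        rng = np.random.default_rng(11)
        n = 20
        g = random_genotypes(n, 300, seed=11)
        K = compute_kinship(g).values
        L = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        y = L @ rng.normal(size=n) * 0.8 + rng.normal(size=n) * 0.6 + 2.0
        X = np.ones((n, 1))
        vc, delta, _, _ = reml_null(y, K, X)
        deltas = np.logspace(-5, 5, 20001)
        sg2, se2 = self.brute_force_reml(y, K, X, deltas)
        assert vc.sigma_g2 == pytest.approx(sg2, abs=1e-3)
        assert vc.sigma_e2 == pytest.approx(se2, abs=1e-3)


class TestMLM:
    def test_matches_glm_when_no_polygenic_variance(self):
        # sigma_g2 = 0 truth: REML usually pins delta at its boundary, and the
        # scan must then reproduce the GLM to machine precision; chance
        # positive estimates on null data are tolerated but must be rare
        n_boundary = 0
        for seed in range(6):
            g = random_genotypes(60, 300, seed=seed)
            K = compute_kinship(g)
            y = np.random.default_rng(100 + seed).normal(size=60)
            res_glm = glm_scan(g, y)
            res_mlm, vc = mlm_scan(g, y, K)
            if vc.sigma_g2 == 0.0:
                n_boundary += 1
                np.testing.assert_allclose(
                    res_mlm.table["p"], res_glm.table["p"], rtol=1e-6
                )
        assert n_boundary >= 3

    def test_structured_cohort_calibration(self):
        # family structure: GLM inflates, MLM stays near 1
        cfg = SimConfig(n_samples=150, n_chrom=4, markers_per_chrom=500,
                        chrom_length_bp=25_000_000, generations=3,
                        inbred_mating_fraction=0.2, missing_rate=0.0,
                        het_error_rate=0.0, seed=23)
        g, m, _, _ = simulate_dataset(cfg)
        y, _ = simulate_phenotype(
            g, QTLSpec(marker_index=0, qtl_var=0.0, h2_polygenic=0.6), seed=23
        )
        K = compute_kinship(g)
        res_mlm, vc = mlm_scan(g, y, K, m=m)
        res_glm = glm_scan(g, y, m=m)
        assert vc.h2 > 0.2
        assert res_mlm.lambda_gc < res_glm.lambda_gc
        assert 0.8 < res_mlm.lambda_gc < 1.25

    def test_exact_reml_close_to_p3d_on_small_data(self):
        rng = np.random.default_rng(14)
        g = random_genotypes(30, 40, seed=14)
        K = compute_kinship(g)
        y = rng.normal(size=30)
        res_p3d, _ = mlm_scan(g, y, K)
        res_exact, _ = mlm_scan(g, y, K, exact_reml=True)
        np.testing.assert_allclose(
            res_exact.table["p"], res_p3d.table["p"], rtol=0.5
        )  # same ranking territory; exact refit shifts p modestly
        assert (res_exact.table["p"] > 0).all()


class TestGenotypeSummary:
    def test_constant_trait(self):
        out = genotype_trait_summary(
            np.array([0, 0, 1, 2]), ("T", "C"), np.full(4, 5.0)
        )
        assert (out["mean"] == 5.0).all() and (out["sd"] == 0.0).all()

    def test_hand_computed_groups(self):
        dosage = np.array([0, 0, 1, 1, 2, 2])
        y = np.array([3.1, 3.3, 3.0, 3.4, 2.9, 3.5])
        out = genotype_trait_summary(dosage, ("T", "C"), y)
        assert out.loc["TT", "n"] == 2
        assert out.loc["TT", "mean"] == pytest.approx(3.2)
        assert out.loc["TC", "sd"] == pytest.approx(np.std([3.0, 3.4], ddof=1))
        assert out.loc["CC", "mean"] == pytest.approx(3.2)

    def test_missing_genotype_forms_undefined_group(self):
        dosage = np.array([0, 1, 2, -1])
        y = np.array([1.0, 2.0, 3.0, 3.32])
        out = genotype_trait_summary(dosage, ("T", "C"), y)
        assert out.loc["undefined", "n"] == 1
        assert out.loc["undefined", "mean"] == pytest.approx(3.32)
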