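import numpy as np
import pytest

from iadep import (
    GBLUP,
    TraitConfig,
    VarianceComponents,
    compute_grm,
    gblup_fit_predict,
    reml_h2,
    ridge_fit,
    simulate_genotypes,
    simulate_trait,
)
from iadep.data_io import GenotypeMatrix


def _panel_from(dosages):
    dosages = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(dosages.shape[0])],
        markers=[f"m{j}" for j in range(dosages.shape[1])],
        dosages=dosages,
    )


class TestGRM:
    def test_single_snp_hand_example(self):
        # dosages (0, 2): p = 0.5, Z = (-1, +1), scale = 0.5
        g = _panel_from([[0], [2]])
        grm = compute_grm(g)
        np.testing.assert_allclose(grm.matrix, [[2, -2], [-2, 2]])
        assert grm.scale == 0.5

    def test_duplicated_individual(self):
        g = simulate_genotypes(30, 100, seed=1)
        g.dosages[1] = g.dosages[0]
        grm = compute_grm(g)
        np.testing.assert_allclose(grm.matrix[0], grm.matrix[1])
        np.testing.assert_allclose(grm.matrix[0, 1], grm.matrix[0, 0])

    def test_diagonal_mean_near_one_under_hwe(self):
        g = simulate_genotypes(800, 2000, seed=2)
        grm = compute_grm(g)
        assert abs(np.diag(grm.matrix).mean() - 1.0) < 0.05

    def test_symmetric_and_psd(self):
        g = simulate_genotypes(100, 300, seed=3)
        grm = compute_grm(g)
        np.testing.assert_allclose(grm.matrix, grm.matrix.T)
        evals = np.linalg.eigvalsh(grm.matrix)
        assert evals.min() > -1e-8

    def test_monomorphic_panel_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(_panel_from([[0, 2], [0, 2]]))


class TestGBLUP:
    def _sim(self, n=60, m=200, h2=0.5, seed=4):
        g = simulate_genotypes(n, m, seed=seed)
        pheno, truth = simulate_trait(
            g, TraitConfig(n_qtl_additive=20, h2_target=h2, seed=seed))
        return g, pheno["y"].to_numpy(), truth

    def test_zero_genetic_variance_predicts_training_mean(self):
        g, y, _ = self._sim()
        grm = compute_grm(g)
        tr, te = np.arange(40), np.arange(40, 60)
        vc = VarianceComponents(sigma2_g=1e-12, sigma2_e=1.0)
        pred = gblup_fit_predict(grm, y[tr], tr, te, vc=vc)
        np.testing.assert_allclose(pred, np.full(20, y[tr].mean()), atol=1e-6)

    def test_equivalence_with_marker_ridge_blup(self):
        """GBLUP on G = ZZ'/c equals RR-BLUP with matched variance ratio."""
        g, y, _ = self._sim(n=60, m=200, seed=5)
        grm = compute_grm(g)
        tr, te = np.arange(45), np.arange(45, 60)
        sigma_u2, sigma_e2 = 0.02, 0.7
        vc = VarianceComponents(sigma2_g=grm.scale * sigma_u2, sigma2_e=sigma_e2)
        pred = gblup_fit_predict(grm, y[tr], tr, te, vc=vc)

        # independent marker-effect oracle
        Z = g.dosages - 2 * grm.allele_freq[None, :]
        V = sigma_u2 * Z[tr] @ Z[tr].T + sigma_e2 * np.eye(45)
        Vi = np.linalg.inv(V)
        ones = np.ones(45)
        mu = (ones @ Vi @ y[tr]) / (ones @ Vi @ ones)
        u_hat = sigma_u2 * Z[tr].T @ Vi @ (y[tr] - mu)
        oracle = mu + Z[te] @ u_hat
        np.testing.assert_allclose(pred, oracle, atol=1e-6)

    def test_genetic_twin_recovers_phenotype_at_full_heritability(self):
        g, _, _ = self._sim(n=50, m=300, seed=6)
        g.dosages[-1] = g.dosages[0]  # test sample duplicates training sample 0
        pheno, truth = simulate_trait(
            g, TraitConfig(n_qtl_additive=30, h2_target=1.0, seed=7))
        y = pheno["y"].to_numpy()
        grm = compute_grm(g)
        tr, te = np.arange(49), np.array([49])
        vc = VarianceComponents(sigma2_g=float(np.var(y)), sigma2_e=1e-9)
        pred = gblup_fit_predict(grm, y[tr], tr, te, vc=vc)
        np.testing.assert_allclose(pred[0], y[0], atol=1e-5)

    def test_location_equivariance(self):
        g, y, _ = self._sim(n=80, m=150, seed=8)
        grm = compute_grm(g)
        tr, te = np.arange(60), np.arange(60, 80)
        base = gblup_fit_predict(grm, y[tr], tr, te)
        shifted = gblup_fit_predict(grm, y[tr] + 100.0, tr, te)
        np.testing.assert_allclose(shifted, base + 100.0, atol=1e-6)

    def test_model_object_summary(self):
        g, y, _ = self._sim(n=60, m=100, seed=9)
        import pandas as pd

        pheno = pd.DataFrame({"y": y}, index=g.samples)
        res = GBLUP(g, pheno).fit(train_idx=np.arange(45))
        assert "h2" in res.summary()
        assert res.predict(np.arange(45, 60)).shape == (15,)


class TestRidge:
    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(10)
        X, y = rng.standard_normal((40, 8)), rng.standard_normal(40)
        beta, icept, flagged = ridge_fit(X, y, 0.0)
        Xd = np.column_stack([np.ones(40), X])
        ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert not flagged
        np.testing.assert_allclose(beta, ols[1:], atol=1e-8)
        np.testing.assert_allclose(icept, ols[0], atol=1e-8)

    def test_coefficients_shrink_monotonically(self):
        rng = np.random.default_rng(11)
        X, y = rng.standard_normal((30, 10)), rng.standard_normal(30)
        norms = [np.linalg.norm(ridge_fit(X, y, lam)[0])
                 for lam in (0.0, 1.0, 10.0, 100.0, 1e4)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2 * norms[0]

    def test_matches_gradient_descent_oracle(self):
        rng = np.random.default_rng(12)
        X, y = rng.standard_normal((30, 10)), rng.standard_normal(30)
        lam = 3.0
        beta, icept, _ = ridge_fit(X, y, lam)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        b = np.zeros(10)
        lr = 1.0 / (np.linalg.norm(Xc, 2) ** 2 + lam)
        for _ in range(20000):
            b -= lr * (Xc.T @ (Xc @ b - yc) + lam * b)
        np.testing.assert_allclose(beta, b, atol=1e-5)

    def test_rank_deficient_lambda_zero_flagged_minimum_norm(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((5, 10))  # underdetermined
        y = rng.standard_normal(5)
        beta, _, flagged = ridge_fit(X, y, 0.0)
        assert flagged
        assert np.isfinite(beta).all()

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ridge_fit(np.eye(3), np.ones(3), -1.0)


class TestREML:
    def test_pure_noise_gives_low_h2(self):
        ests = []
        for seed in range(3):
            g = simulate_genotypes(500, 400, seed=seed)
            grm = compute_grm(g)
            y = np.random.default_rng(100 + seed).standard_normal(500)
            ests.append(reml_h2(grm.matrix, y).h2)
        assert np.mean(ests) < 0.1

    def test_noise_free_genetic_value_gives_high_h2(self):
        g = simulate_genotypes(300, 400, seed=20)
        pheno, _ = simulate_trait(g, TraitConfig(n_qtl_additive=50, h2_target=1.0, seed=21))
        vc = reml_h2(compute_grm(g).matrix, pheno["y"].to_numpy())
        assert vc.h2 > 0.9

    def test_recovers_intermediate_h2(self):
        ests = []
        for seed in range(3):
            g = simulate_genotypes(500, 600, seed=30 + seed)
            pheno, _ = simulate_trait(
                g, TraitConfig(n_qtl_additive=50, h2_target=0.5, seed=60 + seed))
            ests.append(reml_h2(compute_grm(g).matrix, pheno["y"].to_numpy()).h2)
        assert 0.35 < np.mean(ests) < 0.65

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="20"):
            reml_h2(np.eye(10), np.zeros(10))

    def test_components_nonnegative_and_h2_in_unit_interval(self):
        g = simulate_genotypes(200, 300, seed=40)
        pheno, _ = simulate_trait(g, TraitConfig(n_qtl_additive=20, h2_target=0.3, seed=41))
        vc = reml_h2(compute_grm(g).matrix, pheno["y"].to_numpy())
        assert vc.sigma2_g >= 0 and vc.sigma2_e >= 0
        assert 0.0 <= vc.h2 <= 1.0
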