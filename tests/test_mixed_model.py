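import numpy as np
import pandas as pd
import pytest
from scipy import linalg
from sklearn.base import clone

from kgp.data_model import GenotypeMatrix, KinshipMatrix, Pedigree, PhenotypeTable
from kgp.kinship import genomic_relationship_matrix, numerator_relationship_matrix
from kgp.mixed_model import (
    FlatLikelihoodError,
    GBLUPRegressor,
    ModelSpec,
    backsolve_ase,
    fit_gblup,
    fit_reml,
    gblup_solve,
    predict_phenotype,
    predictive_ability,
    reml_kernel,
)
from kgp.synthetic_data import SimConfig, simulate_dataset
from tests.conftest import single_trait_config


def henderson_mme_oracle(y, X, A, s2g, s2e):
    """Brute-force mixed-model equations by explicit dense inversion."""
    n = len(y)
    lam = s2e / s2g
    Ainv = linalg.inv(A)
    top = np.hstack([X.T @ X, X.T])
    bot = np.hstack([X, np.eye(n) + Ainv * lam])
    lhs = np.vstack([top, bot])
    rhs = np.concatenate([X.T @ y, y])
    sol = linalg.solve(lhs, rhs)
    return sol[: X.shape[1]], sol[X.shape[1]:]


# ----------------------------------------------------------------------- REML


class TestREML:
    def test_identity_kinship_unidentifiable(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        with pytest.raises(FlatLikelihoodError):
            reml_kernel(y, np.ones((30, 1)), np.eye(30))

    def test_half_sib_anova_oracle(self):
        # balanced paternal half-sib design: REML on the animal model and
        # the sire-variance ANOVA estimator agree on the same data
        n_sires, n_off = 40, 20
        h2, sd = 0.4, 1.0
        rng = np.random.default_rng(7)
        s2g = h2 * sd**2
        sire_eff = rng.normal(0, np.sqrt(s2g / 4), size=n_sires)
        y = np.repeat(sire_eff, n_off) + rng.normal(
            0, np.sqrt(sd**2 - s2g / 4), size=n_sires * n_off
        )
        # A: 0.25 between half sibs within a sire family
        block = np.full((n_off, n_off), 0.25) + 0.75 * np.eye(n_off)
        A = linalg.block_diag(*[block] * n_sires)
        vc, _ = reml_kernel(y, np.ones((len(y), 1)), A)
        # ANOVA oracle
        groups = y.reshape(n_sires, n_off)
        ms_between = n_off * groups.mean(axis=1).var(ddof=1)
        ms_within = groups.var(axis=1, ddof=1).mean()
        s2s = (ms_between - ms_within) / n_off
        h2_anova = 4 * s2s / (s2s + ms_within)
        assert vc.h2 == pytest.approx(h2_anova, abs=0.02)

    def test_shift_invariance(self, small_dataset):
        A = numerator_relationship_matrix(small_dataset.pedigree)
        pheno = small_dataset.phenotypes
        spec = ModelSpec(response="weight")
        vc1 = fit_reml(pheno, spec, A)
        shifted = PhenotypeTable(pheno.data.assign(weight=pheno.data.weight + 100.0))
        vc2 = fit_reml(shifted, spec, A)
        assert vc2.h2 == pytest.approx(vc1.h2, abs=1e-6)
        assert vc2.sigma2_g == pytest.approx(vc1.sigma2_g, rel=1e-5)

    def test_scale_equivariance(self, small_dataset):
        A = numerator_relationship_matrix(small_dataset.pedigree)
        pheno = small_dataset.phenotypes
        spec = ModelSpec(response="weight")
        vc1 = fit_reml(pheno, spec, A)
        scaled = PhenotypeTable(pheno.data.assign(weight=pheno.data.weight * 3.0))
        vc2 = fit_reml(scaled, spec, A)
        assert vc2.h2 == pytest.approx(vc1.h2, abs=1e-6)
        assert vc2.sigma2_g == pytest.approx(9.0 * vc1.sigma2_g, rel=1e-4)

    def test_boundary_solution_flagged(self):
        rng = np.random.default_rng(3)
        n = 60
        K = np.eye(n)
        K[: n // 2, : n // 2] += 0.5  # identifiable structure, zero signal
        y = rng.normal(size=n)
        vc, _ = reml_kernel(y, np.ones((n, 1)), K)
        assert vc.converged
        assert vc.sigma2_g >= 0.0

    def test_nonpositive_definite_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        K = linalg.block_diag(*[K] * 5)
        with pytest.raises(ValueError, match="regulariz"):
            reml_kernel(np.zeros(10), np.ones((10, 1)), K)


# ---------------------------------------------------------------------- GBLUP


class TestGBLUP:
    def test_identity_kinship_pure_shrinkage(self):
        rng = np.random.default_rng(1)
        n, h2 = 25, 0.3
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        beta, g_hat = gblup_solve(y, X, np.eye(n), h2, 1 - h2)
        np.testing.assert_allclose(g_hat, h2 * (y - beta[0]), atol=1e-10)

    def test_matches_henderson_oracle(self):
        # 2 families, pedigree A, known variances, n = 6
        ped = Pedigree(pd.DataFrame({
            "id": ["s1", "d1", "s2", "d2", "o1", "o2", "o3", "o4", "o5", "o6"],
            "sire": [None] * 4 + ["s1", "s1", "s1", "s2", "s2", "s2"],
            "dam": [None] * 4 + ["d1", "d1", "d1", "d2", "d2", "d2"],
            "stock_origin": ["wild"] * 10,
        }))
        ids = [f"o{i}" for i in range(1, 7)]
        A = numerator_relationship_matrix(ped).subset(ids).values
        rng = np.random.default_rng(2)
        y = rng.normal(size=6)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        beta, g_hat = gblup_solve(y, X, A, 1.0, 1.0)
        beta_o, g_o = henderson_mme_oracle(y, X, A, 1.0, 1.0)
        np.testing.assert_allclose(beta, beta_o, atol=1e-8)
        np.testing.assert_allclose(g_hat, g_o, atol=1e-8)

    def test_matches_henderson_oracle_n50(self):
        rng = np.random.default_rng(4)
        n = 50
        L = np.tril(rng.normal(size=(n, n))) * 0.2 + np.eye(n)
        K = L @ L.T
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        beta, g_hat = gblup_solve(y, X, K, 0.7, 1.3)
        beta_o, g_o = henderson_mme_oracle(y, X, K, 0.7, 1.3)
        np.testing.assert_allclose(g_hat, g_o, atol=1e-8)

    def test_vanishing_genetic_variance_shrinks_to_zero(self):
        rng = np.random.default_rng(5)
        n = 20
        K = np.eye(n) + 0.3
        y = rng.normal(size=n)
        _, g_hat = gblup_solve(y, np.ones((n, 1)), K, 1e-12, 1.0)
        np.testing.assert_allclose(g_hat, 0.0, atol=1e-9)

    def test_genomic_breeding_values_sum_to_zero_with_intercept(self, small_dataset):
        # centered W makes G·1 vanish (up to the ridge), so genomic BLUPs
        # are centered exactly through the intercept
        G = genomic_relationship_matrix(small_dataset.genotypes)
        fit = fit_gblup(small_dataset.phenotypes, ModelSpec(response="weight"), G)
        y = small_dataset.phenotypes.trait("weight").to_numpy()
        assert abs(fit.g_hat.sum()) < 1e-6 * np.std(y) * len(fit.g_hat)

    def test_id_mismatch_raises(self, small_dataset):
        A = numerator_relationship_matrix(small_dataset.pedigree)
        bad = PhenotypeTable(pd.DataFrame({"id": ["nobody"], "weight": [3.0],
                                           "stock_origin": ["wild"]}))
        with pytest.raises(ValueError, match="absent"):
            fit_gblup(bad, ModelSpec(response="weight"), A)


# ------------------------------------------------------------- ASE backsolve


@pytest.fixture(scope="module")
def fitted():
    cfg = single_trait_config(h2=0.42, missing_rate=0.0)
    data = simulate_dataset(cfg, seed=5)
    X = data.genotypes.to_float()
    y = data.phenotypes.trait("weight").to_numpy()
    model = GBLUPRegressor().fit(X, y)
    return model, X


class TestASEBacksolve:
    def test_reconstruction_identity(self, fitted):
        model, X = fitted
        p = model.allele_freq_
        W = X - 2 * p
        recon = W @ model.ase_
        rel_err = np.linalg.norm(recon - model.g_hat_) / np.linalg.norm(model.g_hat_)
        assert rel_err < 1e-4

    def test_single_marker_equals_gls_regression(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 3, 40).astype(float)
        w = x - x.mean()
        g_hat = 0.4 * w + rng.normal(0, 0.05, 40)
        p = x.mean() / 2
        phi = 1.0 / (2 * p * (1 - p))
        W = w[:, None]
        ase = backsolve_ase(g_hat, W, phi)
        # with one marker G = phi·ww', so alpha = (w'G^-1 g)·phi reduces to
        # the (ridge-regularized) projection coefficient of g_hat on w
        G = phi * np.outer(w, w) + 1e-6 * np.eye(40)
        expected = phi * (w @ linalg.solve(G, g_hat))
        assert ase[0] == pytest.approx(expected, rel=1e-10)

    def test_zero_breeding_values_zero_effects(self, fitted):
        model, X = fitted
        p = model.allele_freq_
        W = X - 2 * p
        ase = backsolve_ase(np.zeros(X.shape[0]), W, model.phi_)
        np.testing.assert_allclose(ase, 0.0, atol=1e-12)


# ------------------------------------------------------------------- predict


class TestPredict:
    def test_training_predictions_equal_fitted_values(self):
        cfg = single_trait_config(h2=0.42, missing_rate=0.0)
        data = simulate_dataset(cfg, seed=6)
        X = data.genotypes.to_float()
        y = data.phenotypes.trait("weight").to_numpy()
        model = GBLUPRegressor().fit(X, y)
        y_hat = model.predict(X)
        fitted = model.beta_[0] + model.g_hat_
        np.testing.assert_allclose(y_hat, fitted, atol=1e-3 * np.std(y))

    def test_zero_ase_predicts_fixed_mean(self):
        X = np.ones((4, 3))
        y_hat = predict_phenotype(np.array([2.5]), np.zeros(3),
                                  np.ones((4, 1)), X - 1.0)
        np.testing.assert_allclose(y_hat, 2.5)

    def test_unseen_factor_level_named(self, small_dataset):
        A = numerator_relationship_matrix(small_dataset.pedigree)
        pheno = small_dataset.phenotypes
        from kgp.mixed_model import _design_matrix

        _, _, levels = _design_matrix(pheno.data, ["stock_origin"])
        alien = pd.DataFrame({"stock_origin": ["martian"]})
        with pytest.raises(ValueError, match="martian"):
            _design_matrix(alien, ["stock_origin"], levels=levels)


# --------------------------------------------------------- predictive ability


class TestPredictiveAbility:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = predictive_ability(y, y, h2=1.0)
        assert m["accuracy"] == pytest.approx(1.0)
        assert m["r2"] == pytest.approx(1.0)

    def test_heritability_denominator_can_exceed_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = predictive_ability(y, y, h2=0.25)
        assert m["accuracy"] == pytest.approx(2.0)

    def test_unit_heritability_reports_raw_r(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=200)
        y_hat = 0.7 * y + rng.normal(size=200) * 0.5
        m = predictive_ability(y, y_hat, h2=1.0)
        assert m["accuracy"] == pytest.approx(m["r"])
        assert m["r2"] == pytest.approx(m["r"] ** 2)

    def test_zero_variance_flagged(self):
        m = predictive_ability([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not m["defined"]
        assert np.isnan(m["accuracy"])


# ------------------------------------------------------------ sklearn surface


class TestEstimatorAPI:
    def test_clone_and_params(self):
        model = GBLUPRegressor(h2=0.4, ridge=1e-5)
        c = clone(model)
        assert c.get_params() == {"h2": 0.4, "ridge": 1e-5}

    def test_fit_attributes(self, small_dataset):
        X = small_dataset.genotypes.to_float()
        y = small_dataset.phenotypes.trait("weight").to_numpy()
        model = GBLUPRegressor().fit(X, y)
        assert model.g_hat_.shape == (X.shape[0],)
        assert model.ase_.shape == (X.shape[1],)
        assert 0 <= model.h2_ <= 1
        assert model.varcomp_.sigma2_e > 0

    def test_fixed_h2_skips_reml(self, small_dataset):
        X = small_dataset.genotypes.to_float()
        y = small_dataset.phenotypes.trait("weight").to_numpy()
        model = GBLUPRegressor(h2=0.42).fit(X, y)
        assert model.h2_ == 0.42
        assert model.varcomp_.n_iter == 0

    def test_pipeline_composition(self, small_dataset):
        from sklearn.pipeline import Pipeline

        from kgp.marker_stats import MarkerQC

        X = small_dataset.genotypes.to_float()
        y = small_dataset.phenotypes.trait("weight").to_numpy()
        pipe = Pipeline([
            ("qc", MarkerQC(max_missing=0.2, min_maf=0.05)),
            ("gblup", GBLUPRegressor()),
        ])
        pipe.fit(X, y)
        assert pipe.predict(X).shape == y.shape


# --------------------------------------------------- A-vs-G ranking agreement


def test_pedigree_and_dense_marker_blup_rank_agree():
    """With very many unlinked markers, G converges toward the pedigree
    expectation and the two BLUP rankings agree."""
    cfg = single_trait_config(h2=0.42, n_markers=10_000, missing_rate=0.0,
                              genetic_mode="pedigree")
    data = simulate_dataset(cfg, seed=11)
    pheno = data.phenotypes
    spec = ModelSpec(response="weight")
    A = numerator_relationship_matrix(data.pedigree)
    G = genomic_relationship_matrix(data.genotypes)
    fit_a = fit_gblup(pheno, spec, A)
    fit_g = fit_gblup(pheno, spec, G)
    from scipy.stats import spearmanr

    rho = spearmanr(fit_a.g_hat, fit_g.g_hat)[0]
    assert rho > 0.9
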