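"""Variance-components ML estimation: oracles, recovery, invariances."""

import numpy as np
import pytest
from scipy import stats

import meqherit as mh
from meqherit.pedigree import kinship
from meqherit.polygenic import (
    PolygenicError,
    UnidentifiableError,
    build_design,
    fit_polygenic,
    grid_search_direct,
    lrt_pvalue,
    profile_loglik_direct,
    spectral_decompose,
)


def mvn_loglik_direct(y, X, K, h2, sigma2_p, beta):
    """Full (non-profiled) Gaussian log-density by dense factorization."""
    n = len(y)
    Omega = sigma2_p * (h2 * K + (1.0 - h2) * np.eye(n))
    return stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=Omega)


def mvn_loglik_spectral(y, X, K, h2, sigma2_p, beta):
    d, U = np.linalg.eigh(K)
    lam = sigma2_p * (h2 * d + (1.0 - h2))
    r = U.T @ (y - X @ beta)
    return -0.5 * (np.sum(np.log(2 * np.pi * lam)) + np.sum(r * r / lam))


@pytest.fixture(scope="module")
def fit_inputs(fixture30):
    coh = fixture30
    y = np.asarray(coh.phenotypes["latent_value"], dtype=float)
    X = np.ones((len(y), 1))
    K = kinship(coh.pedigree).values
    groups = [i.family_id for i in coh.pedigree.individuals]
    return y, X, K, groups


class TestLikelihoodEquivalence:
    def test_spectral_equals_dense_at_random_points(self, fit_inputs):
        y, X, K, _ = fit_inputs
        rng = np.random.default_rng(5)
        for _ in range(20):
            h2 = rng.uniform(0.0, 0.99)
            s2 = rng.uniform(0.3, 3.0)
            beta = rng.normal(size=1)
            a = mvn_loglik_direct(y, X, K, h2, s2, beta)
            b = mvn_loglik_spectral(y, X, K, h2, s2, beta)
            assert a == pytest.approx(b, abs=1e-6)

    def test_fit_matches_grid_search_oracle(self, fit_inputs):
        y, X, K, groups = fit_inputs
        fit = fit_polygenic(y, X, K, groups=groups)
        h2_grid, ll_grid = grid_search_direct(
            y, X, K, grid=np.linspace(0.0, 1.0, 401)
        )
        assert fit.h2 == pytest.approx(h2_grid, abs=0.01)
        assert fit.loglik >= ll_grid - 1e-10
        ll_direct_at_fit = profile_loglik_direct(y, X, K, fit.h2)[0]
        assert fit.loglik == pytest.approx(ll_direct_at_fit, abs=1e-6)

    def test_blockwise_eig_equals_dense(self, fit_inputs):
        y, X, K, groups = fit_inputs
        f1 = fit_polygenic(y, X, K, groups=groups)
        f2 = fit_polygenic(y, X, K)
        assert f1.h2 == pytest.approx(f2.h2, abs=1e-7)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)


class TestContracts:
    def test_identity_K_unidentifiable(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        with pytest.raises(UnidentifiableError):
            fit_polygenic(y, np.ones((20, 1)), np.eye(20))

    def test_non_psd_rejected(self, fit_inputs):
        y, X, K, _ = fit_inputs
        bad = K.copy()
        bad[0, 1] = bad[1, 0] = 1.9  # breaks positive semidefiniteness
        with pytest.raises(PolygenicError, match="semidefinite"):
            fit_polygenic(y, X, bad)

    def test_tiny_or_incomplete_inputs_rejected(self, fit_inputs):
        y, X, K, _ = fit_inputs
        with pytest.raises(PolygenicError):
            fit_polygenic(y[:2], X[:2], K[:2, :2])
        y2 = y.copy()
        y2[0] = np.nan
        with pytest.raises(PolygenicError, match="complete"):
            fit_polygenic(y2, X, K)

    def test_rank_deficient_design_rejected(self, fixture30):
        import pandas as pd

        df = fixture30.phenotypes.copy()
        df["sex"] = "female"  # constant column collides with the intercept
        with pytest.raises(PolygenicError, match="rank"):
            build_design(df, mh.ModelSpec("bad", ("sex",)))

    def test_variance_identity_and_nonnegativity(self, fit_inputs):
        y, X, K, groups = fit_inputs
        fit = fit_polygenic(y, X, K, groups=groups)
        assert fit.sigma2_a >= 0 and fit.sigma2_e >= 0
        assert fit.h2 == pytest.approx(fit.sigma2_a / fit.sigma2_p)
        assert fit.loglik >= fit.loglik_null


class TestLRT:
    def test_zero_statistic_gives_half(self):
        assert lrt_pvalue(-10.0, -10.0) == pytest.approx(0.5)

    def test_boundary_mixture_quantile(self):
        # LRT = 2.706: half the chi2_1 tail; independently
        # P(chi2_1 > c) = 2 * Phibar(sqrt(c))
        p = lrt_pvalue(-10.0, -10.0 - 2.706 / 2.0)
        indep = stats.norm.sf(np.sqrt(2.706))
        assert p == pytest.approx(0.05, abs=5e-4)
        assert p == pytest.approx(indep, rel=1e-10)

    def test_monotone_in_statistic(self):
        stats_ = [0.0, 0.5, 1.0, 3.0, 10.0, 40.0]
        ps = [lrt_pvalue(-1.0, -1.0 - s / 2.0) for s in stats_]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_negative_delta_rejected(self):
        with pytest.raises(PolygenicError):
            lrt_pvalue(-10.0, -9.9)


class TestInvariances:
    def test_affine_rescaling_of_phenotype(self, fit_inputs):
        y, X, K, groups = fit_inputs
        f1 = fit_polygenic(y, X, K, groups=groups)
        f2 = fit_polygenic(3.5 * y - 40.0, X, K, groups=groups)
        assert f2.h2 == pytest.approx(f1.h2, abs=1e-6)
        assert f2.sigma2_p == pytest.approx(3.5**2 * f1.sigma2_p, rel=1e-6)
        assert f2.beta["b0"] == pytest.approx(3.5 * f1.beta["b0"] - 40.0, rel=1e-6)

    def test_loglik_nondecreasing_in_nesting(self, fixture30):
        phen = fixture30.phenotypes.assign(
            meq_total=fixture30.phenotypes["latent_value"]
        )
        fits = mh.fit_table2_suite(phen, fixture30.pedigree)
        ll = {f.model: f.loglik for f in fits}
        assert ll["sex_age_age2_sexage"] >= ll["sex_age"] - 1e-8
        assert ll["sex_age"] >= ll["unadjusted"] - 1e-8


class TestNullBehaviour:
    def test_iid_noise_estimates_near_zero(self):
        """ML h2 on pure noise has only the boundary-pileup positive bias."""
        cfg = mh.SimConfig(n_families=40, seed=9)
        ped = mh.simulate_pedigree(cfg)
        K = kinship(ped)
        groups = [i.family_id for i in ped.individuals]
        eig = spectral_decompose(K, groups=groups)
        n = len(ped)
        X = np.ones((n, 1))
        rng = np.random.default_rng(99)
        h2s = [
            fit_polygenic(rng.normal(size=n), X, K, eig=eig).h2
            for _ in range(200)
        ]
        assert np.mean(h2s) < 0.07


class TestRecovery:
    @pytest.mark.parametrize("h2_true", [0.2, 0.8])
    def test_intercept_only_recovery(self, h2_true):
        """Mean ML estimate over 100 ~800-individual cohorts within 0.04."""
        seeds = np.random.default_rng(777 + int(h2_true * 10)).integers(
            2**31, size=100
        )
        h2s, ses = [], []
        for s in seeds:
            cfg = mh.SimConfig(
                n_families=110, sigma2_a=h2_true, sigma2_e=1 - h2_true,
                beta_age=0.0, beta_sex=0.0, beta_residence=0.0,
                mean_score=0.0, censor=False, seed=int(s),
            )
            coh = mh.simulate_cohort(cfg)
            ped = coh.pedigree
            K = kinship(ped)
            groups = [i.family_id for i in ped.individuals]
            fit = fit_polygenic(
                np.asarray(coh.phenotypes["latent_value"]),
                np.ones((len(ped), 1)), K, groups=groups,
            )
            h2s.append(fit.h2)
            ses.append(fit.se_h2)
        h2s, ses = np.array(h2s), np.array(ses)
        assert abs(h2s.mean() - h2_true) < 0.04
        # reported curvature SE tracks the sampling SD
        assert abs(h2s.std(ddof=1) - ses.mean()) < 0.3 * ses.mean()

    def test_adjusted_recovery_and_se_calibration(self, calibrated_batch):
        h2_adj = calibrated_batch["sex_age"]
        assert abs(h2_adj.mean() - 0.48) < 0.04
        se = calibrated_batch["se_sex_age"]
        assert abs(h2_adj.std(ddof=1) - se.mean()) < 0.3 * se.mean()

    def test_adjustment_raises_h2_when_covariates_matter(self, calibrated_batch):
        assert (
            calibrated_batch["sex_age"].mean()
            > calibrated_batch["unadjusted"].mean() + 0.1
        )

    def test_overfitting_age2_interaction_changes_nothing(self, calibrated_batch):
        """Adding age^2 and sex-by-age to data generated without them."""
        assert calibrated_batch["sex_age_age2_sexage"].mean() == pytest.approx(
            calibrated_batch["sex_age"].mean(), abs=0.01
        )

    def test_uninformative_covariates_leave_h2_unchanged(self):
        seeds = range(30)
        means = {m.name: [] for m in mh.TABLE2_MODELS}
        for s in seeds:
            cfg = mh.SimConfig(
                n_families=60, sigma2_a=0.5, sigma2_e=0.5,
                beta_age=0.0, beta_sex=0.0, beta_residence=0.0,
                mean_score=0.0, censor=False, seed=1000 + s,
            )
            coh = mh.simulate_cohort(cfg)
            phen = coh.phenotypes.assign(meq_total=coh.phenotypes["latent_value"])
            for f in mh.fit_table2_suite(phen, coh.pedigree):
                means[f.model].append(f.h2)
        avg = {k: np.mean(v) for k, v in means.items()}
        assert max(avg.values()) - min(avg.values()) < 0.03
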