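"""REML, GBLUP and SNP-BLUP against dense linear-algebra oracles."""

import numpy as np
import pytest

from gwablup.datamodel import center_genotypes
from gwablup.grm import GRMatrix, SnpWeightVector, build_grm
from gwablup.mixed_model import (
    MixedModelSpec,
    gblup_solve,
    reml_estimate,
    reml_loglik,
    snpblup_solve,
)
from gwablup.simulate import SimConfig, simulate_genotypes, simulate_phenotypes

from conftest import hwe_genotypes


def dense_reml_loglik(y, G, R_diag, sg, se):
    """Direct matrix REML log-likelihood with an intercept, for oracles."""
    n = len(y)
    V = sg * G + se * np.diag(R_diag)
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    xvx = one @ Vi @ one
    beta = (one @ Vi @ y) / xvx
    r = y - one * beta
    _, logdet = np.linalg.slogdet(V)
    return -0.5 * (logdet + np.log(xvx) + r @ Vi @ r)


def toy_spec(n=40, m=120, h2=0.4, seed=0, n_val=0):
    rng = np.random.default_rng(seed)
    g = hwe_genotypes(n + n_val, m, seed=seed + 1)
    p = g.codes.mean(axis=0) / 2
    X = center_genotypes(g, p)
    G = build_grm(X)
    train = g.sample_ids[:n]
    val = g.sample_ids[n:]
    R_diag = 1.0 / rng.uniform(1.0, 2.5, n)
    t = np.arange(n)
    L = np.linalg.cholesky(G.values[np.ix_(t, t)] + 1e-8 * np.eye(n))
    gval = L @ rng.standard_normal(n) * np.sqrt(h2)
    e = rng.standard_normal(n) * np.sqrt((1 - h2) * R_diag)
    y = 3.0 + gval + e
    spec = MixedModelSpec(G=G, y=y, train_ids=train, validation_ids=val,
                          R_diag=R_diag)
    return spec, X, G


class TestRemlEstimate:
    def test_loglik_matches_dense_formula(self):
        spec, _, G = toy_spec(seed=3)
        t = spec.train_idx
        for sg, se in [(0.3, 0.7), (1.2, 0.4), (0.05, 2.0)]:
            dense = dense_reml_loglik(
                spec.y, G.values[np.ix_(t, t)], spec.R_diag, sg, se
            )
            assert reml_loglik(spec, sg, se) == pytest.approx(dense, abs=1e-8)

    def test_optimum_matches_grid_search_oracle(self):
        """The AI-REML optimum attains the dense grid-search maximum."""
        spec, _, G = toy_spec(n=40, seed=7)
        est = reml_estimate(spec)
        t = spec.train_idx
        Gtt = G.values[np.ix_(t, t)]
        grid = np.linspace(0.02, 3.0, 40)
        grid_best = max(
            dense_reml_loglik(spec.y, Gtt, spec.R_diag, sg, se)
            for sg in grid for se in grid
        )
        at_opt = dense_reml_loglik(
            spec.y, Gtt, spec.R_diag, est.sigma2_g, est.sigma2_e
        )
        assert at_opt >= grid_best - 1e-4

    def test_loglik_trace_monotone(self):
        spec, _, _ = toy_spec(n=60, seed=11)
        est = reml_estimate(spec)
        trace = np.array(est.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert est.converged

    def test_pure_noise_gives_tiny_genetic_variance(self):
        spec, _, _ = toy_spec(n=150, m=300, h2=1e-6, seed=13)
        est = reml_estimate(spec)
        total = est.sigma2_g + est.sigma2_e
        assert est.sigma2_g < 0.10 * total

    def test_parameter_recovery_h2_030(self):
        """h2 estimates center on the simulated truth across replicates."""
        hits = 0
        for rep in range(8):
            cfg = SimConfig(n_train=400, n_validation=0, m=1500, n_qtl=0,
                            h2=0.3, seed=500 + rep)
            g = simulate_genotypes(cfg)
            obs, _, _ = simulate_phenotypes(g, cfg)
            from gwablup.datamodel import (
                compute_observation_weights,
                weighted_allele_freq,
            )

            vc = cfg.variance_components()
            w = compute_observation_weights(obs, vc)
            train = obs.ids_for("train")
            p = weighted_allele_freq(g, w, train)
            X = center_genotypes(g, p, w, train)
            G = build_grm(X)
            y = obs.table["trait"].to_numpy(float)
            wt = w.as_series().reindex(train).to_numpy()
            est = reml_estimate(
                MixedModelSpec(G=G, y=y, train_ids=train, R_diag=1.0 / wt)
            )
            # weighted-residual model: residual absorbs PE + lactation noise
            target = vc.sigma2_g / (vc.sigma2_g + vc.sigma2_pe + vc.sigma2_e)
            if abs(est.h2 - target) < 3 * 0.08:
                hits += 1
        assert hits >= 7

    def test_too_few_animals_rejected(self):
        spec, _, _ = toy_spec(n=40, seed=1)
        small = MixedModelSpec(
            G=spec.G, y=spec.y[:20], train_ids=spec.train_ids[:20],
            R_diag=spec.R_diag[:20],
        )
        with pytest.raises(ValueError, match="at least 30"):
            reml_estimate(small)


def mme_oracle(y, G_all, train_idx, R_diag, sg, se):
    """Joint mixed-model equations over (mu, g_all) by dense solve."""
    n_all = G_all.shape[0]
    n = len(train_idx)
    Z = np.zeros((n, n_all))
    Z[np.arange(n), train_idx] = 1.0
    Rinv = np.diag(1.0 / (R_diag * se))
    Ginv = np.linalg.inv(G_all) / sg
    lhs = np.zeros((1 + n_all, 1 + n_all))
    one = np.ones((n, 1))
    lhs[0, 0] = (one.T @ Rinv @ one).item()
    lhs[0, 1:] = (one.T @ Rinv @ Z).ravel()
    lhs[1:, 0] = lhs[0, 1:]
    lhs[1:, 1:] = Z.T @ Rinv @ Z + Ginv
    rhs = np.concatenate([[(one.T @ Rinv @ y).item()], Z.T @ Rinv @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[0], sol[1:]


class TestGblupSolve:
    def test_matches_dense_mme_oracle_including_validation(self):
        spec, _, G = toy_spec(n=40, n_val=10, seed=21)
        # jitter G to be safely invertible for the oracle
        G = GRMatrix(ids=G.ids, values=G.values + 1e-6 * np.eye(len(G.ids)),
                     denominator=G.denominator)
        spec = MixedModelSpec(G=G, y=spec.y, train_ids=spec.train_ids,
                              validation_ids=spec.validation_ids,
                              R_diag=spec.R_diag)
        fit = gblup_solve(spec, (0.5, 0.8))
        mu, g_hat = mme_oracle(
            spec.y, G.values, spec.train_idx, spec.R_diag, 0.5, 0.8
        )
        assert fit.mu == pytest.approx(mu, abs=1e-8)
        np.testing.assert_allclose(fit.gebv.to_numpy(), g_hat, atol=1e-8)

    def test_full_shrinkage_limit(self):
        spec, _, _ = toy_spec(n=40, seed=2)
        fit = gblup_solve(spec, (1e-10, 1.0))
        assert np.abs(fit.gebv.to_numpy()).max() < 1e-6

    def test_shrinkage_monotone_in_genetic_variance(self):
        spec, _, _ = toy_spec(n=50, seed=4)
        norms = [
            np.linalg.norm(gblup_solve(spec, (sg, 1.0)).gebv.to_numpy())
            for sg in [0.01, 0.1, 0.5, 2.0]
        ]
        assert np.all(np.diff(norms) > 0)

    def test_permutation_invariance(self):
        spec, _, G = toy_spec(n=30, n_val=5, seed=31)
        fit = gblup_solve(spec, (0.6, 0.9))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(spec.train_ids))
        spec_p = MixedModelSpec(
            G=G, y=spec.y[perm],
            train_ids=[spec.train_ids[i] for i in perm],
            validation_ids=spec.validation_ids,
            R_diag=spec.R_diag[perm],
        )
        fit_p = gblup_solve(spec_p, (0.6, 0.9))
        np.testing.assert_allclose(
            fit_p.gebv.reindex(fit.gebv.index).to_numpy(),
            fit.gebv.to_numpy(), atol=1e-9,
        )

    def test_cg_path_agrees_with_cholesky(self):
        spec, _, _ = toy_spec(n=60, seed=41)
        direct = gblup_solve(spec, (0.5, 1.0), method="direct")
        iterative = gblup_solve(spec, (0.5, 1.0), method="cg")
        np.testing.assert_allclose(
            iterative.gebv.to_numpy(), direct.gebv.to_numpy(), atol=1e-6
        )


class TestSnpBlupEquivalence:
    def test_gblup_equals_snpblup_for_arbitrary_weights(self):
        cfg = SimConfig(n_train=150, n_validation=50, m=600, seed=51)
        g = simulate_genotypes(cfg)
        obs, _, _ = simulate_phenotypes(g, cfg)
        rng = np.random.default_rng(1)
        p = g.codes.mean(axis=0) / 2
        X = center_genotypes(g, p)
        D = SnpWeightVector(rng.uniform(0.01, 3.0, g.n_snps))
        G = build_grm(X, D)
        train = obs.ids_for("train")
        val = obs.ids_for("validation")
        y = obs.table.set_index("sample_id").loc[train, "trait"].to_numpy(float)
        R_diag = 1.0 / rng.uniform(1, 3, len(train))
        spec = MixedModelSpec(G=G, y=y, train_ids=train, validation_ids=val,
                              R_diag=R_diag)
        fit = gblup_solve(spec, (0.8, 1.5))
        effects, gebv_snp, mu = snpblup_solve(
            X, D, (0.8, 1.5), y, train, R_diag=R_diag
        )
        scale = np.std(y)
        assert np.abs(
            gebv_snp.reindex(fit.gebv.index).to_numpy() - fit.gebv.to_numpy()
        ).max() < 1e-6 * scale
        assert mu == pytest.approx(fit.mu, abs=1e-8)

    def test_zero_weight_snp_gets_zero_effect(self):
        rng = np.random.default_rng(8)
        g = hwe_genotypes(50, 20, seed=8)
        X = center_genotypes(g, g.codes.mean(axis=0) / 2)
        d = rng.uniform(0.5, 2, 20)
        d[7] = 0.0
        y = rng.standard_normal(50)
        effects, _, _ = snpblup_solve(
            X, SnpWeightVector(d), (1.0, 1.0), y, g.sample_ids
        )
        assert effects[7] == 0.0
        assert np.abs(effects[np.arange(20) != 7]).min() > 0

    def test_single_snp_no_noise_limit(self):
        # one animal, one SNP, vanishing residual: effect -> y / X
        g = hwe_genotypes(30, 1, p=np.array([0.5]), seed=3)
        X = center_genotypes(g, np.array([0.5]))
        coef = np.array([2.5])
        y = X.X @ coef
        effects, _, _ = snpblup_solve(
            X, SnpWeightVector(np.ones(1)), (1.0, 1e-10), y, g.sample_ids,
            fit_mean=False,
        )
        assert effects[0] == pytest.approx(2.5, rel=1e-4)
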