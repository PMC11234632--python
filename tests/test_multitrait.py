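"""Canonical transformation, LR combination and multitrait equivalences."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from gwablup.datamodel import center_genotypes
from gwablup.grm import build_grm
from gwablup.multitrait import (
    CanonicalTransform,
    TraitCovariances,
    back_transform,
    canonical_transform,
    combine_canonical_lr,
    cross_trait_weights,
    to_canonical,
)

from conftest import hwe_genotypes
from test_weights import scan_from_lr


def random_pd(k, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((k, k))
    return A @ A.T * scale / k + 0.1 * np.eye(k)


class TestCanonicalTransform:
    def test_diagonal_case_is_trivial(self):
        cov = TraitCovariances(["a", "b"], np.diag([0.5, 0.2]), np.eye(2))
        tr = canonical_transform(cov)
        np.testing.assert_allclose(tr.canonical_genetic_variances, [0.5, 0.2])
        np.testing.assert_allclose(np.abs(tr.Q), np.eye(2), atol=1e-12)

    def test_simultaneous_diagonalization_properties(self):
        cov = TraitCovariances(
            ["a", "b", "c"], random_pd(3, 1), random_pd(3, 2)
        )
        tr = canonical_transform(cov)
        np.testing.assert_allclose(tr.Q @ cov.Ecov @ tr.Q.T, np.eye(3),
                                   atol=1e-10)
        QG = tr.Q @ cov.Gcov @ tr.Q.T
        np.testing.assert_allclose(QG, np.diag(tr.canonical_genetic_variances),
                                   atol=1e-10)
        assert np.all(np.diff(tr.canonical_genetic_variances) <= 1e-12)

    def test_equicorrelated_two_traits_match_ge_oracle(self):
        rho_g, rho_e = 0.6, 0.3
        G0 = np.array([[1.0, rho_g], [rho_g, 1.0]]) * 0.4
        E0 = np.array([[1.0, rho_e], [rho_e, 1.0]])
        tr = canonical_transform(TraitCovariances(["a", "b"], G0, E0))
        oracle = np.sort(scipy.linalg.eigvals(G0, E0).real)[::-1]
        np.testing.assert_allclose(tr.canonical_genetic_variances, oracle,
                                   atol=1e-10)
        # closed form for the equicorrelated pair: (1 +/- rho_g)/(1 +/- rho_e)
        expected = np.sort([0.4 * (1 + rho_g) / (1 + rho_e),
                            0.4 * (1 - rho_g) / (1 - rho_e)])[::-1]
        np.testing.assert_allclose(tr.canonical_genetic_variances, expected,
                                   atol=1e-10)

    def test_invariant_to_trait_rescaling(self):
        G0, E0 = random_pd(3, 5), random_pd(3, 6)
        S = np.diag([10.0, 0.2, 3.0])
        tr1 = canonical_transform(TraitCovariances(["a", "b", "c"], G0, E0))
        tr2 = canonical_transform(
            TraitCovariances(["a", "b", "c"], S @ G0 @ S, S @ E0 @ S)
        )
        np.testing.assert_allclose(
            tr2.canonical_genetic_variances,
            tr1.canonical_genetic_variances, atol=1e-10,
        )

    def test_nonpd_environmental_matrix_rejected(self):
        # correlations (0.97, -0.17, 0.16) reconstruct a non-PD matrix
        e_corr = np.array(
            [[1.0, 0.97, -0.17], [0.97, 1.0, 0.16], [-0.17, 0.16, 1.0]]
        )
        cov = TraitCovariances.from_correlations(
            ["milk", "protein", "scc"], [0.26, 0.20, 0.16], [1, 1, 1],
            np.array([[1, 0.85, 0.10], [0.85, 1, 0.096], [0.10, 0.096, 1]]),
            e_corr,
        )
        assert np.linalg.eigvalsh(e_corr)[0] < 0
        with pytest.raises(ValueError, match="not positive definite"):
            canonical_transform(cov)
        clipped = canonical_transform(cov, clip_nonpd=True)
        assert np.isfinite(clipped.canonical_genetic_variances).all()


class TestTransformRoundTrip:
    def test_round_trip_identity(self):
        cov = TraitCovariances(["a", "b", "c"], random_pd(3, 7),
                               random_pd(3, 8))
        tr = canonical_transform(cov)
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((25, 3))
        np.testing.assert_allclose(
            back_transform(to_canonical(Y, tr), tr), Y, atol=1e-10
        )

    def test_identity_transform_is_noop(self):
        tr = CanonicalTransform(Q=np.eye(2),
                                canonical_genetic_variances=np.ones(2),
                                trait_names=["a", "b"])
        Y = np.arange(10, dtype=float).reshape(5, 2)
        np.testing.assert_array_equal(to_canonical(Y, tr), Y)

    def test_linearity_of_back_transform(self):
        cov = TraitCovariances(["a", "b"], random_pd(2, 9), random_pd(2, 10))
        tr = canonical_transform(cov)
        rng = np.random.default_rng(2)
        A, B = rng.standard_normal((2, 6, 2))
        np.testing.assert_allclose(
            back_transform(2.0 * A + B, tr),
            2.0 * back_transform(A, tr) + back_transform(B, tr), atol=1e-12,
        )

    def test_missing_records_rejected(self):
        cov = TraitCovariances(["a", "b"], random_pd(2, 3), random_pd(2, 4))
        tr = canonical_transform(cov)
        Y = np.ones((4, 2))
        Y[1, 0] = np.nan
        with pytest.raises(ValueError, match="complete records"):
            to_canonical(Y, tr)


class TestCombineLr:
    def test_single_scan_is_identity(self):
        scan = scan_from_lr([1.0, 2.0, 0.5])
        out = combine_canonical_lr([scan])
        np.testing.assert_array_equal(out.lr, scan.lr)

    def test_independent_null_traits_sum_to_chi2_k_mean(self):
        rng = np.random.default_rng(12)
        k, m = 3, 4000
        scans = [scan_from_lr(0.5 * rng.chisquare(1, m)) for _ in range(k)]
        out = combine_canonical_lr(scans)
        assert np.mean(2 * out.lr) == pytest.approx(k, rel=0.05)

    def test_single_trait_qtl_dominates_combined_peak(self):
        rng = np.random.default_rng(13)
        base = 0.5 * rng.chisquare(1, 200)
        lr1 = base.copy()
        lr1[77] = 30.0
        scans = [scan_from_lr(lr1), scan_from_lr(0.5 * rng.chisquare(1, 200))]
        out = combine_canonical_lr(scans)
        assert int(np.argmax(out.lr)) == 77

    def test_map_mismatch_rejected(self):
        s1 = scan_from_lr([1.0, 2.0])
        s2 = scan_from_lr([1.0, 2.0], pos=[5, 6])
        with pytest.raises(ValueError, match="SNP maps"):
            combine_canonical_lr([s1, s2])


class TestCrossTraitWeights:
    def test_equal_vectors_are_fixed_point(self):
        pp = np.array([0.1, 0.5, 0.9])
        np.testing.assert_allclose(cross_trait_weights(pp, pp), pp)

    def test_hand_value(self):
        assert cross_trait_weights(
            np.array([0.25]), np.array([1.0])
        )[0] == pytest.approx(0.5)

    def test_cauchy_schwarz_bound(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(1e-3, 1, (2, 100))
        d = cross_trait_weights(a, b)
        assert np.all(d**2 <= a * b + 1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_trait_weights(np.ones(3), np.ones(4))


def stacked_mme_oracle(Y, G_all, train_idx, R_diag, Gcov, Ecov):
    """Direct multitrait GLS: V = Gcov x G_tt + Ecov x R, trait-major."""
    T = Y.shape[1]
    n = len(train_idx)
    n_all = G_all.shape[0]
    G_tt = G_all[np.ix_(train_idx, train_idx)]
    G_at = G_all[:, train_idx]
    R = np.diag(R_diag)
    V = np.kron(Gcov, G_tt) + np.kron(Ecov, R)
    Xd = np.kron(np.eye(T), np.ones((n, 1)))  # per-trait means
    y = Y.T.ravel()
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(Xd.T @ Vi @ Xd, Xd.T @ Vi @ y)
    r = y - Xd @ beta
    C = np.kron(Gcov, G_at)  # cov(g_all_stacked, y_stacked)
    g_hat = C @ Vi @ r
    return g_hat.reshape(T, n_all).T


class TestCanonicalMtGblupEquivalence:
    def test_canonical_route_matches_stacked_oracle(self):
        """Back-transformed canonical GEBV equal the direct multitrait MME."""
        from gwablup.mixed_model import MixedModelSpec, gblup_solve

        rng = np.random.default_rng(44)
        n, n_all, T = 50, 60, 3
        g = hwe_genotypes(n_all, 400, seed=44)
        X = center_genotypes(g, g.codes.mean(axis=0) / 2)
        G = build_grm(X)
        Gcov = random_pd(T, 20, scale=0.5)
        Ecov = random_pd(T, 21)
        train = g.sample_ids[:n]
        train_idx = np.arange(n)
        R_diag = 1.0 / rng.uniform(1, 2.5, n)
        Y = rng.standard_normal((n, T)) + 2.0

        tr = canonical_transform(TraitCovariances(["a", "b", "c"], Gcov, Ecov))
        Yc = to_canonical(Y, tr)
        gebv_c = np.column_stack(
            [
                gblup_solve(
                    MixedModelSpec(
                        G=G, y=Yc[:, t], train_ids=train,
                        validation_ids=g.sample_ids[n:], R_diag=R_diag,
                    ),
                    (max(tr.canonical_genetic_variances[t], 1e-10), 1.0),
                ).gebv.to_numpy()
                for t in range(T)
            ]
        )
        ours = back_transform(gebv_c, tr)
        oracle = stacked_mme_oracle(Y, G.values, train_idx, R_diag, Gcov, Ecov)
        np.testing.assert_allclose(ours, oracle, atol=1e-6)


class TestSingleTraitReduction:
    def test_multitrait_pipeline_with_one_trait_matches_single(self, sim_small):
        """A one-trait canonical analysis reproduces single-trait GWABLUP."""
        from gwablup.pipeline import run_multitrait, run_single_trait

        cfg, g, obs = (sim_small["config"], sim_small["genotypes"],
                       sim_small["obs"])
        vc = cfg.variance_components()
        # treat sigma2_pe + sigma2_e as environmental for the 1-trait "set"
        env = vc.sigma2_pe + vc.sigma2_e
        cov = TraitCovariances(["trait"], np.array([[vc.sigma2_g]]),
                               np.array([[env]]))
        mt = run_multitrait(g, obs, cov, vc, modes=("mtgwablup",), window=5)
        # the canonical trait is y/sqrt(env); the LR scan and the GEBV are
        # invariant to that joint rescaling, so the single-trait run with
        # components (sigma2_g, env) on the original scale must agree
        st = run_single_trait(
            g, obs, "trait", vc, modes=("gwablup",),
            prediction_varcomp=(vc.sigma2_g, env), evaluate=False,
        )
        ours = mt.gebv["mtgwablup"][:, 0]
        single = st.fits["gwablup"].gebv.reindex(mt.ids).to_numpy()
        np.testing.assert_allclose(ours, single, atol=1e-8)
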