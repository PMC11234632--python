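"""Canonical-transformation multitrait analysis.

With complete records on every trait, a multitrait animal model can be
rotated into independent single-trait analyses: find Q that
simultaneously diagonalizes the genetic covariance matrix G0 and the
environmental covariance matrix E0,

    Q E0 Q' = I,      Q G0 Q' = diag(canonical genetic variances),

analyse each canonical trait y_c = Q y separately (same relationship
matrix, environmental variance 1), and back-transform the canonical
GEBV with Q^-1.  The back-transformed GEBV equal those of the full
multitrait animal model.

For multitrait GWAS the canonical traits are independent, so per-SNP
likelihood ratios simply add across canonical traits; the summed LR feeds
the same smoothing / posterior-probability machinery as a single-trait
scan, giving one shared weight vector for all canonical traits.  The
per-trait-pair alternative D_jj(t,s) = sqrt(PP_j(t) PP_j(s)) is provided
for trait sets where a shared weight vector is not believable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .gwas import GwasScanResult
from scipy.stats import chi2


@dataclass
class TraitCovariances:
    """Genetic and environmental covariance matrices for a trait set."""

    trait_names: list[str]
    Gcov: np.ndarray
    Ecov: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.trait_names)
        self.Gcov = np.asarray(self.Gcov, dtype=float)
        self.Ecov = np.asarray(self.Ecov, dtype=float)
        for name, M in [("Gcov", self.Gcov), ("Ecov", self.Ecov)]:
            if M.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")

    @classmethod
    def from_correlations(cls, trait_names, g_var, e_var, g_corr, e_corr):
        """Build covariance matrices from variances and correlation matrices."""
        g_sd = np.sqrt(np.asarray(g_var, dtype=float))
        e_sd = np.sqrt(np.asarray(e_var, dtype=float))
        return cls(
            trait_names=list(trait_names),
            Gcov=np.asarray(g_corr) * np.outer(g_sd, g_sd),
            Ecov=np.asarray(e_corr) * np.outer(e_sd, e_sd),
        )


@dataclass
class CanonicalTransform:
    """Rows of Q map original traits to canonical traits (y_c = Q y)."""

    Q: np.ndarray
    canonical_genetic_variances: np.ndarray
    trait_names: list[str]

    @property
    def n_traits(self) -> int:
        return self.Q.shape[0]

    @property
    def Q_inv(self) -> np.ndarray:
        return np.linalg.inv(self.Q)


def canonical_transform(
    cov: TraitCovariances, clip_nonpd: bool = False
) -> CanonicalTransform:
    """Simultaneously diagonalize (Gcov, Ecov).

    Solves the generalized symmetric eigenproblem Gcov q = lambda Ecov q;
    the eigenvectors, scaled so Q Ecov Q' = I, define canonical traits with
    unit environmental variance and genetic variances equal to the
    eigenvalues (ordered descending).  Ecov must be positive definite;
    with ``clip_nonpd`` a non-PD input is projected to the nearest PD
    matrix by eigenvalue clipping at 1e-6 before transforming.
    """
    Ecov, Gcov = cov.Ecov, cov.Gcov
    e_eigs = np.linalg.eigvalsh(Ecov)
    if e_eigs[0] <= 0:
        if not clip_nonpd:
            raise ValueError(
                "environmental covariance matrix is not positive definite "
                f"(smallest eigenvalue {e_eigs[0]:.4g}); fix the inputs or "
                "pass clip_nonpd=True to project"
            )
        Ecov = _clip_pd(Ecov)
        Gcov = _clip_psd(Gcov)
    lam, phi = scipy.linalg.eigh(Gcov, Ecov)  # phi' Ecov phi = I
    order = np.argsort(lam)[::-1]
    lam, phi = lam[order], phi[:, order]
    Q = phi.T
    # deterministic sign: largest-magnitude entry of each row positive
    for i in range(Q.shape[0]):
        if Q[i, np.argmax(np.abs(Q[i]))] < 0:
            Q[i] *= -1
    return CanonicalTransform(
        Q=Q,
        canonical_genetic_variances=np.clip(lam, 0.0, None),
        trait_names=list(cov.trait_names),
    )


def _clip_pd(M: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    w, V = np.linalg.eigh(M)
    return (V * np.maximum(w, floor)) @ V.T


def _clip_psd(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(M)
    return (V * np.maximum(w, 0.0)) @ V.T


def to_canonical(Y: np.ndarray, transform: CanonicalTransform) -> np.ndarray:
    """Map animals x traits observations to canonical traits (no missing)."""
    Y = np.asarray(Y, dtype=float)
    if np.isnan(Y).any():
        raise ValueError(
            "missing trait records: the canonical transformation requires "
            "complete records; analyse traits separately instead"
        )
    if Y.shape[1] != transform.n_traits:
        raise ValueError("observation columns do not match the transform")
    return Y @ transform.Q.T


def back_transform(
    gebv_canonical: np.ndarray, transform: CanonicalTransform
) -> np.ndarray:
    """Map animals x canonical-trait GEBV back to the original traits."""
    g = np.asarray(gebv_canonical, dtype=float)
    if g.shape[1] != transform.n_traits:
        raise ValueError("gebv columns do not match the transform")
    return g @ transform.Q_inv.T


def combine_canonical_lr(scans: list[GwasScanResult]) -> GwasScanResult:
    """Sum per-SNP LR across independent canonical-trait scans.

    The reported p-value tests the combined 2*sum(LR) against chi-square
    with one degree of freedom per trait.
    """
    if not scans:
        raise ValueError("need at least one scan")
    ref = scans[0].table[["snp_id", "chrom", "pos"]]
    for s in scans[1:]:
        if not ref.equals(s.table[["snp_id", "chrom", "pos"]]):
            raise ValueError("scans have different SNP maps")
    k = len(scans)
    lr_sum = np.sum([s.lr for s in scans], axis=0)
    p = chi2.sf(2.0 * lr_sum, df=k)
    nlp = -chi2.logsf(2.0 * lr_sum, df=k) / np.log(10.0)
    table = ref.copy()
    table["b_hat"] = np.nan
    table["se"] = np.nan
    table["LR"] = lr_sum
    table["p_value"] = p
    table["neg_log10_p"] = nlp
    return GwasScanResult(
        table=table,
        varcomp=(np.nan, np.nan),
        n=scans[0].n,
        trait="+".join(s.trait for s in scans),
    )


def cross_trait_weights(pp_t: np.ndarray, pp_s: np.ndarray) -> np.ndarray:
    """Cross-trait weights D_jj(t, s) = sqrt(PP_j(t) PP_j(s))."""
    pp_t = np.asarray(pp_t, dtype=float)
    pp_s = np.asarray(pp_s, dtype=float)
    if pp_t.shape != pp_s.shape:
        raise ValueError("posterior-probability vectors differ in length")
    return np.sqrt(pp_t * pp_s)
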