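"""Variance-component estimation and GBLUP / SNP-BLUP prediction.

The working model for a single trait is

    y = 1 mu + g + e,   g ~ N(0, G sigma2_g),   e ~ N(0, R sigma2_e),

with y the training-cow yield deviations, G a genomic relationship matrix
over all genotyped animals and R = diag(1/w_i) the reciprocal observation
weights (cows with more lactations have smaller residual variance).

All heavy computation runs in a spectral parametrization: with
B = R^(-1/2) G_tt R^(-1/2) = U L U', the phenotype covariance becomes
V = R^(1/2) U (sigma2_g L + sigma2_e I) U' R^(1/2), so every REML
iteration and every GLS solve is O(n) after a single eigendecomposition.
Validation animals never contribute phenotypes; their genetic values are
predicted through the G cross-covariance block, which for BLUP equals
g_hat_v = G_vt G_tt^-1 g_hat_t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import LinearOperator, cg

from .datamodel import CenteredGenotypes, VarianceComponents
from .grm import GRMatrix, SnpWeightVector


@dataclass
class MixedModelSpec:
    """Data and structure of a single-trait animal-model analysis."""

    G: GRMatrix
    y: np.ndarray  # training phenotypes, aligned with train_ids
    train_ids: list[str]
    validation_ids: list[str] = field(default_factory=list)
    R_diag: np.ndarray | None = None  # per-training-animal 1/w_i; None = 1
    fit_mean: bool = True

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.train_ids),):
            raise ValueError("y must align with train_ids")
        if self.R_diag is None:
            self.R_diag = np.ones(len(self.train_ids))
        self.R_diag = np.asarray(self.R_diag, dtype=float)
        if np.any(self.R_diag <= 0):
            raise ValueError("R_diag entries must be > 0")
        lookup = {s: i for i, s in enumerate(self.G.ids)}
        missing = [s for s in self.train_ids + self.validation_ids if s not in lookup]
        if missing:
            raise ValueError(f"ids absent from GRM, e.g. {missing[:3]}")
        self.train_idx = np.array([lookup[s] for s in self.train_ids], dtype=np.intp)
        self.validation_idx = np.array(
            [lookup[s] for s in self.validation_ids], dtype=np.intp
        )
        self._rotation = None

    def rotation(self) -> "_Rotation":
        if self._rotation is None:
            self._rotation = _Rotation(self)
        return self._rotation


class _Rotation:
    """One-time spectral decomposition shared by REML, GWAS and BLUP."""

    def __init__(self, spec: MixedModelSpec):
        G_tt = spec.G.submatrix(spec.train_idx)
        self.w = 1.0 / spec.R_diag  # observation weights
        sw = np.sqrt(self.w)
        B = sw[:, None] * G_tt * sw[None, :]
        lam, U = np.linalg.eigh(B)
        self.lam = np.clip(lam, 0.0, None)  # G is PSD up to round-off
        self.U = U
        self.sw = sw
        self.y_rot = U.T @ (sw * spec.y)
        self.x_rot = U.T @ sw  # rotated intercept column
        self.log_det_R = -float(np.sum(np.log(self.w)))

    def rotate(self, v: np.ndarray) -> np.ndarray:
        """Map a training-space vector/matrix into the spectral basis."""
        return self.U.T @ (self.sw[:, None] * v if v.ndim == 2 else self.sw * v)


@dataclass
class RemlEstimate:
    sigma2_g: float
    sigma2_e: float
    se_sigma2_g: float
    se_sigma2_e: float
    loglik_trace: list[float]
    converged: bool
    n_iter: int

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


@dataclass
class GblupFit:
    mu: float
    gebv: pd.Series  # indexed by every id in the GRM
    varcomp_used: tuple[float, float]
    residual_norm: float
    iterations: int = 0

    def gebv_for(self, ids) -> np.ndarray:
        return self.gebv.reindex(ids).to_numpy(dtype=float)


def reml_loglik(
    spec: MixedModelSpec, sigma2_g: float, sigma2_e: float
) -> float:
    """Restricted log-likelihood (up to the universal REML constant)."""
    rot = spec.rotation()
    d = sigma2_g * rot.lam + sigma2_e
    dinv = 1.0 / d
    c = float(rot.x_rot**2 @ dinv)
    xdy = float((rot.x_rot * rot.y_rot) @ dinv)
    ypy = float(rot.y_rot**2 @ dinv) - (xdy**2 / c if spec.fit_mean else 0.0)
    ll = -0.5 * (np.log(d).sum() + rot.log_det_R + ypy)
    if spec.fit_mean:
        ll -= 0.5 * np.log(c)
    return float(ll)


def _reml_derivatives(rot: _Rotation, fit_mean: bool, sg: float, se: float):
    """First derivatives (scores) and average-information matrix, O(n)."""
    d = sg * rot.lam + se
    dinv = 1.0 / d
    x, y, lam = rot.x_rot, rot.y_rot, rot.lam

    def apply_P(v):
        pv = v * dinv
        if fit_mean:
            c = float(x**2 @ dinv)
            pv -= x * dinv * float((x * v) @ dinv) / c
        return pv

    py = apply_P(y)
    # traces of P V_k with V_g -> diag(lam), V_e -> I in the spectral basis
    if fit_mean:
        c = float(x**2 @ dinv)
        tr_pg = float(lam @ dinv) - float((lam * x**2) @ (dinv**2)) / c
        tr_pe = float(dinv.sum()) - float(x**2 @ (dinv**2)) / c
    else:
        tr_pg = float(lam @ dinv)
        tr_pe = float(dinv.sum())
    yp_g_py = float((lam * py) @ py)
    yp_e_py = float(py @ py)
    score = np.array([-0.5 * (tr_pg - yp_g_py), -0.5 * (tr_pe - yp_e_py)])
    p_lpy = apply_P(lam * py)
    p_py = apply_P(py)
    ai = 0.5 * np.array(
        [
            [float((lam * py) @ p_lpy), float((lam * py) @ p_py)],
            [float(py @ p_lpy), float(py @ p_py)],
        ]
    )
    em_grad = np.array([yp_g_py - tr_pg, yp_e_py - tr_pe])
    return score, ai, em_grad


def reml_estimate(
    spec: MixedModelSpec,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> RemlEstimate:
    """AI-REML for (sigma2_g, sigma2_e) with EM fallback steps.

    Average-information updates are attempted first; whenever an AI step
    proposes a non-positive component the iteration falls back to the
    (slower, positivity-respecting) EM update.  Accepted iterations are
    forced monotone in the restricted likelihood by step halving.
    Non-convergence is flagged on the estimate rather than raised.
    """
    if len(spec.train_ids) < 30:
        raise ValueError("REML needs at least 30 training animals")
    rot = spec.rotation()
    vary = float(np.var(spec.y))
    floor = 1e-8 * vary
    theta = np.array([0.5 * vary, 0.5 * vary])
    ll = reml_loglik(spec, *theta)
    trace = [ll]
    converged = False
    n = len(spec.y)
    it = 0
    for it in range(1, max_iter + 1):
        score, ai, em_grad = _reml_derivatives(rot, spec.fit_mean, *theta)
        try:
            step = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            step = None
        proposal = theta + step if step is not None else None
        if proposal is None or np.any(proposal <= 0):
            # EM fallback: sigma_k^2 += sigma_k^4 / n * (y'P V_k P y - tr(P V_k))
            proposal = theta + theta**2 * em_grad / n
            proposal = np.maximum(proposal, floor)
        # step-halving keeps the accepted likelihood path monotone
        new_ll = reml_loglik(spec, *proposal)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            proposal = 0.5 * (proposal + theta)
            new_ll = reml_loglik(spec, *proposal)
            halvings += 1
        rel_change = np.max(np.abs(proposal - theta) / np.maximum(theta, floor))
        theta = proposal
        ll = new_ll
        trace.append(ll)
        if rel_change < tol:
            converged = True
            break
    _, ai, _ = _reml_derivatives(rot, spec.fit_mean, *theta)
    try:
        cov = np.linalg.inv(ai)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        ses = np.array([np.nan, np.nan])
    return RemlEstimate(
        sigma2_g=float(theta[0]),
        sigma2_e=float(theta[1]),
        se_sigma2_g=float(ses[0]),
        se_sigma2_e=float(ses[1]),
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
    )


def gblup_solve(
    spec: MixedModelSpec,
    varcomp: tuple[float, float] | VarianceComponents,
    method: str = "direct",
    cg_tol: float = 1e-8,
) -> GblupFit:
    """Solve the GBLUP mixed-model equations and predict all animals.

    Training animals get their BLUP directly; animals without phenotypes
    (validation cows) are predicted through the G cross-covariance block,
    which is algebraically g_hat_v = G_vt G_tt^-1 g_hat_t.  ``method`` is
    ``direct`` (Cholesky) or ``cg`` (conjugate gradients, for very large n).
    """
    if isinstance(varcomp, VarianceComponents):
        sg, se_ = varcomp.sigma2_g, varcomp.sigma2_e
    else:
        sg, se_ = varcomp
    if not (sg > 0 and se_ > 0):
        raise ValueError("variance components must be > 0")
    t = spec.train_idx
    V = sg * spec.G.submatrix(t) + np.diag(se_ * spec.R_diag)
    one = np.ones(len(t))
    if method == "direct":
        try:
            cf = cho_factor(V, lower=True)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "singular GBLUP system; inspect grm_diagnostics of G"
            ) from e
        solve = lambda b: cho_solve(cf, b)
        iterations = 0
    elif method == "cg":
        op = LinearOperator(V.shape, matvec=lambda v: V @ v)
        counter = {"n": 0}

        def solve(b):
            def cb(_):
                counter["n"] += 1

            x, info = cg(op, b, rtol=cg_tol, maxiter=10 * len(b), callback=cb)
            if info != 0:
                raise np.linalg.LinAlgError(f"CG failed to converge (info={info})")
            return x

        iterations = 0
    else:
        raise ValueError(f"unknown solve method {method!r}")

    if spec.fit_mean:
        vi_one = solve(one)
        mu = float(vi_one @ spec.y) / float(vi_one @ one)
    else:
        mu = 0.0
    alpha = solve(spec.y - mu)
    if method == "cg":
        iterations = counter["n"]
    gebv_all = sg * (spec.G.values[:, t] @ alpha)
    resid = V @ alpha - (spec.y - mu)
    return GblupFit(
        mu=mu,
        gebv=pd.Series(gebv_all, index=spec.G.ids, name="gebv"),
        varcomp_used=(sg, se_),
        residual_norm=float(np.linalg.norm(resid)),
        iterations=iterations,
    )


def snpblup_solve(
    X: CenteredGenotypes,
    D: SnpWeightVector,
    varcomp: tuple[float, float] | VarianceComponents,
    y: np.ndarray,
    train_ids,
    R_diag: np.ndarray | None = None,
    fit_mean: bool = True,
) -> tuple[np.ndarray, pd.Series, float]:
    """Equivalent SNP-effect (ridge) solution of the weighted GBLUP model.

    Each SNP effect has prior variance sigma2_g D_jj / sum_j 2p_j(1-p_j)D_jj,
    so X beta reproduces the GBLUP genetic values built from the same
    weights.  Returns (per-SNP effects, gebv over all animals, mu).
    """
    if isinstance(varcomp, VarianceComponents):
        sg, se_ = varcomp.sigma2_g, varcomp.sigma2_e
    else:
        sg, se_ = varcomp
    y = np.asarray(y, dtype=float)
    lookup = {s: i for i, s in enumerate(X.sample_ids)}
    t = np.array([lookup[s] for s in train_ids], dtype=np.intp)
    if R_diag is None:
        R_diag = np.ones(len(t))
    den = float(np.sum(2.0 * X.p * (1.0 - X.p) * D.values))
    if not den > 0:
        raise ValueError("zero denominator in SNP-BLUP prior variances")
    Xt = X.X[t]
    Vs = (sg / den) * ((Xt * D.values) @ Xt.T) + np.diag(se_ * np.asarray(R_diag))
    cf = cho_factor(Vs, lower=True)
    if fit_mean:
        one = np.ones(len(t))
        vi_one = cho_solve(cf, one)
        mu = float(vi_one @ y) / float(vi_one @ one)
    else:
        mu = 0.0
    alpha = cho_solve(cf, y - mu)
    effects = (sg / den) * (D.values * (Xt.T @ alpha))
    gebv = pd.Series(X.X @ effects, index=X.sample_ids, name="gebv")
    return effects, gebv, mu
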