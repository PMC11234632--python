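"""BayesGC: GBLUP polygenic background plus BayesC variable selection.

The model extends GBLUP with a point-mass-plus-normal SNP term,

    y = mu + Z (g + sum_j I_j X_j b_j) + e,

where I_j in {0, 1} has prior inclusion probability pi, the effect prior
is b_j ~ N(0, sigma2_g / 1000), g ~ N(0, G_u sigma2_g) and
e ~ N(0, R sigma2_e) with R = diag(1/w_i).  Variance components stay
fixed at their REML estimates and pi is not learned.

Gibbs sampling cycles through (a) the overall mean, (b) every SNP in a
randomized order, sampling (I_j, b_j) jointly from the BayesC conditional
with the effect integrated out of the inclusion odds, and (c) the
polygenic vector.  The polygenic full conditional is sampled exactly via
a one-time spectral decomposition of the (weight-standardized) G matrix,
in whose eigenbasis the conditional precision is diagonal.  Randomness is
keyed to SNP identity, not column position, so permuting SNP columns
permutes the posterior inclusion probabilities identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CenteredGenotypes, VarianceComponents
from .grm import GRMatrix

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclass
class BayesGCConfig:
    pi: float = 0.001
    cycles: int = 10_000
    burnin: int = 2_000
    chains: int = 10
    effect_var_divisor: float = 1000.0  # prior var(b_j) = sigma2_g / this
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pi < 1:
            raise ValueError("pi must be in (0, 1)")
        if not self.burnin < self.cycles:
            raise ValueError("burnin must be < cycles")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class BayesGCFit:
    gebv: pd.Series  # posterior-mean genetic value, all animals
    pip: np.ndarray  # per-SNP posterior inclusion probability
    effect_mean: np.ndarray  # posterior mean of I_j b_j
    mu: float
    n_included_trace: list[np.ndarray]  # per chain, per post-burnin cycle
    config: BayesGCConfig


@njit(cache=False)
def _snp_sweep(Xs, w, wxsq, r, b, incl, order, u, z,
               sigma2_e, inv_sb2, log_prior_odds):
    """One randomized Gibbs sweep over all SNP (I_j, b_j) pairs in place."""
    m, n = Xs.shape
    for k in range(m):
        j = order[k]
        bj = b[j]
        if incl[j] == 1:  # remove current contribution from the residual
            for i in range(n):
                r[i] += Xs[j, i] * bj
        rhs = 0.0
        for i in range(n):
            rhs += w[i] * Xs[j, i] * r[i]
        rhs /= sigma2_e
        lhs = wxsq[j] / sigma2_e + inv_sb2
        log_odds = (log_prior_odds
                    + 0.5 * (np.log(inv_sb2) - np.log(lhs))
                    + 0.5 * rhs * rhs / lhs)
        if log_odds > 35.0:
            p_incl = 1.0
        elif log_odds < -35.0:
            p_incl = 0.0
        else:
            p_incl = 1.0 / (1.0 + np.exp(-log_odds))
        if u[j] < p_incl:
            bj = rhs / lhs + z[j] / np.sqrt(lhs)
            for i in range(n):
                r[i] -= Xs[j, i] * bj
            b[j] = bj
            incl[j] = 1
        else:
            b[j] = 0.0
            incl[j] = 0


def bayesgc_fit(
    y: np.ndarray,
    X: CenteredGenotypes,
    G_u: GRMatrix,
    varcomp: tuple[float, float] | VarianceComponents,
    config: BayesGCConfig,
    train_ids,
    validation_ids=(),
    R_diag: np.ndarray | None = None,
) -> BayesGCFit:
    """Gibbs-sample the BayesGC model; reproducible given config.seed."""
    if isinstance(varcomp, VarianceComponents):
        sg, se = varcomp.sigma2_g, varcomp.sigma2_e
    else:
        sg, se = varcomp
    y = np.asarray(y, dtype=float)
    train_ids = list(train_ids)
    validation_ids = list(validation_ids)
    lookup_g = {s: i for i, s in enumerate(G_u.ids)}
    t_g = np.array([lookup_g[s] for s in train_ids], dtype=np.intp)
    v_g = np.array([lookup_g[s] for s in validation_ids], dtype=np.intp)
    lookup_x = {s: i for i, s in enumerate(X.sample_ids)}
    t_x = np.array([lookup_x[s] for s in train_ids], dtype=np.intp)
    v_x = np.array([lookup_x[s] for s in validation_ids], dtype=np.intp)
    n = len(train_ids)
    if R_diag is None:
        R_diag = np.ones(n)
    w = 1.0 / np.asarray(R_diag, dtype=float)
    sw = np.sqrt(w)

    G_tt = G_u.submatrix(t_g)
    B = sw[:, None] * G_tt * sw[None, :]
    lam, U = np.linalg.eigh(B)
    if lam[0] < -1e-8 * max(lam[-1], 1.0):
        raise ValueError(f"G is not positive semidefinite (min eig {lam[0]:.3g})")
    lam = np.clip(lam, 0.0, None)
    sqrt_lam = np.sqrt(lam)
    # validation predictor: G_vt G_tt^-1 g_t expressed in the eigenbasis
    active = lam > 1e-10 * max(lam[-1], 1.0)
    if v_g.size:
        T_val = (G_u.values[np.ix_(v_g, t_g)] * sw[None, :]) @ (
            U[:, active] / sqrt_lam[active]
        )

    Xt = X.X[t_x]
    m = Xt.shape[1]
    Xs = np.ascontiguousarray(Xt.T)  # SNP-major for the kernel
    wxsq = (Xt**2).T @ w
    sb2 = sg / config.effect_var_divisor
    log_prior_odds = float(np.log(config.pi / (1.0 - config.pi)))

    # stable per-identity randomness: draws are generated in sorted-snp-id
    # order and scattered to columns through each column's id rank
    snp_ids = X.snps["snp_id"].to_numpy()
    id_rank = np.argsort(np.argsort(snp_ids, kind="stable"), kind="stable")

    post_v = np.zeros(n)
    post_b = np.zeros(m)
    post_pip = np.zeros(m)
    post_mu = 0.0
    n_samples = 0
    included_traces = []
    wsum = float(w.sum())

    for chain in range(config.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), chain])
        )
        v = np.zeros(n)  # polygenic coordinates in the eigenbasis
        b = np.zeros(m)
        incl = np.zeros(m, dtype=np.uint8)
        mu = 0.0
        g_t = np.zeros(n)
        r = y - mu - g_t  # residual y - mu - Xb - g
        trace = np.zeros(config.cycles - config.burnin, dtype=np.int64)
        for cycle in range(config.cycles):
            # (a) overall mean
            r += mu
            mu = float(w @ r) / wsum + rng.standard_normal() * np.sqrt(se / wsum)
            r -= mu
            # (b) SNP effects, identity-keyed randomness
            d_order = rng.random(m)
            d_u = rng.random(m)
            d_z = rng.standard_normal(m)
            u = d_u[id_rank]
            z = d_z[id_rank]
            order = np.argsort(d_order[id_rank], kind="stable").astype(np.int64)
            _snp_sweep(Xs, w, wxsq, r, b, incl, order, u, z,
                       se, 1.0 / sb2, log_prior_odds)
            # (c) polygenic vector in the spectral basis: diagonal precision
            r += g_t
            zres = U.T @ (sw * r)
            prec = lam / se + 1.0 / sg
            mean_v = (sqrt_lam * zres / se) / prec
            v = mean_v + rng.standard_normal(n) / np.sqrt(prec)
            g_t = (U @ (sqrt_lam * v)) / sw
            r -= g_t
            if not np.isfinite(r).all():
                raise FloatingPointError(
                    f"chain {chain}: sampler state became non-finite "
                    f"at cycle {cycle}"
                )
            if cycle >= config.burnin:
                k = cycle - config.burnin
                trace[k] = int(incl.sum())
                post_v += v
                post_b += b * incl
                post_pip += incl
                post_mu += mu
                n_samples += 1
        included_traces.append(trace)

    post_v /= n_samples
    post_b /= n_samples
    post_pip /= n_samples
    post_mu /= n_samples

    gebv = pd.Series(0.0, index=list(G_u.ids), name="gebv")
    g_train = (U @ (sqrt_lam * post_v)) / sw
    gebv.iloc[t_g] = g_train + Xt @ post_b
    if v_g.size:
        gebv.iloc[v_g] = T_val @ post_v[active] + X.X[v_x] @ post_b
    return BayesGCFit(
        gebv=gebv,
        pip=post_pip,
        effect_mean=post_b,
        mu=post_mu,
        n_included_trace=included_traces,
        config=config,
    )


def bayesgc_report(fit: BayesGCFit, snps: pd.DataFrame, out_prefix: str | Path,
                   roles: dict[str, str] | None = None) -> None:
    """Write per-SNP PIP/effect and per-animal gebv TSVs."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "snp_id": snps["snp_id"],
            "chrom": snps["chrom"],
            "pos": snps["pos"],
            "pip": fit.pip,
            "effect_mean": fit.effect_mean,
        }
    ).to_csv(Path(str(out_prefix) + ".snps.tsv"), sep="\t", index=False,
             float_format="%.12g")
    g = fit.gebv.rename_axis("sample_id").reset_index()
    if roles:
        g["role"] = g["sample_id"].map(roles)
    g.to_csv(Path(str(out_prefix) + ".gebv.tsv"), sep="\t", index=False,
             float_format="%.12g")
    chains = pd.DataFrame(
        {
            "chain": np.arange(len(fit.n_included_trace)),
            "mean_included": [tr.mean() for tr in fit.n_included_trace],
            "sd_included": [tr.std() for tr in fit.n_included_trace],
        }
    )
    chains.to_csv(Path(str(out_prefix) + ".chains.tsv"), sep="\t", index=False,
                  float_format="%.12g")
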