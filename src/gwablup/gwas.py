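"""EMMAX-type single-SNP association scan.

Each SNP j is tested in y = X_j b_j + g + e with the polygenic covariance
V = G_u sigma2_g + R sigma2_e held fixed at its null-model (no-SNP) REML
estimates.  The GLS estimate, its standard error and the natural-log
likelihood ratio are

    b_hat_j = (X_j' V^-1 X_j)^-1 X_j' V^-1 y
    se_j    = (X_j' V^-1 X_j)^-1/2
    LR_j    = 1/2 y' V^-1 X_j b_hat_j = 1/2 (b_hat_j / se_j)^2

No intercept is fitted: the genotype columns are centered to zero
weighted training mean, which makes the SNP effect orthogonal to the
overall mean; the phenotype is centered by its weighted mean for the same
reason.  One O(n^3) spectral rotation reduces every per-SNP test to O(n).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .datamodel import CenteredGenotypes, VarianceComponents
from .grm import GRMatrix
from .mixed_model import MixedModelSpec

_LN10 = np.log(10.0)


@dataclass
class GwasScanResult:
    """Per-SNP scan output plus the metadata needed to interpret it."""

    table: pd.DataFrame  # snp_id chrom pos b_hat se LR p_value neg_log10_p
    varcomp: tuple[float, float]
    n: int
    trait: str = "trait"

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos", "b_hat", "se", "LR",
                    "p_value", "neg_log10_p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"scan table lacks columns {sorted(missing)}")

    @property
    def lr(self) -> np.ndarray:
        return self.table["LR"].to_numpy(dtype=float)


def lr_to_pvalue(lr) -> tuple[np.ndarray, np.ndarray]:
    """Map natural-log likelihood ratios to (p, -log10 p) via chi2(1 df).

    2 LR is the squared Wald t statistic, so its null distribution is
    chi-square with one degree of freedom.  The -log10 p is computed from
    the log-scale tail so huge LR values do not underflow to p = 0.
    """
    lr = np.asarray(lr, dtype=float)
    if np.any(lr < 0):
        raise ValueError("likelihood ratios must be >= 0")
    p = chi2.sf(2.0 * lr, df=1)
    # chi2(1) tail = 2 Phi(-sqrt(x)); log_ndtr stays finite far past where
    # logsf underflows, so -log10 p survives LR in the millions
    from scipy.special import log_ndtr

    log_p = np.log(2.0) + log_ndtr(-np.sqrt(2.0 * lr))
    neg_log10_p = -log_p / _LN10
    return p, neg_log10_p


def emmax_scan(
    y: np.ndarray,
    X: CenteredGenotypes,
    G_u: GRMatrix,
    varcomp: tuple[float, float] | VarianceComponents,
    train_ids,
    R_diag: np.ndarray | None = None,
    trait: str = "trait",
    spec: MixedModelSpec | None = None,
) -> GwasScanResult:
    """Scan every SNP by GLS with fixed variance components.

    ``y`` aligns with ``train_ids``; only training animals enter.  The
    phenotype is centered by its observation-weighted mean before testing.
    Degenerate SNP columns (zero GLS information) get b_hat = 0, LR = 0 and
    are flagged in the ``degenerate`` column.  Passing a ``spec`` whose
    training set and weights match reuses its spectral decomposition.
    """
    if isinstance(varcomp, VarianceComponents):
        sg, se_ = varcomp.sigma2_g, varcomp.sigma2_e
    else:
        sg, se_ = varcomp
    if not (sg > 0 and se_ > 0):
        raise ValueError("variance components must be > 0")
    y = np.asarray(y, dtype=float)
    if spec is None:
        spec = MixedModelSpec(
            G=G_u, y=y, train_ids=list(train_ids), R_diag=R_diag,
            fit_mean=False,
        )
    rot = spec.rotation()
    w = rot.w
    yc = y - float(w @ y) / float(w.sum())
    d = sg * rot.lam + se_
    s = 1.0 / np.sqrt(d)
    y_t = s * rot.rotate(yc)
    lookup = {sid: i for i, sid in enumerate(X.sample_ids)}
    t = np.array([lookup[sid] for sid in train_ids], dtype=np.intp)
    Xt = rot.rotate(X.X[t]) * s[:, None]
    info = np.einsum("ij,ij->j", Xt, Xt)  # X_j' V^-1 X_j
    xy = Xt.T @ y_t  # X_j' V^-1 y
    degenerate = info <= 1e-12 * max(1.0, float(info.max(initial=0.0)))
    safe = np.where(degenerate, 1.0, info)
    b_hat = np.where(degenerate, 0.0, xy / safe)
    se_b = np.where(degenerate, np.nan, 1.0 / np.sqrt(safe))
    lr = np.where(degenerate, 0.0, 0.5 * xy**2 / safe)
    p, nlp = lr_to_pvalue(lr)
    table = pd.DataFrame(
        {
            "snp_id": X.snps["snp_id"].to_numpy(),
            "chrom": X.snps["chrom"].to_numpy(),
            "pos": X.snps["pos"].to_numpy(),
            "b_hat": b_hat,
            "se": se_b,
            "LR": lr,
            "p_value": p,
            "neg_log10_p": nlp,
            "degenerate": degenerate,
        }
    )
    return GwasScanResult(
        table=table, varcomp=(sg, se_), n=len(train_ids), trait=trait
    )


SCAN_COLUMNS = ["snp_id", "chrom", "pos", "b_hat", "se", "LR",
                "p_value", "neg_log10_p"]


def write_scan(result: GwasScanResult, path: str | Path) -> None:
    """Write the scan as a TSV, position-sorted, 12 significant digits."""
    result.table[SCAN_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_scan(
    path: str | Path, varcomp=(np.nan, np.nan), n: int = 0, trait: str = "trait"
) -> GwasScanResult:
    t = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    return GwasScanResult(table=t, varcomp=tuple(varcomp), n=n, trait=trait)


def manhattan_plot(result: GwasScanResult, path: str | Path,
                   threshold: float = 1e-7) -> None:
    """Cosmetic Manhattan plot of -log10 p by genome position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, ax = plt.subplots(figsize=(9, 3))
    offset, ticks = 0, []
    for i, (chrom, grp) in enumerate(t.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, grp["neg_log10_p"], s=4,
                   color="C0" if i % 2 == 0 else "C1")
        ticks.append((chrom, x.mean()))
        offset = x.max()
    ax.axhline(-np.log10(threshold), color="steelblue", lw=1)
    ax.set_xticks([p for _, p in ticks], [c for c, _ in ticks])
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 P")
    ax.set_title(result.trait)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
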