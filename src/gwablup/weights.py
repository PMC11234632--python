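"""From GWAS likelihood ratios to per-SNP prediction weights.

GWAS signals are erratic SNP to SNP, so the likelihood ratios are first
smoothed by a moving average over an odd window of neighbouring SNPs
(mimicking the model averaging of Bayesian variable selection), then
converted to posterior probabilities of a non-zero effect,

    PP_j = pi e^(LR_j) / [pi e^(LR_j) + (1 - pi)],

with pi the prior probability that a SNP has a substantial effect.  Under
a BayesC-type architecture the variance a SNP is expected to explain is
proportional to its posterior probability, so the smoothed PP_j are used
directly as the diagonal weights of the weighted genomic relationship
matrix.  The alternative "top SNPs" weighting instead puts weight 1000 on
one genome-wide-significant SNP per association peak and 1 elsewhere.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .grm import SnpWeightVector
from .gwas import GwasScanResult

DEFAULT_PI = 0.001
TOPSNP_WEIGHT = 1000.0
SMOOTHING_WINDOWS = (1, 5, 11, 21, 41, 81, 161)


def smooth_lr(scan: GwasScanResult, s: int) -> np.ndarray:
    """Moving average of LR over a window of ``s`` SNPs centred on each SNP.

    Windows are truncated at chromosome boundaries: only same-chromosome
    neighbours enter and the divisor is the number of SNPs actually in the
    window, so a constant series is left unchanged and no signal leaks
    across chromosomes.  ``s`` must be odd; ``s = 1`` is the identity.
    """
    if s < 1 or s % 2 == 0:
        raise ValueError(f"window size must be an odd positive integer, got {s}")
    lr = scan.lr
    if s == 1:
        return lr.copy()
    half = s // 2
    out = np.empty_like(lr)
    chrom = scan.table["chrom"].to_numpy()
    start = 0
    for _, grp in pd.Series(chrom).groupby(chrom, sort=False):
        nc = len(grp)
        seg = lr[start:start + nc]
        csum = np.concatenate([[0.0], np.cumsum(seg)])
        idx = np.arange(nc)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half, nc - 1)
        out[start:start + nc] = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
        start += nc
    return out


def posterior_prob(smoothed_lr, pi: float = DEFAULT_PI) -> np.ndarray:
    """Posterior probability of a non-zero SNP effect given its (smoothed) LR.

    Computed as the numerically stable logistic 1 / (1 + exp(log((1-pi)/pi)
    - LR)); safe for LR up to at least 1e6.
    """
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must be in (0, 1), got {pi}")
    lr = np.asarray(smoothed_lr, dtype=float)
    out = expit(lr - np.log((1.0 - pi) / pi))
    return float(out) if out.ndim == 0 else out


def select_top_snps(
    scan: GwasScanResult,
    p_threshold: float = 1e-7,
    min_peak_gap_bp: int = 1_000_000,
) -> np.ndarray:
    """Indices of one top SNP per genome-wide-significant association peak.

    Significant SNPs (p < ``p_threshold``) on the same chromosome whose gaps
    are below ``min_peak_gap_bp`` are merged into one peak; the maximum-LR
    SNP of each peak is returned.  An empty selection is allowed.
    """
    t = scan.table
    sig = np.flatnonzero(t["p_value"].to_numpy() < p_threshold)
    if sig.size == 0:
        return np.array([], dtype=np.intp)
    chrom = t["chrom"].to_numpy()[sig]
    pos = t["pos"].to_numpy()[sig]
    lr = scan.lr[sig]
    new_peak = np.ones(sig.size, dtype=bool)
    new_peak[1:] = (chrom[1:] != chrom[:-1]) | (
        (pos[1:] - pos[:-1]) >= min_peak_gap_bp
    )
    peak_id = np.cumsum(new_peak) - 1
    tops = []
    for pk in range(peak_id[-1] + 1):
        members = np.flatnonzero(peak_id == pk)
        tops.append(sig[members[np.argmax(lr[members])]])
    return np.array(sorted(tops), dtype=np.intp)


def make_weights(
    mode: str,
    scan: GwasScanResult | None = None,
    *,
    n_snps: int | None = None,
    window: int = 5,
    pi: float = DEFAULT_PI,
    p_threshold: float = 1e-7,
    min_peak_gap_bp: int = 1_000_000,
    top_weight: float = TOPSNP_WEIGHT,
    custom: np.ndarray | None = None,
) -> SnpWeightVector:
    """Assemble the per-SNP weight vector for a prediction mode.

    ``uniform``: all 1.  ``topsnps``: ``top_weight`` on one SNP per
    significant peak, 1 elsewhere.  ``gwablup``: smoothed posterior
    probabilities.  ``custom``: a user-supplied nonnegative vector.
    """
    if mode == "uniform":
        if n_snps is None:
            n_snps = len(scan.table)
        return SnpWeightVector(np.ones(n_snps), source="uniform")
    if mode == "custom":
        if custom is None:
            raise ValueError("custom mode needs a weight vector")
        return SnpWeightVector(np.asarray(custom, dtype=float), source="custom")
    if scan is None:
        raise ValueError(f"mode {mode!r} needs a GWAS scan")
    if mode == "topsnps":
        vals = np.ones(len(scan.table))
        top = select_top_snps(scan, p_threshold, min_peak_gap_bp)
        vals[top] = top_weight
        return SnpWeightVector(vals, source="topsnps")
    if mode == "gwablup":
        pp = posterior_prob(smooth_lr(scan, window), pi)
        return SnpWeightVector(pp, source="gwablup")
    raise ValueError(f"unknown weight mode {mode!r}")


def weights_table(
    scan: GwasScanResult, window: int = 5, pi: float = DEFAULT_PI
) -> pd.DataFrame:
    """Full per-SNP table: LR, smoothed LR, PP and the resulting D_jj."""
    sm = smooth_lr(scan, window)
    pp = posterior_prob(sm, pi)
    return pd.DataFrame(
        {
            "snp_id": scan.table["snp_id"],
            "chrom": scan.table["chrom"],
            "pos": scan.table["pos"],
            "LR": scan.lr,
            "smoothed_LR": sm,
            "PP": pp,
            "D_jj": pp,
        }
    )


def write_weights(weights: SnpWeightVector, snps: pd.DataFrame,
                  path: str | Path) -> None:
    pd.DataFrame(
        {"snp_id": snps["snp_id"], "D_jj": weights.values}
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_weights(path: str | Path, snp_ids=None) -> SnpWeightVector:
    t = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    if snp_ids is not None:
        t = t.set_index("snp_id").reindex(snp_ids)
        if t["D_jj"].isna().any():
            raise ValueError("weights file does not cover all SNPs")
    return SnpWeightVector(t["D_jj"].to_numpy(dtype=float), source="custom")
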