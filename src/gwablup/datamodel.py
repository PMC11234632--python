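"""Core containers and per-cow / per-SNP statistics.

Phenotypes are yield deviations (YD): lactation records corrected for
systematic effects and averaged over a variable number of lactations per
cow.  Because the number of lactations ``n_i`` varies, YD precision varies
across cows; the reliability of a YD and the observation weight derived
from it are the two scalar statistics computed here, together with
quality-control filtering of SNPs and the weighted centering of genotype
codes that every downstream matrix computation relies on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for a missing call (int8 storage)

SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]


@dataclass(frozen=True)
class SnpInfo:
    """Map entry for a single biallelic SNP (1-based bp position)."""

    snp_id: str
    chrom: str
    pos: int
    allele_a: str = "A"
    allele_b: str = "B"


@dataclass
class GenotypeSet:
    """Sample x SNP genotype codes counting copies of ``allele_b``.

    ``codes`` is an int8 array with entries in {0, 1, 2, MISSING}.  The SNP
    map is a DataFrame with columns ``snp_id, chrom, pos, allele_a,
    allele_b``; within a chromosome SNPs are kept sorted by position (the
    moving-average smoothing of GWAS signals depends on this order).
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate snp ids")
        self._sort_by_position()

    def _sort_by_position(self) -> None:
        snps = self.snps.reset_index(drop=True)
        # stable sort within chromosomes, chromosome blocks keep file order
        chrom_rank = {c: i for i, c in enumerate(pd.unique(snps["chrom"]))}
        order = np.lexsort(
            (snps["pos"].to_numpy(), snps["chrom"].map(chrom_rank).to_numpy())
        )
        if not np.array_equal(order, np.arange(len(snps))):
            warnings.warn("SNPs reordered by (chromosome, position) on load")
            self.snps = snps.iloc[order].reset_index(drop=True)
            self.codes = self.codes[:, order]
        else:
            self.snps = snps

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.codes == MISSING).mean(axis=0)

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"sample id {e.args[0]!r} not in GenotypeSet") from None


@dataclass(frozen=True)
class VarianceComponents:
    """Single-trait variance components in squared trait units.

    Derived ratios are properties so they can never go stale:
    ``lambda_`` = residual/genetic, ``kappa`` = permanent-environment/genetic,
    ``alpha`` = residual/permanent-environment, ``h2`` = genetic/total.
    """

    sigma2_g: float
    sigma2_pe: float
    sigma2_e: float

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_pe", "sigma2_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def lambda_(self) -> float:
        return self.sigma2_e / self.sigma2_g

    @property
    def kappa(self) -> float:
        return self.sigma2_pe / self.sigma2_g

    @property
    def alpha(self) -> float:
        return self.sigma2_e / self.sigma2_pe

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_pe + self.sigma2_e)


@dataclass
class TraitObservations:
    """Per-cow yield deviations with record counts, birth years and roles.

    ``table`` columns: ``sample_id``, one column per trait, ``n_records``
    (lactations, >= 1), ``birth_year``, ``role`` in {train, validation}.
    Validation phenotypes are used for evaluation only, never for fitting.
    """

    table: pd.DataFrame
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"sample_id", "n_records", "birth_year", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
        if not self.trait_names:
            self.trait_names = [
                c for c in self.table.columns if c not in required
            ]
        if (self.table["n_records"] < 1).any():
            raise ValueError("n_records must be >= 1 for every animal")
        bad = set(self.table["role"]) - {"train", "validation"}
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def ids_for(self, role: str) -> list[str]:
        return self.table.loc[self.table["role"] == role, "sample_id"].tolist()

    def y(self, trait: str, role: str | None = None) -> np.ndarray:
        t = self.table if role is None else self.table[self.table["role"] == role]
        return t[trait].to_numpy(dtype=float)

    def check_against(self, genotypes: GenotypeSet) -> None:
        missing = set(self.sample_ids) - set(genotypes.sample_ids)
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped animals lack genotypes, "
                f"e.g. {sorted(missing)[:3]}"
            )


@dataclass
class ObservationWeights:
    """Per-cow observation weight w_i and YD reliability r2_i."""

    sample_id: list[str]
    w: np.ndarray
    r2: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.w, index=self.sample_id, name="w")


@dataclass
class CenteredGenotypes:
    """Centered genotype scores X_ij = M_ij - 2 p_j, missing imputed to 0.

    ``p`` is the training-set, observation-weighted frequency of allele_b,
    so the w-weighted training mean of every column of X is zero.
    """

    X: np.ndarray
    p: np.ndarray
    sample_ids: list[str]
    snps: pd.DataFrame
    weights_used: ObservationWeights | None = None
    training_ids: list[str] | None = None


# ---------------------------------------------------------------------------
# scalar statistics


def observation_weight(n, alpha: float):
    """Weight of a yield deviation averaged over ``n`` lactations.

    w = n (alpha + 1) / (alpha + n) with alpha = residual / permanent-
    environment variance.  w(1) = 1 and w increases to alpha + 1 as the
    number of lactations grows, reflecting the precision gained from
    repeated records while the permanent-environment effect is shared.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("number of lactations must be >= 1")
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    out = n * (alpha + 1.0) / (alpha + n)
    return float(out) if out.ndim == 0 else out


def yd_reliability(n, lambda_: float, kappa: float):
    """Reliability of a yield deviation averaged over ``n`` lactations.

    r2 = n / (n + lambda + n kappa); at n = 1 this equals the trait
    heritability, and it is bounded above by 1 / (1 + kappa).
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("number of lactations must be >= 1")
    if not (lambda_ > 0 and kappa > 0):
        raise ValueError("lambda and kappa must be > 0")
    out = n / (n + lambda_ + n * kappa)
    return float(out) if out.ndim == 0 else out


def compute_observation_weights(
    obs: TraitObservations, vc: VarianceComponents
) -> ObservationWeights:
    n = obs.table["n_records"].to_numpy(dtype=float)
    return ObservationWeights(
        sample_id=obs.sample_ids,
        w=observation_weight(n, vc.alpha),
        r2=yd_reliability(n, vc.lambda_, vc.kappa),
    )


# ---------------------------------------------------------------------------
# QC


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more probable
    than the observed one (cumulative-probability ordering, not mid-p).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("at least one genotyped sample required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    # log P(het = h) up to a shared constant; h has the parity of `rare`
    hets = np.arange(rare % 2, rare + 1, 2)
    lg = math.lgamma
    logp = np.array(
        [
            h * math.log(2.0)
            - lg((rare - h) // 2 + 1)
            - lg(h + 1)
            - lg((2 * n - rare - h) // 2 + 1)
            for h in hets
        ]
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_ab)]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def qc_filter(
    g: GenotypeSet,
    maf_min: float = 0.01,
    callrate_min: float = 0.9,
    hwe_p_min: float = 1e-7,
) -> tuple[GenotypeSet, dict[str, int]]:
    """SNP-level quality control.

    A SNP is kept iff MAF > ``maf_min`` (strict), call rate >= ``callrate_min``
    and HWE exact p > ``hwe_p_min``.  The sample set is unchanged.  Returns
    the filtered set and exclusion counts per filter (a SNP failing several
    filters is counted under each).
    """
    for name, v in [("maf_min", maf_min), ("callrate_min", callrate_min),
                    ("hwe_p_min", hwe_p_min)]:
        if not 0 < v < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    codes = g.codes
    observed = codes != MISSING
    n_obs = observed.sum(axis=0)
    callrate = n_obs / codes.shape[0]
    with np.errstate(invalid="ignore"):
        freq = np.where(
            n_obs > 0, np.where(observed, codes, 0).sum(axis=0) / (2.0 * n_obs), 0.0
        )
    maf = np.minimum(freq, 1.0 - freq)
    n_bb = np.logical_and(observed, codes == 2).sum(axis=0)
    n_ab = np.logical_and(observed, codes == 1).sum(axis=0)
    n_aa = n_obs - n_ab - n_bb
    hwe_p = np.array(
        [
            hwe_exact_test(int(a), int(h), int(b)) if (a + h + b) > 0 else 0.0
            for a, h, b in zip(n_aa, n_ab, n_bb)
        ]
    )
    fail_maf = ~(maf > maf_min)
    fail_call = ~(callrate >= callrate_min)
    fail_hwe = ~(hwe_p > hwe_p_min)
    keep = ~(fail_maf | fail_call | fail_hwe)
    counts = {
        "maf": int(fail_maf.sum()),
        "callrate": int(fail_call.sum()),
        "hwe": int(fail_hwe.sum()),
        "kept": int(keep.sum()),
    }
    if counts["kept"] == 0:
        raise ValueError("no SNPs survive QC")
    filtered = GenotypeSet(
        sample_ids=list(g.sample_ids),
        snps=g.snps.loc[keep].reset_index(drop=True),
        codes=g.codes[:, keep],
    )
    return filtered, counts


# ---------------------------------------------------------------------------
# weighted frequencies and centering


def weighted_allele_freq(
    g: GenotypeSet, weights: ObservationWeights, training_ids
) -> np.ndarray:
    """Observation-weighted allele_b frequency per SNP from training cows.

    p_j = sum_i w_i M_ij / (2 sum_i w_i) over non-missing training entries.
    """
    idx = g.sample_indices(training_ids)
    wmap = pd.Series(weights.w, index=weights.sample_id)
    w = wmap.reindex(training_ids).to_numpy(dtype=float)
    if np.isnan(w).any():
        raise ValueError("training ids missing from observation weights")
    codes = g.codes[idx]
    observed = codes != MISSING
    wsum = observed.T @ w  # per SNP, weights of non-missing entries
    if np.any(wsum <= 0):
        j = int(np.argmax(wsum <= 0))
        raise ValueError(
            f"SNP {g.snps['snp_id'].iloc[j]!r} has no observed training genotypes"
        )
    num = np.where(observed, codes, 0).T.astype(float) @ w
    return num / (2.0 * wsum)


def center_genotypes(
    g: GenotypeSet,
    p: np.ndarray,
    weights: ObservationWeights | None = None,
    training_ids=None,
) -> CenteredGenotypes:
    """X_ij = M_ij - 2 p_j; missing entries become 0 on the centered scale.

    Mean imputation on the centered scale keeps the weighted training mean
    of every column at zero, which is what makes the overall mean
    orthogonal to SNP effects in the association scan.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (g.n_snps,):
        raise ValueError(f"p has shape {p.shape}, expected ({g.n_snps},)")
    X = g.codes.astype(np.float64)
    miss = g.codes == MISSING
    X -= 2.0 * p
    X[miss] = 0.0
    return CenteredGenotypes(
        X=X,
        p=p,
        sample_ids=list(g.sample_ids),
        snps=g.snps,
        weights_used=weights,
        training_ids=list(training_ids) if training_ids is not None else None,
    )
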