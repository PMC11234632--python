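"""Synthetic dairy-cattle data with the structure the toolkit expects.

Genotypes come from a founder-haplotype mosaic: each chromosome has a
small pool of founder haplotypes (allele frequencies uniform on a
configurable band) and every gamete is a mosaic of pool members, switching
founders at a per-SNP rate that controls linkage disequilibrium.  This
reproduces the feature that matters for GWAS-weighted prediction - blocks
of correlated SNPs tagging shared QTL - without a generational pedigree.

Traits follow the repeated-lactation model: a true genetic value built
from a handful of major QTL plus a polygenic tail over all SNPs, a
permanent-environment effect shared across lactations, and independent
lactation residuals; the recorded phenotype is the yield deviation, the
mean over a cow-specific number of lactations.  True breeding values are
returned so simulations can score predictions against the truth as well
as against validation yield deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeSet, TraitObservations, VarianceComponents


@dataclass
class SimConfig:
    """Study-design parameters for one simulated dataset.

    Defaults give a training set of 2,000 cows plus 500 validation cows on
    10,000 SNPs over five chromosomes, a milk-like variance structure
    (h2 = 0.30, permanent-environment/genetic ratio 0.6), lactation counts
    uniform on 1..4, and five major QTL jointly explaining half of the
    genetic variance.
    """

    n_train: int = 2000
    n_validation: int = 500
    m: int = 10_000
    n_chrom: int = 5
    n_founder_haplotypes: int = 30
    switch_rate: float = 0.05  # founder-switch probability per SNP step
    freq_low: float = 0.05
    freq_high: float = 0.95
    snp_spacing_bp: int = 10_000
    n_qtl: int = 5
    qtl_variance_fraction: float = 0.5  # of genetic variance, 0 if n_qtl = 0
    qtl_observed: bool = False  # False: causal loci are not panel SNPs
    h2: float = 0.30
    pe_ratio: float = 0.6  # sigma2_pe / sigma2_g
    sigma2_g: float = 1.0
    lactations_min: int = 1
    lactations_max: int = 4
    trait_names: list[str] = field(default_factory=lambda: ["trait"])
    g_corr: np.ndarray | None = None  # trait x trait genetic correlations
    e_corr: np.ndarray | None = None  # environmental (PE + residual)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if self.m < self.n_qtl:
            raise ValueError("need at least as many SNPs as QTL")
        if not 0 <= self.qtl_variance_fraction <= 1:
            raise ValueError("qtl_variance_fraction must be in [0, 1]")
        if self.n_qtl == 0:
            self.qtl_variance_fraction = 0.0
        lam = 1.0 / self.h2 - 1.0 - self.pe_ratio
        if lam <= 0:
            raise ValueError(
                "h2 and pe_ratio imply a non-positive residual variance"
            )
        k = len(self.trait_names)
        if self.g_corr is None:
            self.g_corr = np.eye(k)
        if self.e_corr is None:
            self.e_corr = np.eye(k)
        self.g_corr = np.asarray(self.g_corr, dtype=float)
        self.e_corr = np.asarray(self.e_corr, dtype=float)

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_validation

    def variance_components(self) -> VarianceComponents:
        sg = self.sigma2_g
        return VarianceComponents(
            sigma2_g=sg,
            sigma2_pe=self.pe_ratio * sg,
            sigma2_e=(1.0 / self.h2 - 1.0 - self.pe_ratio) * sg,
        )


def simulate_genotypes(config: SimConfig, seed: int | None = None) -> GenotypeSet:
    """Founder-mosaic genotypes; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, k = config.n_total, config.n_founder_haplotypes
    per_chrom = np.full(config.n_chrom, config.m // config.n_chrom)
    per_chrom[: config.m % config.n_chrom] += 1
    blocks, snp_frames = [], []
    for c, mc in enumerate(per_chrom, start=1):
        p = rng.uniform(config.freq_low, config.freq_high, size=mc)
        pool = (rng.random((k, mc)) < p).astype(np.int8)
        hap = np.empty((2 * n, mc), dtype=np.int8)
        switch = rng.random((2 * n, mc)) < config.switch_rate
        switch[:, 0] = True
        founders = rng.integers(0, k, size=(2 * n, mc))
        cols = np.arange(mc)
        last_switch = np.maximum.accumulate(np.where(switch, cols, 0), axis=1)
        rows = np.arange(2 * n)[:, None]
        hap = pool[founders[rows, last_switch], cols[None, :]]
        blocks.append(hap[0::2] + hap[1::2])
        snp_frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"c{c}_s{j + 1}" for j in range(mc)],
                    "chrom": str(c),
                    "pos": (cols + 1) * config.snp_spacing_bp,
                    "allele_a": "A",
                    "allele_b": "B",
                }
            )
        )
    codes = np.concatenate(blocks, axis=1)
    sample_ids = [f"cow{i + 1:05d}" for i in range(n)]
    return GenotypeSet(
        sample_ids=sample_ids,
        snps=pd.concat(snp_frames, ignore_index=True),
        codes=codes,
    )


def _scaled(component: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale a zero-mean component to an exact population variance."""
    sd = component.std()
    if sd == 0:
        return component
    return component * (np.sqrt(target_var) / sd)


def simulate_phenotypes(
    g: GenotypeSet, config: SimConfig, seed: int | None = None
) -> tuple[TraitObservations, pd.DataFrame, dict]:
    """Yield deviations plus true breeding values for a genotype set.

    Returns (observations, truth, realized): ``truth`` has one ``g_<trait>``
    column per trait; ``realized`` reports the realized variance of each
    component against its target.  QTL and polygenic parts are rescaled to
    hit their target variances exactly at the population level, so the
    genetic architecture - not sampling noise in the effects - defines the
    study conditions.
    """
    rng = np.random.default_rng(
        (config.seed + 1_000_003) if seed is None else seed
    )
    vc = config.variance_components()
    n, m = g.n_samples, g.n_snps
    traits = config.trait_names
    k = len(traits)
    chol_g = np.linalg.cholesky(config.g_corr)
    chol_e = np.linalg.cholesky(config.e_corr)

    freq = g.codes.mean(axis=0) / 2.0
    X = g.codes.astype(float) - 2.0 * freq

    qtl_idx = np.array([], dtype=np.intp)
    gv = np.zeros((n, k))
    if config.n_qtl > 0:
        eligible = np.flatnonzero((freq > 0.15) & (freq < 0.85))
        chroms = g.snps["chrom"].to_numpy()
        picks = []
        for q in range(config.n_qtl):  # round-robin over chromosomes
            target = str(q % config.n_chrom + 1)
            cand = eligible[chroms[eligible] == target]
            cand = cand[~np.isin(cand, picks)]
            picks.append(int(rng.choice(cand)))
        qtl_idx = np.array(sorted(picks), dtype=np.intp)
        beta_q = rng.standard_normal((len(qtl_idx), k)) @ chol_g.T
        part = X[:, qtl_idx] @ beta_q
        part -= part.mean(axis=0)
        for t in range(k):
            gv[:, t] += _scaled(
                part[:, t], config.qtl_variance_fraction * vc.sigma2_g
            )
    poly_var = (1.0 - config.qtl_variance_fraction) * vc.sigma2_g
    if poly_var > 0:
        beta_p = rng.standard_normal((m, k)) @ chol_g.T
        beta_p[qtl_idx] = 0.0
        part = X @ beta_p
        part -= part.mean(axis=0)
        for t in range(k):
            gv[:, t] += _scaled(part[:, t], poly_var)

    # the QTL and polygenic parts covary through LD; rescale the total so
    # the realized genetic variance is exact
    for t in range(k):
        gv[:, t] = _scaled(gv[:, t] - gv[:, t].mean(), vc.sigma2_g)

    pe = (rng.standard_normal((n, k)) @ chol_e.T) * np.sqrt(vc.sigma2_pe)
    n_rec = rng.integers(config.lactations_min, config.lactations_max + 1, size=n)
    resid = (rng.standard_normal((n, k)) @ chol_e.T) * np.sqrt(
        vc.sigma2_e / n_rec[:, None]
    )
    yd = gv + pe + resid

    role = np.array(
        ["train"] * config.n_train + ["validation"] * config.n_validation
    )
    birth_year = np.where(
        role == "train",
        2010 + (np.arange(n) * 8) // max(config.n_train, 1) % 8,
        2018,
    )
    table = pd.DataFrame({"sample_id": g.sample_ids})
    for t, name in enumerate(traits):
        table[name] = yd[:, t]
    table["n_records"] = n_rec
    table["birth_year"] = birth_year
    table["role"] = role
    obs = TraitObservations(table=table, trait_names=list(traits))

    truth = pd.DataFrame({"sample_id": g.sample_ids})
    for t, name in enumerate(traits):
        truth[f"g_{name}"] = gv[:, t]
    qtl_snps = g.snps["snp_id"].to_numpy()[qtl_idx]

    realized = {
        "sigma2_g_target": vc.sigma2_g,
        "sigma2_g_realized": {nm: float(gv[:, t].var()) for t, nm in enumerate(traits)},
        "sigma2_pe_target": vc.sigma2_pe,
        "sigma2_pe_realized": {nm: float(pe[:, t].var()) for t, nm in enumerate(traits)},
        "sigma2_e_target": vc.sigma2_e,
        "qtl_snp_ids": list(qtl_snps),
        "qtl_indices": qtl_idx.tolist(),
        "qtl_pos": [
            (g.snps["chrom"].iloc[j], int(g.snps["pos"].iloc[j]))
            for j in qtl_idx
        ],
    }
    return obs, truth, realized


def simulate_dataset(
    config: SimConfig, seed: int | None = None
) -> tuple[GenotypeSet, TraitObservations, pd.DataFrame, dict]:
    """Genotypes and phenotypes for one study, honouring ``qtl_observed``.

    With ``qtl_observed = False`` (the default, emulating a SNP-chip panel
    that tags rather than contains the causal variants) the causal loci
    are simulated alongside the panel and removed from the returned
    genotypes: their signal reaches the analysis only through linkage
    disequilibrium with neighbouring panel SNPs.  ``realized`` then maps
    each causal locus to the panel index nearest its position.
    """
    hidden = config.n_qtl > 0 and not config.qtl_observed
    g = simulate_genotypes(config, seed)
    obs, truth, realized = simulate_phenotypes(
        g, config, None if seed is None else seed + 1_000_003
    )
    if not hidden:
        realized["qtl_panel_indices"] = realized["qtl_indices"]
        return g, obs, truth, realized
    qtl_idx = np.asarray(realized["qtl_indices"], dtype=np.intp)
    keep = np.setdiff1d(np.arange(g.n_snps), qtl_idx)
    panel = GenotypeSet(
        sample_ids=list(g.sample_ids),
        snps=g.snps.iloc[keep].reset_index(drop=True),
        codes=g.codes[:, keep],
    )
    nearest = []
    for chrom, pos in realized["qtl_pos"]:
        on_chrom = np.flatnonzero(panel.snps["chrom"].to_numpy() == chrom)
        d = np.abs(panel.snps["pos"].to_numpy()[on_chrom] - pos)
        nearest.append(int(on_chrom[np.argmin(d)]))
    realized["qtl_panel_indices"] = nearest
    return panel, obs, truth, realized
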