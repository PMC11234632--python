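import numpy as np
import pandas as pd
import pytest

from gwablup.datamodel import (
    GenotypeSet,
    center_genotypes,
    compute_observation_weights,
    weighted_allele_freq,
)
from gwablup.grm import build_grm
from gwablup.mixed_model import MixedModelSpec
from gwablup.simulate import SimConfig, simulate_genotypes, simulate_phenotypes


def make_genotypes(codes, chrom=None, pos=None, ids=None) -> GenotypeSet:
    """GenotypeSet from a raw code matrix with defaulted map/ids."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    ids = ids if ids is not None else [f"s{i}" for i in range(n)]
    return GenotypeSet(sample_ids=ids, snps=snps, codes=codes)


def hwe_genotypes(n, m, p=None, seed=0) -> GenotypeSet:
    """Independent Hardy-Weinberg genotypes (no LD), for expectation checks."""
    rng = np.random.default_rng(seed)
    if p is None:
        p = rng.uniform(0.1, 0.9, size=m)
    codes = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    return make_genotypes(codes)


@pytest.fixture(scope="session")
def sim_small():
    """Shared small simulated study: 300 train + 100 validation, 800 SNPs."""
    cfg = SimConfig(n_train=300, n_validation=100, m=800, n_chrom=4, seed=11)
    g = simulate_genotypes(cfg)
    obs, truth, realized = simulate_phenotypes(g, cfg)
    return {"config": cfg, "genotypes": g, "obs": obs, "truth": truth,
            "realized": realized}


@pytest.fixture(scope="session")
def sim_small_model(sim_small):
    """Centered genotypes, G_u and a ready MixedModelSpec for sim_small."""
    cfg, g, obs = (sim_small["config"], sim_small["genotypes"],
                   sim_small["obs"])
    vc = cfg.variance_components()
    w = compute_observation_weights(obs, vc)
    train = obs.ids_for("train")
    val = obs.ids_for("validation")
    p = weighted_allele_freq(g, w, train)
    X = center_genotypes(g, p, w, train)
    G_u = build_grm(X)
    y = obs.table.set_index("sample_id").loc[train, "trait"].to_numpy(float)
    w_train = w.as_series().reindex(train).to_numpy()
    spec = MixedModelSpec(G=G_u, y=y, train_ids=train, validation_ids=val,
                          R_diag=1.0 / w_train)
    return {"X": X, "G_u": G_u, "spec": spec, "y": y, "w_train": w_train,
            "train": train, "val": val, "vc": vc, "weights": w}
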