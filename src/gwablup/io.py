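"""Readers and writers for the on-disk formats the toolkit speaks.

Genotypes come either as a PLINK 1 binary triple (.bed/.bim/.fam,
SNP-major v1 layout) or as a plain dosage TSV; phenotypes as a TSV of
yield deviations with lactation counts, birth years and train/validation
roles; variance components as a small YAML mapping.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    MISSING,
    GenotypeSet,
    TraitObservations,
    VarianceComponents,
)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# two-bit PLINK codes -> copies of allele_b (bim allele 2); 0b01 is missing
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}


def _ext(prefix: str | os.PathLike, ext: str) -> Path:
    return Path(str(prefix) + ext)


def read_plink(prefix: str | Path) -> GenotypeSet:
    """Read a PLINK .bed/.bim/.fam triple into a :class:`GenotypeSet`."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        _ext(prefix, ".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        _ext(prefix, ".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele_a", "allele_b"],
        dtype={"chrom": str, "snp_id": str, "allele_a": str, "allele_b": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(_ext(prefix, ".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK v1)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise ValueError(
            f"{prefix}.bed: expected {bytes_per_snp * m} body bytes, "
            f"found {body.size} (truncated or wrong .fam/.bim?)"
        )
    body = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.int8)
    for k in range(4):
        codes[:, k::4] = _BED_DECODE[(body >> (2 * k)) & 0b11]
    codes = codes[:, :n].T  # -> samples x SNPs
    snps = bim[["snp_id", "chrom", "pos", "allele_a", "allele_b"]].copy()
    return GenotypeSet(sample_ids=fam["iid"].tolist(), snps=snps, codes=codes)


def write_plink(g: GenotypeSet, prefix: str | Path) -> None:
    """Write a :class:`GenotypeSet` as a PLINK .bed/.bim/.fam triple."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fam = pd.DataFrame(
        {
            "fid": g.sample_ids, "iid": g.sample_ids,
            "father": "0", "mother": "0", "sex": "0", "pheno": "-9",
        }
    )
    fam.to_csv(_ext(prefix, ".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": g.snps["chrom"], "snp_id": g.snps["snp_id"], "cm": 0,
            "pos": g.snps["pos"], "allele_a": g.snps["allele_a"],
            "allele_b": g.snps["allele_b"],
        }
    )
    bim.to_csv(_ext(prefix, ".bim"), sep="\t", header=False, index=False)

    n = g.n_samples
    pad = (-n) % 4
    enc = np.zeros(256, dtype=np.uint8)
    for code, bits in _BED_ENCODE.items():
        enc[code & 0xFF] = bits  # int8 MISSING (-1) lands at byte 255
    codes = g.codes.T  # SNP-major
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((codes.shape[0], pad), dtype=np.int8)], axis=1
        )
    two_bit = enc[codes.view(np.uint8)]
    packed = np.zeros((codes.shape[0], codes.shape[1] // 4), dtype=np.uint8)
    for k in range(4):
        packed |= two_bit[:, k::4] << (2 * k)
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_dosage_tsv(path: str | Path) -> GenotypeSet:
    """Read a samples x SNPs dosage TSV (header = snp ids, missing = NA).

    Positions/chromosomes are not part of this format; SNPs are placed on a
    single chromosome at consecutive positions.
    """
    t = pd.read_csv(path, sep="\t", dtype={0: str})
    snp_ids = list(t.columns[1:])
    codes = t.iloc[:, 1:].to_numpy(dtype=float)
    out = np.full(codes.shape, MISSING, dtype=np.int8)
    ok = ~np.isnan(codes)
    vals = codes[ok]
    if not np.isin(vals, [0, 1, 2]).all():
        raise ValueError("dosage TSV entries must be 0/1/2 or NA")
    out[ok] = vals.astype(np.int8)
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids, "chrom": "1",
            "pos": np.arange(1, len(snp_ids) + 1),
            "allele_a": "A", "allele_b": "B",
        }
    )
    return GenotypeSet(sample_ids=t.iloc[:, 0].tolist(), snps=snps, codes=out)


def write_dosage_tsv(g: GenotypeSet, path: str | Path) -> None:
    codes = g.codes.astype(object)
    t = pd.DataFrame(codes, columns=g.snps["snp_id"])
    t = t.mask(g.codes == MISSING, "NA")
    t.insert(0, "sample_id", g.sample_ids)
    t.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path, traits=None) -> TraitObservations:
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return TraitObservations(table=t, trait_names=list(traits) if traits else [])


def write_phenotypes(obs: TraitObservations, path: str | Path) -> None:
    obs.table.to_csv(path, sep="\t", index=False)


def read_variance_components(path: str | Path) -> dict[str, VarianceComponents]:
    """Read per-trait {genetic, permanent_environment, residual} from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for trait, comps in raw.items():
        out[trait] = VarianceComponents(
            sigma2_g=float(comps["genetic"]),
            sigma2_pe=float(comps["permanent_environment"]),
            sigma2_e=float(comps["residual"]),
        )
    return out


def write_variance_components(
    vcs: dict[str, VarianceComponents], path: str | Path
) -> None:
    raw = {
        trait: {
            "genetic": float(vc.sigma2_g),
            "permanent_environment": float(vc.sigma2_pe),
            "residual": float(vc.sigma2_e),
        }
        for trait, vc in vcs.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
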