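"""Weighted genomic relationship matrices.

The genomic relationship matrix over animals is the quadratic form

    G_D = X D X' / sum_j 2 p_j (1 - p_j) D_jj

with X the centered genotype scores, D a diagonal matrix of nonnegative
per-SNP weights and p_j the training-set weighted allele frequency.  With
all weights equal this is VanRaden's method-1 matrix G_u; differential
weights concentrate relationship information on SNPs believed to carry
trait variance.  Because both numerator and denominator are linear in D,
E(G_D) = E(G_u) whatever the weights: weighting redistributes, but does
not rescale, the expected relationships.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CenteredGenotypes


@dataclass
class SnpWeightVector:
    """Per-SNP diagonal weights D_jj with a provenance tag."""

    values: np.ndarray
    source: str = "uniform"  # uniform | topsnps | gwablup | cross-trait | custom

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("SNP weights must be nonnegative")
        if not np.any(self.values > 0):
            raise ValueError("at least one SNP weight must be positive")


@dataclass
class GRMatrix:
    """Symmetric sample x sample genomic relationship matrix."""

    ids: list[str]
    values: np.ndarray
    denominator: float
    weights_ref: SnpWeightVector | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM dimensions inconsistent with ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        if not self.denominator > 0:
            raise ValueError("GRM denominator must be > 0")

    def submatrix(self, rows, cols=None) -> np.ndarray:
        rows = np.asarray(rows, dtype=np.intp)
        cols = rows if cols is None else np.asarray(cols, dtype=np.intp)
        return self.values[np.ix_(rows, cols)]


def build_grm(X: CenteredGenotypes, D: SnpWeightVector | None = None) -> GRMatrix:
    """G_D = X D X' / sum_j 2 p_j (1 - p_j) D_jj over all genotyped animals."""
    m = X.X.shape[1]
    if D is None:
        D = SnpWeightVector(np.ones(m), source="uniform")
    if D.values.shape != (m,):
        raise ValueError(f"weight vector length {D.values.shape[0]} != {m} SNPs")
    den = float(np.sum(2.0 * X.p * (1.0 - X.p) * D.values))
    if not den > 0:
        raise ValueError(
            "zero GRM denominator: all positive weights sit on monomorphic SNPs"
        )
    active = D.values > 0  # skip zero-weight columns entirely
    Xs = X.X[:, active] * np.sqrt(D.values[active])
    G = (Xs @ Xs.T) / den
    G = 0.5 * (G + G.T)  # remove round-off asymmetry
    return GRMatrix(ids=list(X.sample_ids), values=G, denominator=den, weights_ref=D)


def grm_diagnostics(G: GRMatrix, eigenvalues: bool = False) -> dict[str, float]:
    """Summary of a GRM: mean self-relationship, implied inbreeding, range."""
    d = np.diag(G.values)
    off = G.values[~np.eye(len(G.ids), dtype=bool)]
    out = {
        "n": len(G.ids),
        "mean_diag": float(d.mean()),
        "mean_inbreeding": float(d.mean() - 1.0),
        "min_relationship": float(off.min()) if off.size else float("nan"),
        "max_relationship": float(off.max()) if off.size else float("nan"),
        "denominator": G.denominator,
    }
    if eigenvalues:
        out["min_eigenvalue"] = float(np.linalg.eigvalsh(G.values)[0])
    return out


# ---------------------------------------------------------------------------
# persistence: plain TSV and the GCTA binary triple


def write_grm(G: GRMatrix, prefix: str | Path, format: str = "tsv") -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        t = pd.DataFrame(G.values, index=G.ids, columns=G.ids)
        t.index.name = f"denominator={G.denominator!r}"
        t.to_csv(Path(str(prefix) + ".grm.tsv"), sep="\t", float_format="%.17g")
    elif format == "gcta":
        n = len(G.ids)
        tri = G.values[np.tril_indices(n)].astype("<f4")
        Path(str(prefix) + ".grm.bin").write_bytes(tri.tobytes())
        nbin = np.full(tri.shape, G.denominator, dtype="<f4")
        Path(str(prefix) + ".grm.N.bin").write_bytes(nbin.tobytes())
        with open(str(prefix) + ".grm.id", "w") as fh:
            for s in G.ids:
                fh.write(f"{s}\t{s}\n")
    else:
        raise ValueError(f"unknown GRM format {format!r}")


def read_grm(prefix: str | Path, format: str = "tsv") -> GRMatrix:
    prefix = Path(prefix)
    if format == "tsv":
        path = Path(str(prefix) + ".grm.tsv")
        t = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        den = 1.0
        if t.index.name and t.index.name.startswith("denominator="):
            den = float(t.index.name.split("=", 1)[1])
        return GRMatrix(
            ids=[str(c) for c in t.columns], values=t.to_numpy(dtype=float),
            denominator=den,
        )
    if format == "gcta":
        ids = [
            line.split()[1]
            for line in Path(str(prefix) + ".grm.id").read_text().splitlines()
            if line.strip()
        ]
        n = len(ids)
        raw = Path(str(prefix) + ".grm.bin").read_bytes()
        expected = n * (n + 1) // 2
        tri = np.frombuffer(raw, dtype="<f4")
        if tri.size != expected:
            raise ValueError(
                f"{prefix}.grm.bin holds {tri.size} values, "
                f"expected {expected} for {n} ids"
            )
        vals = np.zeros((n, n))
        vals[np.tril_indices(n)] = tri
        vals = vals + np.tril(vals, -1).T
        nraw = np.frombuffer(
            Path(str(prefix) + ".grm.N.bin").read_bytes(), dtype="<f4"
        )
        den = float(nraw[0]) if nraw.size else 1.0
        return GRMatrix(ids=ids, values=vals, denominator=den)
    raise ValueError(f"unknown GRM format {format!r}")
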