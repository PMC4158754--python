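"""Genomic similarity matrices (GSMs) for arbitrary SNP classes.

A GSM is the average allelic correlation between pairs of individuals,
``K = X X' / p`` on normalized genotypes.  GSMs built from disjoint SNP sets
combine additively with SNP-count weights, which is what lets a region and
its complement be split off from (or merged back into) the all-SNP matrix
without touching genotype data.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .genotype_io import NormalizedGenotypes

__all__ = [
    "Region",
    "Gsm",
    "EigenGsm",
    "compute_gsm",
    "combine_gsms",
    "complement_gsm",
    "eigendecompose",
    "kinship_summary",
    "save_gsm",
    "load_gsm",
]

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class Region:
    """A named SNP class; SNPs need not be contiguous."""

    name: str
    snp_ids: tuple[str, ...]

    def __init__(self, name: str, snp_ids) -> None:
        ids = tuple(snp_ids)
        if not ids:
            raise ValueError(f"region {name!r} is empty")
        if len(set(ids)) != len(ids):
            raise ValueError(f"region {name!r} has duplicate SNP IDs")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "snp_ids", ids)

    @property
    def size(self) -> int:
        return len(self.snp_ids)


@dataclass
class Gsm:
    """Materialized genomic similarity matrix with its SNP count."""

    matrix: np.ndarray
    snp_count: int
    source: str = "all"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GSM must be square")
        if self.snp_count <= 0:
            raise ValueError("snp_count must be positive")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GSM must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EigenGsm:
    """Spectral form K = U diag(values) U' with eigenvalues sorted descending."""

    vectors: np.ndarray
    values: np.ndarray
    snp_count: int
    source: str = "all"

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


def compute_gsm(x: NormalizedGenotypes, region: Region | str = "all") -> Gsm:
    """K = X_R X_R' / p_R over the region's SNP columns (or every SNP)."""
    if region == "all":
        block = x.matrix
        name = "all"
        p = x.p
    else:
        if region.size == 0:
            raise ValueError("empty region")
        block = x.columns(region.snp_ids)
        name = region.name
        p = region.size
    if p == 0:
        raise ValueError("cannot build a GSM from zero SNPs")
    k = block @ block.T / p
    k = (k + k.T) / 2.0
    return Gsm(matrix=k, snp_count=p, source=name)


def combine_gsms(parts: list[Gsm]) -> Gsm:
    """SNP-count-weighted average: (sum_m p_m K^m) / (sum_m p_m)."""
    if not parts:
        raise ValueError("no GSMs to combine")
    n = parts[0].n
    if any(part.n != n for part in parts):
        raise ValueError("GSMs have mismatched dimensions")
    total = sum(part.snp_count for part in parts)
    acc = np.zeros((n, n))
    for part in parts:
        acc += part.snp_count * part.matrix
    return Gsm(matrix=acc / total, snp_count=total,
               source="+".join(p.source for p in parts))


def complement_gsm(k_all: Gsm, k_region: Gsm) -> Gsm:
    """GSM of the SNPs in k_all but not in the region: unweighting identity."""
    if k_all.n != k_region.n:
        raise ValueError("GSMs have mismatched dimensions")
    p_diff = k_all.snp_count - k_region.snp_count
    if p_diff <= 0:
        raise ValueError(
            f"region has {k_region.snp_count} SNPs, not fewer than the full "
            f"set's {k_all.snp_count}"
        )
    mat = (k_all.snp_count * k_all.matrix - k_region.snp_count * k_region.matrix) / p_diff
    return Gsm(matrix=(mat + mat.T) / 2.0, snp_count=p_diff,
               source=f"complement({k_region.source})")


def eigendecompose(k: Gsm) -> EigenGsm:
    """Full symmetric eigendecomposition, eigenvalues descending.

    Eigenvalues in (-tol, 0) are clipped to zero (floating-point PSD repair,
    tol = 1e-8 relative to the leading eigenvalue); anything more negative is
    an error because GSMs of real genotype data are Gram matrices.
    """
    if not np.allclose(k.matrix, k.matrix.T, atol=1e-8):
        raise ValueError("matrix is not symmetric")
    values, vectors = np.linalg.eigh(k.matrix)
    order = np.argsort(values)[::-1]
    values = values[order]
    vectors = vectors[:, order]
    tol = 1e-8 * max(1.0, abs(values[0]))
    if values[-1] < -tol:
        raise ValueError(f"matrix has eigenvalue {values[-1]:.3e} below -{tol:.1e}")
    values = np.clip(values, 0.0, None)
    return EigenGsm(vectors=vectors, values=values,
                    snp_count=k.snp_count, source=k.source)


def kinship_summary(k: Gsm, lower_q: float = 0.025, upper_q: float = 0.975) -> tuple[float, float]:
    """Equal-tailed interval of the off-diagonal kinship coefficients.

    Linear interpolation between order statistics of the n(n-1)/2 upper
    triangle entries.
    """
    if k.n < 3:
        raise ValueError("need at least 3 individuals")
    off = k.matrix[np.triu_indices(k.n, k=1)]
    lo, hi = np.quantile(off, [lower_q, upper_q])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# On-disk cache: header (n, snp_count) then the lower triangle row-major
# as 8-byte little-endian reals.
# ---------------------------------------------------------------------------


def save_gsm(k: Gsm, path: str) -> None:
    n = k.n
    tri = k.matrix[np.tril_indices(n)]
    with open(path, "wb") as fh:
        fh.write(struct.pack("<qq", n, k.snp_count))
        fh.write(tri.astype("<f8").tobytes())


def load_gsm(path: str, source: str = "cached") -> Gsm:
    with open(path, "rb") as fh:
        n, snp_count = struct.unpack("<qq", fh.read(16))
        tri = np.frombuffer(fh.read(), dtype="<f8")
    if tri.size != n * (n + 1) // 2:
        raise ValueError(f"{path}: truncated GSM cache")
    mat = np.zeros((n, n))
    mat[np.tril_indices(n)] = tri
    mat = mat + np.tril(mat, -1).T
    return Gsm(matrix=mat, snp_count=int(snp_count), source=source)
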