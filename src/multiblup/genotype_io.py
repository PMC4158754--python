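"""PLINK 1 binary genotype I/O, SNP quality control, and phenotype preparation.

Genotypes are held as 0/1/2 counts of ``allele2`` with ``-1`` marking a
missing call.  Normalization centres each SNP by twice its allele frequency
and scales by the binomial standard deviation ``sqrt(2 f (1-f))``, so that a
genomic similarity matrix built from the normalized matrix is an average of
allelic correlations (the "standardized kinship" convention).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

__all__ = [
    "MISSING",
    "SnpRecord",
    "Sample",
    "GenotypeMatrix",
    "QcThresholds",
    "NormalizedGenotypes",
    "read_plink",
    "write_plink",
    "allele_frequencies",
    "hwe_exact_test",
    "apply_qc",
    "normalize",
    "residualize_phenotype",
    "read_phenotype_table",
]


@dataclass(frozen=True)
class SnpRecord:
    """Identity and map position of one SNP (one column of the call matrix)."""

    snp_id: str
    chromosome: int
    position_bp: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"SNP {self.snp_id}: position_bp must be >= 1")


@dataclass(frozen=True)
class Sample:
    family_id: str
    individual_id: str
    group: str | None = None


@dataclass
class GenotypeMatrix:
    """Raw genotype calls for n samples x p SNPs.

    ``calls[i, j]`` counts copies of ``snps[j].allele2`` carried by sample i,
    or ``MISSING`` (-1).
    """

    samples: list[Sample]
    snps: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP IDs")
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("calls must be in {0, 1, 2, -1}")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def p(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        sample_idx = np.arange(self.n) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.p) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in sample_idx],
            snps=[self.snps[j] for j in snp_idx],
            calls=self.calls[np.ix_(sample_idx, snp_idx)],
        )


@dataclass(frozen=True)
class QcThresholds:
    """SNP filters: minor allele frequency, call rate, Hardy-Weinberg p."""

    min_maf: float = 0.01
    min_call_rate: float = 0.995
    min_hwe_p: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in [0, 1]")
        if not 0 <= self.min_hwe_p <= 1:
            raise ValueError("min_hwe_p must be in [0, 1]")


@dataclass
class NormalizedGenotypes:
    """Centred and scaled genotypes; missing calls imputed to the column mean."""

    matrix: np.ndarray
    freqs: np.ndarray
    snp_ids: list[str]
    snps: list[SnpRecord] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def columns(self, snp_ids) -> np.ndarray:
        index = {s: j for j, s in enumerate(self.snp_ids)}
        try:
            idx = [index[s] for s in snp_ids]
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]} not present") from None
        return self.matrix[:, idx]


# ---------------------------------------------------------------------------
# PLINK 1 binary trio
# ---------------------------------------------------------------------------

# Two-bit genotype codes in a .bed byte, first sample in the low-order bits:
# 00 hom allele1 (0 copies of allele2), 01 missing, 10 het, 11 hom allele2.
_CODE_TO_CALL = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CALL_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam trio (SNP-major PLINK 1 layout)."""
    prefix = os.fspath(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(f"missing PLINK file: {prefix + ext}")

    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    samples = [Sample(row[0], row[1]) for row in fam.itertuples(index=False)]

    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None, dtype=str)
    snps = [
        SnpRecord(r[1], int(r[0]), int(r[3]), r[4], r[5])
        for r in bim.itertuples(index=False)
    ]

    n, p = len(samples), len(snps)
    with open(prefix + ".bed", "rb") as fh:
        header = fh.read(3)
        payload = fh.read()
    if header[:2] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes {header[:2]!r}")
    if len(header) < 3 or header[2] != _SNP_MAJOR:
        raise ValueError(f"{prefix}.bed: not in SNP-major layout")
    bytes_per_snp = (n + 3) // 4
    if len(payload) != bytes_per_snp * p:
        raise ValueError(
            f"{prefix}.bed: payload is {len(payload)} bytes, expected "
            f"{bytes_per_snp * p} for {n} samples x {p} SNPs"
        )

    raw = np.frombuffer(payload, dtype=np.uint8).reshape(p, bytes_per_snp)
    # unpack the four 2-bit codes of every byte
    codes = np.empty((p, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    calls = _CODE_TO_CALL[codes[:, :n]].T
    return GenotypeMatrix(samples=samples, snps=snps, calls=np.ascontiguousarray(calls))


def write_plink(g: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write a GenotypeMatrix as a .bed/.bim/.fam trio readable by read_plink."""
    if g.p == 0:
        raise ValueError("refusing to write a fileset with zero SNPs")
    if g.n == 0:
        raise ValueError("refusing to write a fileset with zero samples")
    prefix = os.fspath(prefix)

    with open(prefix + ".fam", "w") as fh:
        for s in g.samples:
            fh.write(f"{s.family_id} {s.individual_id} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for rec in g.snps:
            fh.write(
                f"{rec.chromosome} {rec.snp_id} 0 {rec.position_bp} "
                f"{rec.allele1} {rec.allele2}\n"
            )

    n = g.n
    bytes_per_snp = (n + 3) // 4
    code = np.zeros((g.p, bytes_per_snp * 4), dtype=np.uint8)
    call_codes = np.empty(g.calls.shape, dtype=np.uint8)
    for call, c in _CALL_TO_CODE.items():
        call_codes[g.calls == call] = c
    code[:, :n] = call_codes.T
    packed = np.zeros((g.p, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= code[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Frequencies, QC, normalization
# ---------------------------------------------------------------------------


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of allele2 among non-missing calls."""
    calls = g.calls
    observed = calls != MISSING
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        bad = [g.snps[j].snp_id for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"all calls missing for SNP(s): {', '.join(bad[:10])}")
    totals = np.where(observed, calls, 0).sum(axis=0)
    return totals / (2.0 * n_obs)


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the conditional probabilities of all configurations no
    more probable than the observed one (two-sided).
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def apply_qc(
    g: GenotypeMatrix, thr: QcThresholds
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove SNPs failing MAF, call-rate or HWE filters.

    All three filters are evaluated on the input matrix; a SNP may be
    reported with several failing filters.  Returns the filtered matrix and
    a removal report with one row per removed SNP.
    """
    calls = g.calls
    observed = calls != MISSING
    call_rate = observed.mean(axis=0)
    freqs = allele_frequencies(g)
    maf = np.minimum(freqs, 1.0 - freqs)

    rows = []
    keep = np.ones(g.p, dtype=bool)
    for j in range(g.p):
        reasons = []
        if maf[j] < thr.min_maf:
            reasons.append("maf")
        if call_rate[j] < thr.min_call_rate:
            reasons.append("call_rate")
        if thr.min_hwe_p > 0:
            col = calls[observed[:, j], j]
            p_hwe = hwe_exact_test(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
            if p_hwe < thr.min_hwe_p:
                reasons.append("hwe")
        if reasons:
            keep[j] = False
            rows.append(
                {
                    "snp_id": g.snps[j].snp_id,
                    "reasons": ";".join(reasons),
                    "maf": maf[j],
                    "call_rate": call_rate[j],
                }
            )
    report = pd.DataFrame(rows, columns=["snp_id", "reasons", "maf", "call_rate"])
    return g.subset(snp_idx=np.flatnonzero(keep)), report


def normalize(g: GenotypeMatrix) -> NormalizedGenotypes:
    """Centre by 2f and scale by sqrt(2f(1-f)); missing calls impute to 0.

    Every SNP must be polymorphic in the supplied sample (0 < f < 1);
    frequencies are always computed in-sample so that training-only
    normalization is leakage-free.
    """
    freqs = allele_frequencies(g)
    mono = (freqs <= 0.0) | (freqs >= 1.0)
    if mono.any():
        bad = [g.snps[j].snp_id for j in np.flatnonzero(mono)]
        raise ValueError(f"monomorphic SNP(s) cannot be normalized: {', '.join(bad[:10])}")
    x = g.calls.astype(np.float64)
    x[g.calls == MISSING] = np.nan
    centre = 2.0 * freqs
    scale = np.sqrt(2.0 * freqs * (1.0 - freqs))
    x = (x - centre) / scale
    x[np.isnan(x)] = 0.0
    return NormalizedGenotypes(matrix=x, freqs=freqs, snp_ids=g.snp_ids, snps=list(g.snps))


def residualize_phenotype(y: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
    """OLS residuals of y on an intercept plus optional covariate columns."""
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        design = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        design = np.column_stack([np.ones(n), covariates])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"covariate design is rank deficient (rank {rank} < {design.shape[1]} "
            "columns including intercept)"
        )
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coefs


def read_phenotype_table(path: str | os.PathLike) -> pd.DataFrame:
    """White-space-delimited table with header; first two columns FID IID."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected FID IID plus at least one value column")
    df = df.rename(columns={df.columns[0]: "FID", df.columns[1]: "IID"})
    df["FID"] = df["FID"].astype(str)
    df["IID"] = df["IID"].astype(str)
    return df
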