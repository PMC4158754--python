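"""Adaptive region discovery: window the genome, test each window's
effect-size variance, and merge significant windows into local regions.

The genome is tiled with overlapping windows (75 kb with a 37.5 kb step by
default).  Each window is tested for a variance contribution distinct from
the genomic background: either an exact REML likelihood-ratio test of a
two-GSM model (window + complement) against the single all-SNP GSM, or — when
individuals are predominantly unrelated — a fast spectral test of the window
variance against a noise-only model.  Windows with p below a seed threshold
(1e-6 by default, Bonferroni-motivated) grow outward, absorbing overlapping
or abutting neighbours below an extension threshold (1e-2); the grown
clusters become local regions and every remaining SNP falls into a single
background region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .genotype_io import GenotypeMatrix, NormalizedGenotypes, SnpRecord, normalize
from .kinship import Gsm, Region, combine_gsms, complement_gsm, compute_gsm, eigendecompose
from .reml import (
    GenotypeBlock,
    RemlFit,
    RemlOptions,
    VarianceModel,
    intercept_design,
    reml_fit,
    reml_fit_fast,
    restricted_loglik,
)

__all__ = [
    "Window",
    "WindowGrid",
    "RegionTest",
    "Partition",
    "AdaptiveOptions",
    "make_windows",
    "test_window_exact",
    "test_window_fast",
    "merge_windows",
    "relatedness_mode",
    "adaptive_multiblup",
]


@dataclass(frozen=True)
class Window:
    chromosome: int
    start_bp: int
    end_bp: int  # half-open [start, end)
    snp_indices: tuple[int, ...]


@dataclass
class WindowGrid:
    windows: list[Window]
    size_bp: int = 75_000
    step_bp: int = 37_500


@dataclass
class RegionTest:
    window_index: int
    l0: float
    l1: float
    statistic: float
    p_value: float
    converged: bool = True


@dataclass
class Partition:
    local_regions: list[Region]
    background: Region
    provenance: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        """Total region count including the background."""
        return len(self.local_regions) + 1


def make_windows(
    snps: list[SnpRecord], size_bp: int = 75_000, step_bp: int = 37_500
) -> WindowGrid:
    """Overlapping windows per chromosome; windows without SNPs are dropped."""
    if step_bp > size_bp:
        raise ValueError("step_bp must not exceed size_bp")
    if step_bp <= 0:
        raise ValueError("step_bp must be positive")
    order = [(s.chromosome, s.position_bp) for s in snps]
    if order != sorted(order):
        raise ValueError("SNPs must be sorted by (chromosome, position)")

    windows: list[Window] = []
    positions = np.array([s.position_bp for s in snps])
    chroms = np.array([s.chromosome for s in snps])
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        start = int(pos.min())
        last = int(pos.max())
        while start <= last:
            inside = idx[(pos >= start) & (pos < start + size_bp)]
            if inside.size:
                windows.append(
                    Window(int(chrom), start, start + size_bp, tuple(int(i) for i in inside))
                )
            start += step_bp
    return WindowGrid(windows=windows, size_bp=size_bp, step_bp=step_bp)


def test_window_exact(
    y: np.ndarray,
    fixed_design: np.ndarray,
    k_window: Gsm,
    k_complement: Gsm,
    window_index: int = 0,
    opts: RemlOptions = RemlOptions(loglik_tol=1e-6),
    null_fit: RemlFit | None = None,
) -> RegionTest:
    """LRT of distinct window variance via two nested REML fits.

    l0 maximizes the likelihood with the single all-SNP GSM (the SNP-count
    weighted combination of window and complement); l1 with the window GSM
    and its complement as separate components.  2(l1 - l0) is referred to
    chi-square(1), which is conservative because the window variance is
    constrained non-negative.  ``null_fit`` lets callers reuse the all-SNP
    fit, which is identical for every window.
    """
    model1 = VarianceModel([("window", k_window), ("complement", k_complement)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if null_fit is None:
            k_all = combine_gsms([k_window, k_complement])
            null_fit = reml_fit(y, fixed_design, VarianceModel([("all", k_all)]), opts)
        fit0 = null_fit
        fit1 = reml_fit(y, fixed_design, model1, opts)
    if not (fit0.converged and fit1.converged):
        warnings.warn(f"window {window_index}: REML non-convergence, p set to 1")
        return RegionTest(window_index, fit0.loglik, fit1.loglik, 0.0, 1.0, False)
    l0 = fit0.loglik
    # the 1-GSM optimum is a feasible point of the 2-GSM model (tied per-SNP
    # variances), so l1 can never legitimately fall below l0
    p_w, p_c = k_window.snp_count, k_complement.snp_count
    s2 = fit0.sigma2[0]
    tied = restricted_loglik(
        y, fixed_design, model1,
        [s2 * p_w / (p_w + p_c), s2 * p_c / (p_w + p_c)],
        fit0.sigma2_e,
    )
    l1 = max(fit1.loglik, tied)
    stat = max(0.0, 2.0 * (l1 - l0))
    return RegionTest(window_index, l0, l1, stat, float(chi2.sf(stat, 1)), True)


def _profile_loglik(lam: np.ndarray, u2: np.ndarray, rss_perp: float,
                    n_eff: int, rho: float) -> float:
    w = 1.0 + rho * lam
    if np.any(w <= 0):
        return -np.inf
    se2 = (np.sum(u2 / w) + rss_perp) / n_eff
    if se2 <= 0:
        return -np.inf
    return -0.5 * (np.sum(np.log(w)) + n_eff * np.log(se2) + n_eff)


def test_window_fast(
    y: np.ndarray,
    fixed_design: np.ndarray,
    x_window: np.ndarray | GenotypeBlock,
    window_index: int = 0,
) -> RegionTest:
    """Spectral LRT of window variance against a noise-only model.

    Valid as a screen when individuals are predominantly unrelated, so that
    the all-SNP GSM is close to the identity and the background term can be
    dropped.  Works in the eigenbasis of the window Gram matrix (cost
    O(n p_w^2), no n x n algebra).  The window variance is profiled over an
    UNCONSTRAINED range keeping V positive definite, so the statistic is
    asymptotically chi-square(1) and the p-values are calibrated rather than
    conservative.
    """
    xw = x_window.x if isinstance(x_window, GenotypeBlock) else np.asarray(x_window)
    if xw.ndim != 2 or xw.shape[1] == 0:
        raise ValueError("window genotype block must have at least one SNP column")
    y = np.asarray(y, dtype=np.float64).ravel()
    F = np.asarray(fixed_design, dtype=np.float64)
    if F.ndim == 1:
        F = F[:, None]
    n, p_m = xw.shape

    q, _ = np.linalg.qr(F)
    y_r = y - q @ (q.T @ y)
    x_r = xw - q @ (q.T @ xw)
    n_eff = n - F.shape[1]

    u_mat, sv, _ = np.linalg.svd(x_r, full_matrices=False)
    lam = sv**2 / p_m
    keep = lam > 1e-12 * max(lam[0], 1.0)
    lam = lam[keep]
    u2 = (u_mat[:, keep].T @ y_r) ** 2
    rss_perp = float(y_r @ y_r - u2.sum())

    se2_null = float(y_r @ y_r) / n_eff
    l0 = -0.5 * (n_eff * np.log(se2_null) + n_eff)
    if lam.size == 0:
        return RegionTest(window_index, l0, l0, 0.0, 1.0, True)

    lo = -1.0 / lam.max()
    # coarse bracket over signed variance ratios, then local refinement
    pos = 10.0 ** np.linspace(-5, 7, 49) / lam.mean()
    neg = lo * 0.999999 * 10.0 ** np.linspace(-8, 0, 25)
    cand = np.concatenate([neg, [0.0], pos])
    cand.sort()
    vals = np.array([_profile_loglik(lam, u2, rss_perp, n_eff, r) for r in cand])
    best = int(np.argmax(vals))
    lo_b = cand[best - 1] if best > 0 else lo * 0.999999
    hi_b = cand[best + 1] if best < cand.size - 1 else cand[-1] * 10
    res = minimize_scalar(
        lambda r: -_profile_loglik(lam, u2, rss_perp, n_eff, r),
        bounds=(lo_b, hi_b),
        method="bounded",
        options={"xatol": 1e-12 * max(1.0, abs(hi_b))},
    )
    l1 = max(float(-res.fun), float(vals[best]), l0)
    stat = max(0.0, 2.0 * (l1 - l0))
    return RegionTest(window_index, l0, l1, stat, float(chi2.sf(stat, 1)), True)


def merge_windows(
    tests: list[RegionTest],
    grid: WindowGrid,
    p_seed: float = 1e-6,
    p_extend: float = 1e-2,
    snp_ids: list[str] | None = None,
) -> Partition:
    """Grow seed windows (p < p_seed) through neighbours with p < p_extend.

    Neighbouring windows are those whose bp intervals overlap or abut on the
    same chromosome; growth propagates transitively, and grown clusters that
    touch are united, so local regions are exactly the connected components
    of sub-threshold windows that contain at least one seed.
    """
    if not (0 < p_seed < 1) or not (0 < p_extend < 1):
        raise ValueError("p thresholds must lie in (0, 1)")
    if len(tests) != len(grid.windows):
        raise ValueError("need exactly one test per window")

    p_by_window = {t.window_index: t.p_value for t in tests}
    if set(p_by_window) != set(range(len(grid.windows))):
        raise ValueError("tests do not cover every window exactly once")

    order = sorted(
        range(len(grid.windows)),
        key=lambda i: (grid.windows[i].chromosome, grid.windows[i].start_bp),
    )
    # connected components among windows below the extension threshold
    clusters: list[list[int]] = []
    current: list[int] = []
    prev = None
    for i in order:
        w = grid.windows[i]
        if p_by_window[i] >= p_extend:
            if current:
                clusters.append(current)
                current = []
            prev = None
            continue
        if (
            current
            and prev is not None
            and w.chromosome == prev.chromosome
            and w.start_bp <= prev.end_bp
        ):
            current.append(i)
        else:
            if current:
                clusters.append(current)
            current = [i]
        prev = w
    if current:
        clusters.append(current)

    seeded = [c for c in clusters if any(p_by_window[i] < p_seed for i in c)]

    n_snps = max((max(w.snp_indices) for w in grid.windows), default=-1) + 1
    all_idx = sorted({i for w in grid.windows for i in w.snp_indices})
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(n_snps)]

    assigned: set[int] = set()
    local_regions = []
    provenance: dict[str, list[int]] = {}
    for r, cluster in enumerate(seeded, start=1):
        members = sorted({j for i in cluster for j in grid.windows[i].snp_indices})
        members = [j for j in members if j not in assigned]
        if not members:
            continue
        assigned.update(members)
        name = f"region_{r}"
        local_regions.append(Region(name, [snp_ids[j] for j in members]))
        provenance[name] = list(cluster)
    background_idx = [j for j in all_idx if j not in assigned]
    if not background_idx:
        raise ValueError("every SNP fell into a local region; background is empty")
    background = Region("background", [snp_ids[j] for j in background_idx])
    return Partition(local_regions=local_regions, background=background,
                     provenance=provenance)


def relatedness_mode(k_all: Gsm, cutoff: float = 0.05) -> str:
    """'fast' when the 97.5% off-diagonal kinship quantile is below cutoff."""
    off = k_all.matrix[np.triu_indices(k_all.n, k=1)]
    return "fast" if float(np.quantile(off, 0.975)) < cutoff else "exact"


@dataclass(frozen=True)
class AdaptiveOptions:
    size_bp: int = 75_000
    step_bp: int = 37_500
    p_seed: float = 1e-6
    p_extend: float = 1e-2
    mode: str = "auto"  # auto | fast | exact
    relatedness_cutoff: float = 0.05
    reml: RemlOptions = RemlOptions()
    workers: int = 1


def window_tests(
    x: NormalizedGenotypes,
    y: np.ndarray,
    fixed_design: np.ndarray,
    grid: WindowGrid,
    mode: str,
    k_all: Gsm | None = None,
) -> list[RegionTest]:
    """Run the per-window variance test in the requested mode, serially."""
    tests = []
    null_fit = None
    if mode == "exact":
        if k_all is None:
            raise ValueError("exact mode needs the all-SNP GSM")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_fit = reml_fit(
                y, fixed_design, VarianceModel([("all", k_all)]),
                RemlOptions(loglik_tol=1e-6),
            )
    for i, w in enumerate(grid.windows):
        cols = x.matrix[:, list(w.snp_indices)]
        if mode == "fast":
            tests.append(test_window_fast(y, fixed_design, cols, window_index=i))
        else:
            k_w = Gsm(cols @ cols.T / cols.shape[1], cols.shape[1], f"window_{i}")
            k_c = complement_gsm(k_all, k_w)
            tests.append(
                test_window_exact(y, fixed_design, k_w, k_c, window_index=i,
                                  null_fit=null_fit)
            )
    return tests


def build_partition_model(
    x: NormalizedGenotypes, partition: Partition, k_all: Gsm | None = None
) -> tuple[VarianceModel, list[GenotypeBlock], Gsm]:
    """Variance model for a partition: local genotype blocks + background GSM.

    Returns the model (background first), the local blocks, and the
    background GSM.  The background GSM is recovered from the all-SNP GSM by
    the complement identity when k_all is supplied, avoiding an O(n^2 p)
    recomputation.
    """
    blocks = [
        GenotypeBlock(x.columns(r.snp_ids), list(r.snp_ids), r.name)
        for r in partition.local_regions
    ]
    if k_all is None:
        k_all = compute_gsm(x, "all")
    if blocks:
        k_locals = [b.to_gsm() for b in blocks]
        k_bg = complement_gsm(k_all, combine_gsms(k_locals))
    else:
        k_bg = k_all
    k_bg.source = "background"
    model = VarianceModel([("background", k_bg)] + [(b.name, b) for b in blocks])
    return model, blocks, k_bg


def adaptive_multiblup(
    g: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    options: AdaptiveOptions = AdaptiveOptions(),
):
    """Full adaptive pipeline on post-QC genotypes.

    Returns (partition, tests, fit, prediction_model).
    """
    from .predict import snp_effects_from_fit  # deferred: predict imports reml

    x = normalize(g)
    y = np.asarray(y, dtype=np.float64).ravel()
    F = intercept_design(x.n, covariates)
    grid = make_windows(g.snps, options.size_bp, options.step_bp)
    k_all = compute_gsm(x, "all")

    mode = options.mode
    if mode == "auto":
        mode = relatedness_mode(k_all, options.relatedness_cutoff)
    if mode not in ("fast", "exact"):
        raise ValueError(f"unknown mode {options.mode!r}")

    if options.workers > 1:
        from .cli import parallel_window_tests

        tests = parallel_window_tests(x, y, F, grid, mode, k_all, options.workers)
    else:
        tests = window_tests(x, y, F, grid, mode, k_all)

    partition = merge_windows(tests, grid, options.p_seed, options.p_extend,
                              snp_ids=x.snp_ids)
    model, blocks, k_bg = build_partition_model(x, partition, k_all)

    total_local = sum(b.p for b in blocks)
    if total_local < x.n:
        fit = reml_fit_fast(y, F, k_bg, blocks, options.reml)
    else:
        fit = reml_fit(y, F, model, options.reml)

    # SNP-level representation of every component (background included)
    effects_model = VarianceModel(
        [("background", GenotypeBlock(x.columns(partition.background.snp_ids),
                                      list(partition.background.snp_ids),
                                      "background"))]
        + [(b.name, b) for b in blocks]
    )
    pm = snp_effects_from_fit(fit, effects_model, x)
    return partition, tests, fit, pm
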