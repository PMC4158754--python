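"""Comparator predictors: genetic risk scores and forward stepwise regression.

Both work from single-SNP association statistics on the normalized genotype
scale.  The risk score keeps every SNP passing a p-value threshold with its
marginal effect estimate; stepwise regression adds the most conditionally
significant SNP until none passes the stopping threshold, then refits the
selected SNPs jointly by least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .genotype_io import NormalizedGenotypes
from .predict import PredictionModel, RegionEffects

__all__ = [
    "AssocTable",
    "marginal_assoc",
    "genetic_risk_score",
    "ld_prune",
    "stepwise_regression",
    "DEFAULT_GRS_THRESHOLDS",
]

# five thresholds, 1..5 on the -log10 scale
DEFAULT_GRS_THRESHOLDS = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5)


@dataclass
class AssocTable:
    table: pd.DataFrame  # columns: snp_id, beta, se, p_value

    def __post_init__(self) -> None:
        required = {"snp_id", "beta", "se", "p_value"}
        if not required <= set(self.table.columns):
            raise ValueError(f"association table needs columns {sorted(required)}")


def _project_out(y: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, int]:
    n = y.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        design = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        design = np.column_stack([np.ones(n), covariates])
    q, _ = np.linalg.qr(design)
    return y - q @ (q.T @ y), design.shape[1]


def marginal_assoc(
    x: NormalizedGenotypes, y: np.ndarray, covariates: np.ndarray | None = None
) -> AssocTable:
    """Per-SNP simple regression of y on each normalized SNP after projecting
    both onto the orthogonal complement of [intercept | covariates]."""
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.shape[0]
    y_r, c = _project_out(y, covariates)
    x_r, _ = _project_out(x.matrix, covariates)
    sxx = np.sum(x_r**2, axis=0)
    if (sxx <= 0).any():
        bad = [x.snp_ids[j] for j in np.flatnonzero(sxx <= 0)]
        raise ValueError(f"zero-variance SNP(s) after projection: {', '.join(bad[:10])}")
    beta = (x_r.T @ y_r) / sxx
    df = n - c - 1
    rss = np.sum(y_r**2) - beta**2 * sxx
    se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * t_dist.sf(np.abs(tval), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return AssocTable(
        pd.DataFrame({"snp_id": x.snp_ids, "beta": beta, "se": se, "p_value": p})
    )


def _model_from_effects(
    x: NormalizedGenotypes, snp_idx: np.ndarray, beta: np.ndarray,
    intercept: float, name: str
) -> PredictionModel:
    meta = {s.snp_id: s for s in x.snps}
    ids = [x.snp_ids[j] for j in snp_idx]
    f = x.freqs[snp_idx]
    region = RegionEffects(
        name=name,
        snp_ids=ids,
        allele1=[meta[s].allele1 for s in ids],
        allele2=[meta[s].allele2 for s in ids],
        centre=2.0 * f,
        scale=np.sqrt(2.0 * f * (1.0 - f)),
        beta=np.asarray(beta, dtype=np.float64),
    )
    return PredictionModel(fixed_coefs=np.array([intercept]), regions=[region])


def genetic_risk_score(
    assoc: AssocTable,
    x: NormalizedGenotypes,
    thresholds=DEFAULT_GRS_THRESHOLDS,
    intercept: float = 0.0,
) -> list[PredictionModel]:
    """One linear predictor per threshold: marginal betas of all SNPs with
    p below the threshold."""
    models = []
    tab = assoc.table
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
        mask = tab["p_value"].to_numpy() < t
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            warnings.warn(f"no SNP passes threshold {t}; intercept-only model")
        models.append(
            _model_from_effects(
                x, idx, tab["beta"].to_numpy()[idx], intercept, f"grs_p<{t:g}"
            )
        )
    return models


def ld_prune(x: NormalizedGenotypes, r2_max: float = 0.2, window: int = 50) -> list[str]:
    """Greedy left-to-right pruning: keep a SNP unless its squared correlation
    with any of the previous ``window`` kept SNPs exceeds r2_max."""
    if not 0 < r2_max < 1:
        raise ValueError("r2_max must lie in (0, 1)")
    n = x.n
    kept_cols: list[np.ndarray] = []
    kept_ids: list[str] = []
    for j in range(x.p):
        col = x.matrix[:, j]
        norm = np.linalg.norm(col)
        if norm == 0:
            continue
        ok = True
        for prev in kept_cols[-window:]:
            r = float(col @ prev) / (norm * np.linalg.norm(prev))
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept_cols.append(col)
            kept_ids.append(x.snp_ids[j])
    return kept_ids


def stepwise_regression(
    x: NormalizedGenotypes,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    p_stop: float = 1e-6,
) -> PredictionModel:
    """Forward selection on conditional significance.

    At each step the candidate with the smallest conditional p-value — the
    t-test of its coefficient in a joint refit with everything already
    selected — enters the model; selection stops once no candidate reaches
    ``p_stop``.  Conditional p-values are computed exactly via Gram-Schmidt
    residualization, which is algebraically the joint-refit t-test.  Final
    coefficients are a joint least-squares fit of the selected SNPs.
    """
    if not 0 < p_stop < 1:
        raise ValueError("p_stop must lie strictly inside (0, 1)")
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.shape[0]
    y_r, c = _project_out(y, covariates)
    x_r, _ = _project_out(x.matrix, covariates)
    x_work = x_r.copy()
    active = np.ones(x.p, dtype=bool)
    selected: list[int] = []

    while True:
        df = n - c - len(selected) - 1
        if df <= 1:
            break
        sxx = np.sum(x_work**2, axis=0)
        usable = active & (sxx > 1e-10 * n)
        if not usable.any():
            break
        idx = np.flatnonzero(usable)
        beta = (x_work[:, idx].T @ y_r) / sxx[idx]
        rss = float(y_r @ y_r) - beta**2 * sxx[idx]
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, np.abs(beta) / se, np.inf)
        p = 2.0 * t_dist.sf(tval, df)
        jbest = int(idx[np.argmin(p)])
        if p.min() >= p_stop:
            break
        selected.append(jbest)
        active[jbest] = False
        # orthogonalize remaining work columns and the response against the
        # chosen column
        u = x_work[:, jbest]
        unorm2 = float(u @ u)
        coef = (x_work.T @ u) / unorm2
        x_work -= np.outer(u, coef)
        x_work[:, jbest] = 0.0
        y_r = y_r - u * (float(u @ y_r) / unorm2)

    if not selected:
        return _model_from_effects(x, np.array([], dtype=int), np.array([]),
                                   float(np.mean(y)), "stepwise")

    sel = np.array(selected)
    design = np.column_stack([np.ones(n), x.matrix[:, sel]])
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
        design = np.column_stack([design, cov])
    coefs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("selected design rank-deficient; coefficients from lstsq")
    betas = coefs[1 : 1 + sel.size]
    return _model_from_effects(x, sel, betas, float(coefs[0]), "stepwise")
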