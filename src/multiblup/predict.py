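"""Turn REML fits into portable SNP-effect prediction models and evaluate them.

For a component held as a normalized genotype block, the BLUP effect sizes
are obtained by back-solving

    beta_m = (sigma2_m / p_m) X_m' V^-1 (y - F b),

which reproduces the component's fitted random effects on the training
samples (X_m beta_m = ghat_m) while letting new individuals be scored from
their genotypes alone.  Training-sample allele frequencies are frozen into
the model so that test genotypes are normalized without leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    NormalizedGenotypes,
    normalize,
    residualize_phenotype,
)
from .kinship import Gsm, Region, compute_gsm
from .reml import (
    GenotypeBlock,
    RemlFit,
    RemlOptions,
    VarianceModel,
    intercept_design,
    reml_fit,
    reml_fit_fast,
)

__all__ = [
    "RegionEffects",
    "PredictionModel",
    "Metrics",
    "snp_effects_from_fit",
    "predict_phenotype",
    "genetic_score",
    "predict_via_kinship",
    "evaluate",
    "grouped_kfold",
    "fit_prediction_model",
    "cross_validate",
]


@dataclass
class RegionEffects:
    """Normalized-scale effect sizes for the SNPs of one region."""

    name: str
    snp_ids: list[str]
    allele1: list[str]
    allele2: list[str]
    centre: np.ndarray  # 2 f_j, training frequencies
    scale: np.ndarray  # sqrt(2 f_j (1 - f_j))
    beta: np.ndarray


@dataclass
class PredictionModel:
    fixed_coefs: np.ndarray
    regions: list[RegionEffects]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for reg in self.regions:
            for j, sid in enumerate(reg.snp_ids):
                rows.append(
                    {
                        "SNP": sid,
                        "A1": reg.allele1[j],
                        "A2": reg.allele2[j],
                        "region": reg.name,
                        "centre": reg.centre[j],
                        "scale": reg.scale[j],
                        "beta_normalized": reg.beta[j],
                        "beta_per_allele": reg.beta[j] / reg.scale[j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class Metrics:
    correlation: float | None
    mse: float
    median_abs_error: float
    auc: float | None = None


def snp_effects_from_fit(
    fit: RemlFit,
    model: VarianceModel,
    x: NormalizedGenotypes,
    y: np.ndarray | None = None,
    fixed_design: np.ndarray | None = None,
) -> PredictionModel:
    """Back-solve per-SNP effects from a fit whose components are genotype
    blocks; ``x`` supplies the training normalization parameters."""
    if fit.py is None:
        raise ValueError("fit carries no P y vector; refit before extracting effects")
    meta = {s.snp_id: s for s in x.snps}
    freq = dict(zip(x.snp_ids, x.freqs))
    sigma_by_name = dict(zip(fit.component_names, fit.sigma2))
    regions = []
    for name, obj in model.components:
        if not isinstance(obj, GenotypeBlock):
            raise ValueError(
                f"component {name!r} has no SNP-level representation; "
                "use predict_via_kinship"
            )
        if name not in sigma_by_name:
            raise ValueError(f"component {name!r} not present in the fit")
        s2 = sigma_by_name[name]
        beta = (
            np.zeros(obj.p)
            if s2 == 0.0
            else (s2 / obj.p) * (obj.x.T @ fit.py)
        )
        f = np.array([freq[s] for s in obj.snp_ids])
        regions.append(
            RegionEffects(
                name=name,
                snp_ids=list(obj.snp_ids),
                allele1=[meta[s].allele1 for s in obj.snp_ids],
                allele2=[meta[s].allele2 for s in obj.snp_ids],
                centre=2.0 * f,
                scale=np.sqrt(2.0 * f * (1.0 - f)),
                beta=np.asarray(beta),
            )
        )
    return PredictionModel(fixed_coefs=np.asarray(fit.fixed_coefs), regions=regions)


def _normalized_test_calls(pm: PredictionModel, g_new: GenotypeMatrix):
    """Test genotypes on the training normalized scale, orientation-resolved."""
    index = {s.snp_id: j for j, s in enumerate(g_new.snps)}
    new_snps = {s.snp_id: s for s in g_new.snps}
    scores_parts = []
    for reg in pm.regions:
        missing_ids = [s for s in reg.snp_ids if s not in index]
        if missing_ids:
            raise KeyError(
                f"{len(missing_ids)} model SNP(s) absent from new data, e.g. "
                f"{', '.join(missing_ids[:10])}"
            )
        cols = np.array([index[s] for s in reg.snp_ids])
        calls = g_new.calls[:, cols].astype(np.float64)
        flip = np.zeros(len(cols), dtype=bool)
        for j, sid in enumerate(reg.snp_ids):
            rec = new_snps[sid]
            if (rec.allele1, rec.allele2) == (reg.allele1[j], reg.allele2[j]):
                continue
            if (rec.allele1, rec.allele2) == (reg.allele2[j], reg.allele1[j]):
                flip[j] = True
            else:
                raise ValueError(
                    f"allele mismatch at {sid}: model {reg.allele1[j]}/{reg.allele2[j]} "
                    f"vs data {rec.allele1}/{rec.allele2}"
                )
        miss = calls == MISSING
        calls[:, flip] = 2.0 - calls[:, flip]
        z = (calls - reg.centre) / reg.scale
        z[miss] = 0.0  # missing calls contribute nothing
        scores_parts.append(z @ reg.beta)
    return np.sum(scores_parts, axis=0)


def genetic_score(pm: PredictionModel, g_new: GenotypeMatrix) -> np.ndarray:
    """Sum of per-region genetic contributions (no fixed part)."""
    return _normalized_test_calls(pm, g_new)


def predict_phenotype(
    pm: PredictionModel,
    g_new: GenotypeMatrix,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Fixed part plus genetic score for each new individual."""
    fixed = pm.fixed_coefs
    design = intercept_design(g_new.n, covariates)
    if design.shape[1] != fixed.shape[0]:
        if covariates is None:
            design = np.ones((g_new.n, 1))
            fixed = fixed[:1]  # intercept only when covariates are unavailable
        else:
            raise ValueError(
                f"fixed design has {design.shape[1]} columns but the model "
                f"stores {fixed.shape[0]} coefficients"
            )
    return design @ fixed + genetic_score(pm, g_new)


def predict_via_kinship(
    fit: RemlFit,
    k_cross_blocks: dict[str, np.ndarray],
    k_train_blocks: dict[str, Gsm],
    fixed_design_new: np.ndarray | None = None,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Kinship-route prediction: ghat_T = K_TS (K_SS + ridge I)^-1 ghat_S.

    ``k_cross_blocks[name]`` is the n_test x n_train similarity block for a
    component, ``k_train_blocks[name]`` its training GSM.  The small ridge
    (relative to the mean diagonal) makes low-rank regional matrices
    invertible.
    """
    first = next(iter(k_cross_blocks.values()))
    n_test = first.shape[0]
    total = np.zeros(n_test)
    for name, k_ts in k_cross_blocks.items():
        ghat_s = fit.ghat[name]
        k_ss = k_train_blocks[name].matrix
        lam = ridge * float(np.mean(np.diag(k_ss)))
        a = k_ss + lam * np.eye(k_ss.shape[0])
        try:
            sol = np.linalg.solve(a, ghat_s)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"training GSM for {name!r} singular despite ridge"
            ) from exc
        total += k_ts @ sol
    if fixed_design_new is None:
        total += fit.fixed_coefs[0]
    else:
        total += np.asarray(fixed_design_new) @ fit.fixed_coefs
    return total


def evaluate(
    pred: np.ndarray, obs: np.ndarray, binary_labels: np.ndarray | None = None
) -> Metrics:
    """Pearson correlation, MSE, median absolute error, and optional AUC."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    obs = np.asarray(obs, dtype=np.float64).ravel()
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("pred and obs must have equal length >= 3")
    err = pred - obs
    mse = float(np.mean(err**2))
    medae = float(np.median(np.abs(err)))
    if np.std(pred) == 0 or np.std(obs) == 0:
        corr = None  # undefined, not zero
    else:
        corr = float(np.corrcoef(pred, obs)[0, 1])
    auc = None
    if binary_labels is not None:
        labels = np.asarray(binary_labels)
        if np.unique(labels).size == 2:
            auc = float(roc_auc_score(labels, pred))
    return Metrics(correlation=corr, mse=mse, median_abs_error=medae, auc=auc)


def grouped_kfold(
    n: int,
    groups: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Fold assignment keeping whole groups together.

    Groups are placed largest-first into the currently smallest fold, with
    ties among equal-size groups and equal-size folds broken by a seeded
    shuffle; without groups a seeded permutation is split into k near-equal
    folds.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if groups is None:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, k)):
            folds[chunk] = f
        return folds
    groups = np.asarray(groups)
    uniq, inverse = np.unique(groups, return_inverse=True)
    if k > uniq.size:
        raise ValueError(f"k={k} exceeds the number of groups ({uniq.size})")
    sizes = np.bincount(inverse)
    if (sizes >= 2 * n / k).any():
        warnings.warn("some groups are large relative to the fold size")
    order = rng.permutation(uniq.size)
    order = order[np.argsort(-sizes[order], kind="stable")]
    fold_sizes = np.zeros(k, dtype=int)
    for gi in order:
        f = int(np.argmin(fold_sizes))
        folds[inverse == gi] = f
        fold_sizes[f] += sizes[gi]
    return folds


# ---------------------------------------------------------------------------
# Method fitting shared by cross-validation and the simulation study
# ---------------------------------------------------------------------------


def _regions_to_model(x: NormalizedGenotypes, regions: list[Region]):
    """Blocks for every region; the largest becomes a materialized GSM when
    that permits the low-rank REML path."""
    blocks = [GenotypeBlock(x.columns(r.snp_ids), list(r.snp_ids), r.name) for r in regions]
    return blocks


def fit_prediction_model(
    g_train: GenotypeMatrix,
    y_train: np.ndarray,
    method: str = "blup",
    regions: list[Region] | None = None,
    reml_opts: RemlOptions = RemlOptions(),
    **params,
):
    """Fit one prediction method on training data; returns (PredictionModel, fit).

    ``blup`` is multi-component prediction with a single all-SNP region, so
    the two share one code path exactly.
    """
    from . import adaptive as _adaptive
    from . import baselines as _baselines

    x = normalize(g_train)
    y_train = np.asarray(y_train, dtype=np.float64).ravel()
    F = np.ones((x.n, 1))

    if method == "adaptive":
        opts = params.get("adaptive_options", _adaptive.AdaptiveOptions())
        _, _, fit, pm = _adaptive.adaptive_multiblup(g_train, y_train, options=opts)
        return pm, fit
    if method == "grs":
        assoc = _baselines.marginal_assoc(x, y_train)
        threshold = params.get("threshold", 1e-2)
        models = _baselines.genetic_risk_score(assoc, x, [threshold])
        return models[0], None
    if method == "stepwise":
        pm = _baselines.stepwise_regression(
            x, y_train, p_stop=params.get("p_stop", 1e-6)
        )
        return pm, None

    if method == "blup" or regions is None:
        regions = [Region("all", x.snp_ids)]
    elif method != "multiblup":
        raise ValueError(f"unknown method {method!r}")
    covered = {s for r in regions for s in r.snp_ids}
    rest = [s for s in x.snp_ids if s not in covered]
    if rest:
        regions = list(regions) + [Region("background", rest)]

    blocks = _regions_to_model(x, regions)
    sizes = [b.p for b in blocks]
    largest = int(np.argmax(sizes))
    rest_total = sum(sizes) - sizes[largest]
    if rest_total < x.n:
        fullrank = blocks[largest].to_gsm()
        other = [b for i, b in enumerate(blocks) if i != largest]
        fit = reml_fit_fast(y_train, F, fullrank, other, reml_opts)
    else:
        model = VarianceModel([(b.name, b) for b in blocks])
        fit = reml_fit(y_train, F, model, reml_opts)
    effects_model = VarianceModel([(b.name, b) for b in blocks])
    pm = snp_effects_from_fit(fit, effects_model, x)
    return pm, fit


def cross_validate(
    g: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    method: str = "blup",
    k: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
    regions: list[Region] | None = None,
    split_ratio: tuple[int, int] | None = None,
    binary: bool | None = None,
    **params,
) -> pd.DataFrame:
    """Grouped k-fold (or single train:test split) evaluation of one method.

    All training-derived quantities — covariate adjustment, allele
    frequencies, normalization, region discovery, REML and effect estimation
    — are recomputed inside every fold from training samples only.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = g.n
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}

    if split_ratio is not None:
        train_w, test_w = split_ratio
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_test = int(round(n * test_w / (train_w + test_w)))
        folds = np.zeros(n, dtype=int)
        folds[perm[:n_test]] = 1
        fold_ids = [1]
    else:
        folds = grouped_kfold(n, groups, k, seed)
        fold_ids = sorted(set(folds))

    rows = []
    for f in fold_ids:
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        g_tr, g_te = g.subset(train_idx), g.subset(test_idx)
        design_tr = intercept_design(train_idx.size,
                                     None if covariates is None else covariates[train_idx])
        design_te = intercept_design(test_idx.size,
                                     None if covariates is None else covariates[test_idx])
        coefs, *_ = np.linalg.lstsq(design_tr, y[train_idx], rcond=None)
        y_tr = y[train_idx] - design_tr @ coefs
        y_te = y[test_idx] - design_te @ coefs

        pm, _ = fit_prediction_model(g_tr, y_tr, method=method, regions=regions, **params)
        pred = predict_phenotype(pm, g_te)
        labels = y[test_idx] if binary else None
        m = evaluate(pred, y_te, binary_labels=labels)
        rows.append(
            {
                "fold": f,
                "n_test": test_idx.size,
                "correlation": m.correlation,
                "mse": m.mse,
                "median_abs_error": m.median_abs_error,
                "auc": m.auc,
            }
        )
    df = pd.DataFrame(rows)
    mean_row = df.drop(columns=["fold"]).mean(numeric_only=True)
    mean_row["fold"] = "mean"
    return pd.concat([df, mean_row.to_frame().T], ignore_index=True)
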