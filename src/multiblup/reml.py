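"""Multi-component variance estimation by average-information REML.

The model is ``y = F b + g_1 + ... + g_M + e`` with ``g_m ~ N(0, sigma2_m K_m)``
and ``e ~ N(0, sigma2_e I)``, where each ``K_m`` is a genomic similarity
matrix (materialized, or held implicitly as a normalized genotype block with
``K_m = X_m X_m' / p_m``).  Estimation maximizes the restricted log-likelihood

    l = -1/2 [ log|V| + log|F' V^-1 F| + y' P y ],
    V = sum_m sigma2_m K_m + sigma2_e I,
    P = V^-1 - V^-1 F (F' V^-1 F)^-1 F' V^-1,

(the additive constant ``-(n-c)/2 log 2pi`` is omitted throughout), using
Newton steps with the average-information matrix as approximate Hessian,
step-halving to keep the likelihood monotone, and a rule that permanently
zeroes any component whose variance share stays below 0.01% for two
consecutive iterations.

Two interchangeable back ends drive the same iteration: a dense path that
factorizes the n x n covariance directly, and a low-rank path that applies
the Woodbury identity when at most one component has full rank and the
remaining components hold fewer SNPs than there are individuals, so no
n x n matrix product is needed after a one-time eigendecomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .kinship import EigenGsm, Gsm, eigendecompose

__all__ = [
    "GenotypeBlock",
    "VarianceModel",
    "RemlOptions",
    "RemlFit",
    "restricted_loglik",
    "reml_fit",
    "reml_fit_fast",
    "heritability_shares",
]


@dataclass
class GenotypeBlock:
    """Implicit GSM: normalized genotype columns of one region, K = XX'/p."""

    x: np.ndarray
    snp_ids: list[str]
    name: str = "region"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.ndim != 2:
            raise ValueError("genotype block must be a 2-D array")
        if self.x.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids do not match block columns")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]

    def to_gsm(self) -> Gsm:
        k = self.x @ self.x.T / self.p
        return Gsm(matrix=(k + k.T) / 2.0, snp_count=self.p, source=self.name)


@dataclass
class VarianceModel:
    """Ordered genetic components; the noise term is always implicit."""

    components: list[tuple[str, Gsm | GenotypeBlock]]

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.components]

    @property
    def M(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class RemlOptions:
    max_iter: int = 100
    loglik_tol: float = 1e-4
    zero_share_threshold: float = 1e-4  # 0.01% of total variance
    zero_consecutive: int = 2
    constraint_floor: float = 0.0
    max_halvings: int = 30

    def __post_init__(self) -> None:
        if self.loglik_tol <= 0 or self.max_iter <= 0:
            raise ValueError("tolerances and iteration caps must be positive")


@dataclass
class RemlFit:
    sigma2: np.ndarray
    sigma2_e: float
    fixed_coefs: np.ndarray
    loglik: float
    converged: bool
    trace: list[tuple[np.ndarray, float, float]]
    ghat: dict[str, np.ndarray]
    zeroed: set[str]
    component_names: list[str]
    py: np.ndarray = field(repr=False, default=None)
    mean_diags: np.ndarray = field(repr=False, default=None)


def _component_matrix(obj: Gsm | GenotypeBlock) -> np.ndarray:
    if isinstance(obj, GenotypeBlock):
        return obj.to_gsm().matrix
    return obj.matrix


def _component_meandiag(obj: Gsm | GenotypeBlock) -> float:
    if isinstance(obj, GenotypeBlock):
        return float(np.sum(obj.x**2) / (obj.p * obj.n))
    return float(np.mean(np.diag(obj.matrix)))


# ---------------------------------------------------------------------------
# Engines.  An engine evaluates the restricted log-likelihood and (optionally)
# the gradient / average-information matrix at a parameter vector.  Parameter
# order: genetic components first, noise last.
# ---------------------------------------------------------------------------


class _State:
    __slots__ = ("loglik", "grad", "ai", "py", "beta")

    def __init__(self, loglik, grad=None, ai=None, py=None, beta=None):
        self.loglik = loglik
        self.grad = grad
        self.ai = ai
        self.py = py
        self.beta = beta


class _DenseEngine:
    """Direct n x n algebra; works for any set of components."""

    def __init__(self, y: np.ndarray, F: np.ndarray, k_list: list[np.ndarray]):
        self.y = y
        self.F = F
        self.k = k_list
        self.n = y.shape[0]
        self.eye = np.eye(self.n)

    def evaluate(self, sigma2: np.ndarray, sigma2_e: float, derivs: bool = True):
        n, F, y = self.n, self.F, self.y
        V = sigma2_e * self.eye.copy()
        for s2, K in zip(sigma2, self.k):
            if s2 != 0.0:
                V += s2 * K
        try:
            cho = cho_factor(V, lower=True, check_finite=False)
        except (LinAlgError, np.linalg.LinAlgError):
            return None
        logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
        vinv_f = cho_solve(cho, F, check_finite=False)
        m_f = F.T @ vinv_f
        try:
            mf_cho = cho_factor(m_f, lower=True, check_finite=False)
        except (LinAlgError, np.linalg.LinAlgError):
            return None
        logdet_mf = 2.0 * np.sum(np.log(np.diag(mf_cho[0])))
        vinv_y = cho_solve(cho, y, check_finite=False)
        beta = cho_solve(mf_cho, F.T @ vinv_y, check_finite=False)
        py = vinv_y - vinv_f @ beta
        ypy = float(y @ py)
        loglik = -0.5 * (logdet_v + logdet_mf + ypy)
        if not np.isfinite(loglik):
            return None
        if not derivs:
            return _State(loglik)

        vinv = cho_solve(cho, self.eye, check_finite=False)

        def p_mult(v):
            t = cho_solve(cho, v, check_finite=False)
            return t - vinv_f @ cho_solve(mf_cho, vinv_f.T @ v, check_finite=False)

        m_all = len(self.k) + 1
        traces = np.empty(m_all)
        vs = np.empty((self.n, m_all))
        for m, K in enumerate(self.k):
            tr1 = float(np.sum(vinv * K))
            b_m = vinv_f.T @ K @ vinv_f
            tr2 = float(np.trace(cho_solve(mf_cho, b_m, check_finite=False)))
            traces[m] = tr1 - tr2
            vs[:, m] = K @ py
        traces[-1] = float(np.trace(vinv)) - float(
            np.trace(cho_solve(mf_cho, vinv_f.T @ vinv_f, check_finite=False))
        )
        vs[:, -1] = py

        grad = -0.5 * (traces - py @ vs)
        ws = np.column_stack([p_mult(vs[:, m]) for m in range(m_all)])
        ai = 0.5 * (vs.T @ ws)
        ai = (ai + ai.T) / 2.0
        return _State(loglik, grad, ai, py, beta)


class _WoodburyEngine:
    """Low-rank path: at most one full-rank GSM (given spectrally) plus
    genotype blocks whose total SNP count is below n.

    Everything is rotated once into the eigenbasis of the full-rank GSM, in
    which A = sigma2_1 E + sigma2_e I is diagonal, and regional components
    enter through the p-dimensional capacitance matrix of the Woodbury
    identity.
    """

    def __init__(self, y, F, eig: EigenGsm | None, blocks: list[GenotypeBlock]):
        self.n = y.shape[0]
        self.has_full = eig is not None
        z_cols = [b.x / np.sqrt(b.p) for b in blocks]
        z = np.concatenate(z_cols, axis=1) if z_cols else np.zeros((self.n, 0))
        if self.has_full:
            self.e = eig.values
            self.u = eig.vectors
            self.y = self.u.T @ y
            self.F = self.u.T @ F
            self.z = self.u.T @ z if z.shape[1] else z
        else:
            self.e = None
            self.u = None
            self.y, self.F, self.z = y, F, z
            self.g0 = self.z.T @ self.z  # constant because A is then scalar
        self.block_slices = []
        start = 0
        for b in blocks:
            self.block_slices.append(slice(start, start + b.p))
            start += b.p
        self.q = start

    def evaluate(self, sigma2: np.ndarray, sigma2_e: float, derivs: bool = True):
        n, F, y, z = self.n, self.F, self.y, self.z
        if self.has_full:
            s2_full, s2_blocks = sigma2[0], np.asarray(sigma2[1:])
            a = s2_full * self.e + sigma2_e
            if np.any(a <= 0):
                return None
        else:
            s2_blocks = np.asarray(sigma2)
            if sigma2_e <= 0:
                return None
            a = np.full(n, sigma2_e)
        inv_a = 1.0 / a
        logdet_a = float(np.sum(np.log(a)))

        # active regional columns (zero-variance components drop out of V)
        d_per_block = s2_blocks
        active = [i for i, s2 in enumerate(d_per_block) if s2 > 0]
        act_cols = (
            np.concatenate([np.arange(self.q)[self.block_slices[i]] for i in active])
            if active
            else np.array([], dtype=int)
        )
        za = z[:, act_cols]
        d_act = np.concatenate(
            [np.full(self.block_slices[i].stop - self.block_slices[i].start, d_per_block[i]) for i in active]
        ) if active else np.array([])

        if act_cols.size:
            c_act = za.T @ (za * inv_a[:, None]) if self.has_full else self.g0[np.ix_(act_cols, act_cols)] / sigma2_e
            m_w = c_act + np.diag(1.0 / d_act)
            try:
                w_cho = cho_factor(m_w, lower=True, check_finite=False)
            except (LinAlgError, np.linalg.LinAlgError):
                return None
            logdet_v = logdet_a + float(np.sum(np.log(d_act))) + 2.0 * np.sum(
                np.log(np.diag(w_cho[0]))
            )

            def vinv_mult(v):
                t = za.T @ (v * inv_a if v.ndim == 1 else v * inv_a[:, None])
                s = cho_solve(w_cho, t, check_finite=False)
                return (v * inv_a if v.ndim == 1 else v * inv_a[:, None]) - (
                    (za @ s) * inv_a if v.ndim == 1 else (za @ s) * inv_a[:, None]
                )
        else:
            w_cho = None
            logdet_v = logdet_a

            def vinv_mult(v):
                return v * inv_a if v.ndim == 1 else v * inv_a[:, None]

        vinv_f = vinv_mult(F)
        m_f = F.T @ vinv_f
        try:
            mf_cho = cho_factor(m_f, lower=True, check_finite=False)
        except (LinAlgError, np.linalg.LinAlgError):
            return None
        logdet_mf = 2.0 * np.sum(np.log(np.diag(mf_cho[0])))
        vinv_y = vinv_mult(y)
        beta = cho_solve(mf_cho, F.T @ vinv_y, check_finite=False)
        py = vinv_y - vinv_f @ beta
        loglik = -0.5 * (logdet_v + logdet_mf + float(y @ py))
        if not np.isfinite(loglik):
            return None
        if not derivs:
            return _State(loglik)

        def p_mult(v):
            return vinv_mult(v) - vinv_f @ cho_solve(
                mf_cho, vinv_f.T @ v, check_finite=False
            )

        # tr(V^-1 K) for each component via the Woodbury expansion
        n_comp = len(sigma2) + 1
        traces = np.empty(n_comp)
        vs = np.empty((n, n_comp))

        if w_cho is not None:
            w_mat = cho_solve(w_cho, np.eye(d_act.size), check_finite=False)

        def tr_vinv_diag(dvals):
            # tr(V^-1 diag(dvals)) with diag in the working basis
            base = float(np.sum(dvals * inv_a))
            if w_cho is None:
                return base
            s_mat = za.T @ (za * (dvals * inv_a**2)[:, None])
            return base - float(np.sum(w_mat * s_mat))

        # full Z' V^-1 Z (needed for regional traces, including inactive ones)
        if self.q:
            c_all_a = z.T @ (z * inv_a[:, None]) if self.has_full else self.g0 / sigma2_e
            if w_cho is not None:
                c_cross = c_all_a[:, act_cols]
                t_zvz = c_all_a - c_cross @ w_mat @ c_cross.T
            else:
                t_zvz = c_all_a

        idx = 0
        if self.has_full:
            traces[0] = tr_vinv_diag(self.e) - float(
                np.trace(
                    cho_solve(
                        mf_cho, vinv_f.T @ (vinv_f * self.e[:, None]), check_finite=False
                    )
                )
            )
            vs[:, 0] = self.e * py
            idx = 1
        for i, sl in enumerate(self.block_slices):
            z_m = z[:, sl]
            zf = z_m.T @ vinv_f
            tr2 = float(
                np.trace(cho_solve(mf_cho, zf.T @ zf, check_finite=False))
            )
            traces[idx + i] = float(np.trace(t_zvz[sl, sl])) - tr2
            vs[:, idx + i] = z_m @ (z_m.T @ py)
        traces[-1] = tr_vinv_diag(np.ones(n)) - float(
            np.trace(cho_solve(mf_cho, vinv_f.T @ vinv_f, check_finite=False))
        )
        vs[:, -1] = py

        grad = -0.5 * (traces - py @ vs)
        ws = np.column_stack([p_mult(vs[:, m]) for m in range(n_comp)])
        ai = 0.5 * (vs.T @ ws)
        ai = (ai + ai.T) / 2.0
        return _State(loglik, grad, ai, py, beta)

    def to_original(self, v: np.ndarray) -> np.ndarray:
        return self.u @ v if self.has_full else v


# ---------------------------------------------------------------------------
# AI-REML driver (shared by both engines)
# ---------------------------------------------------------------------------


def _initial_theta(y: np.ndarray, mean_diags: np.ndarray) -> np.ndarray:
    """Symmetric start: genetic components split half the phenotypic variance
    equally (on the share scale), noise takes the other half."""
    var_y = float(np.var(y, ddof=1))
    m = mean_diags.size
    theta = np.empty(m + 1)
    if m:
        theta[:m] = 0.5 * var_y / (m * mean_diags)
    theta[-1] = 0.5 * var_y
    return theta


def _ai_reml(engine, names: list[str], mean_diags: np.ndarray, y: np.ndarray,
             opts: RemlOptions) -> tuple:
    m = len(names)
    theta = _initial_theta(y, mean_diags)
    noise_floor = max(1e-10 * theta[-1], 1e-300)
    state = engine.evaluate(theta[:m], theta[-1])
    if state is None:
        raise ValueError(f"initial covariance not positive definite at {theta}")

    zeroed = np.zeros(m, dtype=bool)
    below_count = np.zeros(m, dtype=int)
    trace = [(theta[:m].copy(), theta[-1], state.loglik)]
    converged = False

    for _ in range(opts.max_iter):
        prev_loglik = state.loglik
        free = np.append(~zeroed, True)  # noise always free
        g_free = state.grad[free]
        ai_free = state.ai[np.ix_(free, free)]
        delta_free = None
        try:
            delta_free = np.linalg.solve(ai_free, g_free)
            if not np.all(np.isfinite(delta_free)):
                delta_free = None
        except np.linalg.LinAlgError:
            delta_free = None
        if delta_free is None:
            # AI matrix singular: fall back to an EM step for this iteration
            delta_free, *_ = np.linalg.lstsq(ai_free, g_free, rcond=1e-10)
            if not np.all(np.isfinite(delta_free)):
                theta_free = theta[free]
                delta_free = (theta_free**2) * 2.0 * g_free / engine.n

        delta = np.zeros(m + 1)
        delta[free] = delta_free

        accepted = None
        factor = 1.0
        for _halving in range(opts.max_halvings):
            prop = theta + factor * delta
            prop[:m] = np.where(zeroed, 0.0, np.maximum(prop[:m], opts.constraint_floor))
            prop[-1] = max(prop[-1], noise_floor)
            st = engine.evaluate(prop[:m], prop[-1])
            if st is not None and st.loglik >= state.loglik - 1e-10:
                accepted = (prop, st)
                break
            factor /= 2.0
        if accepted is None:
            break  # cannot improve: treat as stalled at current estimates
        theta, state = accepted

        # permanent zeroing: share below threshold for consecutive iterations
        contrib = theta[:m] * mean_diags
        total = contrib.sum() + theta[-1]
        shares = contrib / total
        low = shares < opts.zero_share_threshold
        below_count = np.where(low, below_count + 1, 0)
        newly = (~zeroed) & (below_count >= opts.zero_consecutive)
        if newly.any():
            zeroed |= newly
            theta[:m][zeroed] = 0.0
            st = engine.evaluate(theta[:m], theta[-1])
            if st is not None:
                state = st

        trace.append((theta[:m].copy(), theta[-1], state.loglik))
        if abs(state.loglik - prev_loglik) < opts.loglik_tol:
            converged = True
            break

    return theta, state, trace, zeroed, converged


def _finalize(engine, model_objs, names, theta, state, trace, zeroed_mask,
              converged, mean_diags, original_basis=None) -> RemlFit:
    m = len(names)
    py = state.py
    if original_basis is not None:
        py = original_basis(py)
    ghat = {}
    for j, (name, obj) in enumerate(zip(names, model_objs)):
        s2 = theta[j]
        if s2 == 0.0:
            ghat[name] = np.zeros(engine.n)
        elif isinstance(obj, GenotypeBlock):
            ghat[name] = s2 / obj.p * (obj.x @ (obj.x.T @ py))
        elif isinstance(obj, EigenGsm):
            ghat[name] = s2 * (obj.vectors @ (obj.values * (obj.vectors.T @ py)))
        else:
            ghat[name] = s2 * (obj.matrix @ py)
    if not converged:
        warnings.warn("AI-REML did not converge within the iteration cap")
    return RemlFit(
        sigma2=theta[:m].copy(),
        sigma2_e=float(theta[-1]),
        fixed_coefs=np.asarray(state.beta).ravel(),
        loglik=float(state.loglik),
        converged=converged,
        trace=trace,
        ghat=ghat,
        zeroed={names[j] for j in range(m) if zeroed_mask[j]},
        component_names=list(names),
        py=py,
        mean_diags=mean_diags.copy(),
    )


def _check_inputs(y, fixed_design):
    y = np.asarray(y, dtype=np.float64).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype vector contains non-finite values")
    F = np.asarray(fixed_design, dtype=np.float64)
    if F.ndim == 1:
        F = F[:, None]
    if F.shape[0] != y.shape[0]:
        raise ValueError("fixed design and phenotype lengths differ")
    if y.shape[0] <= F.shape[1] + 1:
        raise ValueError("need more samples than fixed effects plus one")
    return y, F


def intercept_design(n: int, covariates: np.ndarray | None = None) -> np.ndarray:
    """Intercept column plus optional covariates."""
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return np.ones((n, 1))
    covariates = np.asarray(covariates, dtype=np.float64)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    return np.column_stack([np.ones(n), covariates])


def restricted_loglik(y, fixed_design, model: VarianceModel,
                      sigma2, sigma2_e: float) -> float:
    """Restricted log-likelihood at fixed variances (constant-free convention)."""
    y, F = _check_inputs(y, fixed_design)
    sigma2 = np.asarray(sigma2, dtype=np.float64)
    if sigma2.size != model.M:
        raise ValueError("sigma2 length does not match the number of components")
    engine = _DenseEngine(y, F, [_component_matrix(o) for _, o in model.components])
    state = engine.evaluate(sigma2, float(sigma2_e), derivs=False)
    if state is None:
        raise ValueError(
            f"covariance not positive definite at sigma2={sigma2}, "
            f"sigma2_e={sigma2_e}"
        )
    return float(state.loglik)


def reml_fit(y, fixed_design, model: VarianceModel,
             opts: RemlOptions = RemlOptions()) -> RemlFit:
    """AI-REML with dense covariance algebra (any component structure)."""
    y, F = _check_inputs(y, fixed_design)
    names = model.names
    objs = [o for _, o in model.components]
    k_list = [_component_matrix(o) for o in objs]
    mean_diags = np.array([float(np.mean(np.diag(K))) for K in k_list])
    engine = _DenseEngine(y, F, k_list)
    theta, state, trace, zeroed, converged = _ai_reml(engine, names, mean_diags, y, opts)
    return _finalize(engine, objs, names, theta, state, trace, zeroed,
                     converged, mean_diags)


def reml_fit_fast(y, fixed_design, fullrank: Gsm | EigenGsm | None,
                  regional_blocks: list[GenotypeBlock],
                  opts: RemlOptions = RemlOptions()) -> RemlFit:
    """AI-REML via the Woodbury identity / one-time eigendecomposition.

    Requires that the regional blocks together hold fewer SNPs than there
    are individuals; produces the same estimates as :func:`reml_fit`.
    """
    y, F = _check_inputs(y, fixed_design)
    n = y.shape[0]
    total_regional = sum(b.p for b in regional_blocks)
    if total_regional >= n:
        raise ValueError(
            f"regional blocks hold {total_regional} SNPs >= n={n}; "
            "use reml_fit for this model"
        )
    eig = None
    names = []
    objs: list = []
    if fullrank is not None:
        eig = fullrank if isinstance(fullrank, EigenGsm) else eigendecompose(fullrank)
        names.append(eig.source)
        objs.append(eig)
        mean_diag_full = [float(np.mean(eig.values))]
    else:
        mean_diag_full = []
    names += [b.name for b in regional_blocks]
    objs += list(regional_blocks)
    mean_diags = np.array(
        mean_diag_full + [_component_meandiag(b) for b in regional_blocks]
    )
    engine = _WoodburyEngine(y, F, eig, regional_blocks)
    theta, state, trace, zeroed, converged = _ai_reml(engine, names, mean_diags, y, opts)
    return _finalize(engine, objs, names, theta, state, trace, zeroed,
                     converged, mean_diags, original_basis=engine.to_original)


def heritability_shares(fit: RemlFit, model: VarianceModel | None = None) -> np.ndarray:
    """Per-component fraction of phenotypic variance, on the scale of each
    GSM's mean diagonal: sigma2_m * meandiag(K_m) / (sum + sigma2_e)."""
    contrib = fit.sigma2 * fit.mean_diags
    total = contrib.sum() + fit.sigma2_e
    return contrib / total
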