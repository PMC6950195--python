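"""Global models: OLS benchmark and a linear mixed model.

The mixed model treats the five pollutant coefficients plus intercept
as fixed effects and lets every city carry its own random deviation of
all six coefficients (diagonal variance-components G matrix), while the
within-city errors follow a first-order autoregressive process:

    y = Xβ + Zγ + ε,   Var(γ) = G = diag(σ1²…σ6²),
    Var(ε) = R = blockdiag over cities of σ²·[r^|i−j|].

Variance parameters are estimated by REML on the profiled −2 restricted
log-likelihood, optimized over (log σ1²…log σ6², artanh r, log σ²) by
quasi-Newton from several deterministic starts.  The marginal
covariance V = ZGZᵀ + R is block-diagonal per city, and each block is
handled with the AR(1) whitening transform plus a rank-6 Woodbury
update, so no T × T matrix is ever factorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .local_models import model_aicc


class ModelError(ValueError):
    pass


class SingularityError(ModelError):
    pass


class ConvergenceError(ModelError):
    pass


# ----------------------------------------------------------------------
# OLS


@dataclass
class GlobalFit:
    """OLS estimates with classical inference and fit statistics."""

    beta: np.ndarray
    se: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    standardized: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    ra2: float
    aicc: float
    rmse: float
    mae: float
    n: int
    p: int
    coef_labels: list[str] = field(default_factory=list)
    model: str = "OLS"
    data_fingerprint: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n": self.n,
            "p": self.p,
            "coefficients": {
                lab: {
                    "estimate": float(b),
                    "std_error": float(s),
                    "t": float(t),
                    "p_value": float(pv),
                    "standardized": float(st),
                }
                for lab, b, s, t, pv, st in zip(
                    self.coef_labels, self.beta, self.se, self.tvals, self.pvals, self.standardized
                )
            },
            "ra2": self.ra2,
            "aicc": self.aicc,
            "rmse": self.rmse,
            "mae": self.mae,
        }


def fit_ols(ds) -> GlobalFit:
    """Ordinary least squares β̂ = (XᵀX)⁻¹XᵀY with classical standard
    errors, t statistics, two-sided p-values (t, n − p df) and
    standardized estimates β̂_k·sd(X_k)/sd(Y)."""
    from .diagnostics import fit_metrics

    X = ds.design_matrix()
    y = ds.y
    n, p = X.shape
    if n <= p:
        raise ModelError(f"need n > p, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the dependent columns by checking each against the rest
        bad = []
        for j in range(1, p):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(ds.predictor_names[j - 1])
        raise SingularityError(f"design matrix is rank deficient; collinear: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=n - p)
    sd_y = float(np.std(y, ddof=1))
    standardized = np.zeros(p)
    standardized[1:] = beta[1:] * np.std(X[:, 1:], axis=0, ddof=1) / sd_y
    ra2, rmse, mae = fit_metrics(y, fitted, p)
    return GlobalFit(
        beta=beta,
        se=se,
        tvals=tvals,
        pvals=pvals,
        standardized=standardized,
        residuals=resid,
        fitted=fitted,
        ra2=ra2,
        aicc=model_aicc(rss, n, float(p)),
        rmse=rmse,
        mae=mae,
        n=n,
        p=p,
        coef_labels=["Intercept", *ds.predictor_names],
        data_fingerprint=ds.fingerprint(),
    )


# ----------------------------------------------------------------------
# AR(1) pieces


def ar1_covariance(r: float, sigma2: float, T: int) -> np.ndarray:
    """T × T AR(1) covariance with entries σ²·r^|i−j|."""
    if not abs(r) < 1:
        raise ModelError("|r| must be < 1")
    if sigma2 <= 0:
        raise ModelError("sigma2 must be > 0")
    idx = np.arange(T)
    return sigma2 * r ** np.abs(idx[:, None] - idx[None, :])


def _ar1_whiten(a: np.ndarray, r: float) -> np.ndarray:
    """Apply T with TCTᵀ = I for the unit-variance AR(1) correlation C.

    Row 1 is kept; row t becomes (a_t − r·a_{t−1})/sqrt(1 − r²).
    """
    out = np.empty_like(a, dtype=float)
    out[0] = a[0]
    c = 1.0 / np.sqrt(1.0 - r * r)
    out[1:] = (a[1:] - r * a[:-1]) * c
    return out


# ----------------------------------------------------------------------
# REML machinery


class _LmmWork:
    """Per-city blocks of the design, reused across objective calls."""

    def __init__(self, ds):
        X = ds.design_matrix()
        y = ds.y
        idx = ds.location_index()
        self.n, self.p = X.shape
        self.q = self.p  # random effects: intercept + the 5 slopes
        self.blocks = []
        for s in range(ds.n_locations):
            m = idx == s
            if m.sum() < 8:
                raise ModelError(
                    f"location index {s} has {int(m.sum())} records; need >= 8"
                )
            self.blocks.append((X[m], y[m]))
        self.X, self.y = X, y


def _unpack(theta: np.ndarray) -> tuple[np.ndarray, float, float]:
    theta = np.asarray(theta, float)
    g = np.exp(theta[:6])
    r = np.tanh(theta[6])
    s2 = np.exp(theta[7])
    return g, r, s2


def _profile(theta: np.ndarray, work: _LmmWork):
    """Profiled GLS quantities at one variance-parameter point.

    Returns (sum log|V_c|, XᵀV⁻¹X, XᵀV⁻¹y, yᵀV⁻¹y) using the whitened
    Woodbury representation of each city block.
    """
    g, r, s2 = _unpack(theta)
    L = np.sqrt(g)
    p = work.p
    logdet = 0.0
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    parts = []  # per-city (A, M cho, Xt, yt) for later BLUPs
    for Xc, yc in work.blocks:
        T = len(yc)
        Xt = _ar1_whiten(Xc, r) / np.sqrt(s2)
        yt = _ar1_whiten(yc, r) / np.sqrt(s2)
        A = Xt * L  # Z = X here: all six coefficients are random
        M = np.eye(work.q) + A.T @ A
        sign, ld_M = np.linalg.slogdet(M)
        if sign <= 0:
            raise FloatingPointError("non-PD Woodbury core")
        logdet += T * np.log(s2) + (T - 1) * np.log(1 - r * r) + ld_M
        Minv_AtXt = np.linalg.solve(M, A.T @ Xt)
        Minv_Atyt = np.linalg.solve(M, A.T @ yt)
        XtVX += Xt.T @ Xt - (A.T @ Xt).T @ Minv_AtXt
        XtVy += Xt.T @ yt - (A.T @ Xt).T @ Minv_Atyt
        ytVy += float(yt @ yt - (A.T @ yt) @ Minv_Atyt)
        parts.append((A, M, Xt, yt))
    return logdet, XtVX, XtVy, ytVy, parts


def reml_objective(theta, ds_or_work) -> float:
    """−2 × restricted log-likelihood of the variance parameters.

    ``theta`` packs (log σ1²…log σ6², artanh r, log σ²).  Returns +inf
    instead of raising when an intermediate quantity overflows, so the
    optimizer can simply step away.
    """
    work = ds_or_work if isinstance(ds_or_work, _LmmWork) else _LmmWork(ds_or_work)
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            logdet, XtVX, XtVy, ytVy, _ = _profile(np.asarray(theta, float), work)
            sign, ld_X = np.linalg.slogdet(XtVX)
            if sign <= 0:
                return np.inf
            beta = np.linalg.solve(XtVX, XtVy)
            quad = ytVy - float(beta @ XtVy)
            val = logdet + ld_X + quad + (work.n - work.p) * np.log(2 * np.pi)
    except (FloatingPointError, np.linalg.LinAlgError):
        return np.inf
    return float(val) if np.isfinite(val) else np.inf


def _penalized_objective(theta, work: _LmmWork) -> float:
    """Finite surrogate for the optimizer: replaces the +inf sentinel by
    a large smooth penalty so quasi-Newton line searches can recover."""
    val = reml_objective(theta, work)
    if not np.isfinite(val):
        return 1e25 * (1.0 + float(np.sum(np.square(theta))))
    return val


@dataclass
class LmmFit:
    """REML mixed-model fit: fixed effects, BLUPs and variance parts."""

    beta_fixed: np.ndarray
    se_fixed: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    var_components: np.ndarray  # σ1²..σ6²
    ar1_r: float
    resid_var: float
    gamma: np.ndarray  # S × 6 predicted random effects
    rc2: float
    aicc: float
    loglik_ml: float
    loglik_reml: float
    converged: bool
    n_iter: int
    fitted: np.ndarray
    residuals: np.ndarray
    rmse: float
    mae: float
    n: int
    p: int
    coef_labels: list[str] = field(default_factory=list)
    model: str = "LMM"
    data_fingerprint: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n": self.n,
            "p": self.p,
            "fixed_effects": {
                lab: {
                    "estimate": float(b),
                    "std_error": float(s),
                    "t": float(t),
                    "p_value": float(pv),
                }
                for lab, b, s, t, pv in zip(
                    self.coef_labels, self.beta_fixed, self.se_fixed, self.tvals, self.pvals
                )
            },
            "variance_components": {
                lab: float(v) for lab, v in zip(self.coef_labels, self.var_components)
            },
            "ar1_r": self.ar1_r,
            "resid_var": self.resid_var,
            "rc2": self.rc2,
            "aicc": self.aicc,
            "loglik_ml": self.loglik_ml,
            "loglik_reml": self.loglik_reml,
            "converged": self.converged,
            "rmse": self.rmse,
            "mae": self.mae,
        }


def _ols_start(work: _LmmWork) -> tuple[float, float]:
    """Residual variance and pooled within-city lag-1 autocorrelation of
    an OLS fit, used to seed the optimizer."""
    beta, *_ = np.linalg.lstsq(work.X, work.y, rcond=None)
    num = den = 0.0
    s2 = 0.0
    cnt = 0
    for Xc, yc in work.blocks:
        e = yc - Xc @ beta
        num += float(e[1:] @ e[:-1])
        den += float(e @ e)
        s2 += float(e @ e)
        cnt += len(e)
    r0 = np.clip(num / den if den > 0 else 0.0, -0.9, 0.9)
    return s2 / max(cnt - work.p, 1), float(r0)


def fit_lmm(ds, opts: dict | None = None) -> LmmFit:
    """Fit the mixed model by REML with deterministic multi-starts.

    The reported AICc is computed from the ML log-likelihood evaluated
    at the REML-optimal variance parameters, with parameter count
    p + 8 (six fixed slopes/intercept + six variance components + r +
    σ²); the REML criterion itself is exposed as ``loglik_reml``.
    """
    opts = opts or {}
    work = _LmmWork(ds)
    n, p = work.n, work.p
    s2_ols, r0 = _ols_start(work)
    # scale each random-effect variance start by the mean square of its
    # design column so every component contributes comparably
    ms = np.mean(work.X**2, axis=0)

    def start(frac_re: float, r: float, frac_resid: float) -> np.ndarray:
        lv = np.log(np.maximum(frac_re * s2_ols / ms, 1e-12))
        return np.concatenate([lv, [np.arctanh(r), np.log(frac_resid * s2_ols)]])

    starts = [
        start(0.05, r0, 0.9),
        start(1e-4, 0.0, 1.0),
        start(0.3, 0.3, 0.6),
    ][: opts.get("n_starts", 3)]
    bounds = [(-25.0, 25.0)] * 6 + [(-5.0, 5.0), (-25.0, 25.0)]
    maxiter = opts.get("maxiter", 200)

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _penalized_objective,
            x0,
            args=(work,),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError("no optimizer start produced a finite REML objective")

    theta = best.x
    g, r, s2 = _unpack(theta)
    logdet, XtVX, XtVy, ytVy, parts = _profile(theta, work)
    beta = np.linalg.solve(XtVX, XtVy)
    cov_beta = np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    df = max(ds.n_locations - 1, 1)
    pvals = 2 * stats.t.sf(np.abs(tvals), df=df)
    quad_beta = ytVy - float(beta @ XtVy)
    m2_reml = logdet + np.linalg.slogdet(XtVX)[1] + quad_beta + (n - p) * np.log(2 * np.pi)
    m2_ml = logdet + quad_beta + n * np.log(2 * np.pi)

    # BLUPs: γ̂_c = G Z_cᵀ V_c⁻¹ (y_c − X_c β̂)
    gamma = np.zeros((ds.n_locations, work.q))
    fitted = np.empty(n)
    pos = 0
    for s_idx, ((Xc, yc), (A, M, Xt, yt)) in enumerate(zip(work.blocks, parts)):
        rt = yt - Xt @ beta  # whitened residual of the fixed part
        ZtVinv_r = Xt.T @ rt - (A.T @ Xt).T @ np.linalg.solve(M, A.T @ rt)
        gamma[s_idx] = g * ZtVinv_r
        T = len(yc)
        fitted[pos : pos + T] = Xc @ (beta + gamma[s_idx])
        pos += T
    residuals = work.y - fitted

    k = p + 8
    aicc = m2_ml + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    grad_ok = bool(best.success) or float(np.max(np.abs(best.jac))) < 1e-2

    fit = LmmFit(
        beta_fixed=beta,
        se_fixed=se,
        tvals=tvals,
        pvals=pvals,
        var_components=g,
        ar1_r=float(r),
        resid_var=float(s2),
        gamma=gamma,
        rc2=np.nan,
        aicc=float(aicc),
        loglik_ml=-0.5 * m2_ml,
        loglik_reml=-0.5 * m2_reml,
        converged=grad_ok,
        n_iter=int(best.nit),
        fitted=fitted,
        residuals=residuals,
        rmse=float(np.sqrt(np.mean(residuals**2))),
        mae=float(np.mean(np.abs(residuals))),
        n=n,
        p=p,
        coef_labels=["Intercept", *ds.predictor_names],
        data_fingerprint=ds.fingerprint(),
    )
    fit.rc2 = conditional_r2(fit, ds)
    return fit


def city_models(fit: LmmFit) -> np.ndarray:
    """Per-city coefficient table: row s = β̂_fixed + γ̂_s (S × 6)."""
    if not fit.converged:
        raise ConvergenceError("mixed-model fit did not converge")
    return fit.beta_fixed + fit.gamma


def conditional_r2(fit: LmmFit, ds) -> float:
    """Proportion of variance explained by fixed plus random effects:

        Rc² = (σ_f² + σ_r²) / (σ_f² + σ_r² + σ_ε²)

    with σ_f² the variance of Xβ̂ over records, σ_r² the mean of
    z_iᵀĜz_i and σ_ε² the marginal residual variance.
    """
    X = ds.design_matrix()
    var_f = float(np.var(X @ fit.beta_fixed, ddof=1))
    var_r = float(np.mean((X**2) @ fit.var_components))
    var_e = float(fit.resid_var)
    total = var_f + var_r + var_e
    if total <= 0:
        raise ModelError("all variance components are zero; Rc2 undefined")
    return (var_f + var_r) / total
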