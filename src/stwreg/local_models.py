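"""Locally weighted least squares: GWR, TWR and GTWR in one engine.

At every focal record i a weighted regression

    β̂(u_i, v_i, t_i) = (XᵀW_i X)⁻¹ XᵀW_i y

is solved, with the diagonal weight matrix W_i built from spatial,
temporal or combined space-time kernel weights.  The focal diagonal of
the hat matrix is accumulated into tr(S), which serves as the effective
number of parameters for the corrected AIC and the adjusted R².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kernels import (
    KernelConfig,
    adaptive_bandwidth_from_d2,
    kernel_weight,
    select_bandwidth,
    squared_distances,
)

_COND_LIMIT = 1e10


class LocalModelError(ValueError):
    pass


class LocalSingularityError(LocalModelError):
    """The weighted normal matrix is singular or ill-conditioned."""


@dataclass
class LocalFit:
    """Result of a GWR/TWR/GTWR fit: one coefficient vector per record."""

    coef: np.ndarray  # n × p
    coef_names: list[str]
    fitted: np.ndarray
    residuals: np.ndarray
    trS: float
    aicc: float
    ra2: float
    rmse: float
    mae: float
    cfg: KernelConfig
    summary: pd.DataFrame = None
    model: str = "GTWR"
    data_fingerprint: str = ""
    n: int = 0
    p: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "mode": self.cfg.mode,
            "kernel": self.cfg.kernel,
            "k": self.cfg.k,
            "tau": self.cfg.tau,
            "n": self.n,
            "trS": self.trS,
            "aicc": self.aicc,
            "ra2": self.ra2,
            "rmse": self.rmse,
            "mae": self.mae,
            "coefficient_summary": None
            if self.summary is None
            else self.summary.to_dict(orient="index"),
        }


# ----------------------------------------------------------------------


def local_wls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    focal_row: np.ndarray,
    focal_weight: float = 1.0,
) -> tuple[np.ndarray, float]:
    """One local weighted least-squares solve.

    Returns the local coefficient vector and the focal diagonal element
    of the hat matrix, x_fᵀ(XᵀWX)⁻¹x_f·w_f.  Solved through a Cholesky
    factorization of the weighted normal matrix; an explicit inverse is
    never formed.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    p = X.shape[1]
    active = w > 0
    if active.sum() < p:
        raise LocalSingularityError(
            f"only {int(active.sum())} records have positive weight; need >= {p}"
        )
    Xa, ya, wa = X[active], y[active], w[active]
    A = (Xa * wa[:, None]).T @ Xa
    if np.linalg.cond(A) > _COND_LIMIT:
        raise LocalSingularityError(
            "ill-conditioned local normal matrix; increase the neighbour count k"
        )
    c = cho_factor(A)
    beta = cho_solve(c, Xa.T @ (wa * ya))
    hat = float(focal_row @ cho_solve(c, focal_row) * focal_weight)
    return beta, hat


def model_aicc(rss: float, n: int, trS: float) -> float:
    """Corrected AIC of a local smoother with effective parameters tr(S):

        AICc = 2n·ln σ̂ + n·ln 2π + n·(n + tr(S))/(n − 2 − tr(S)),

    σ̂ = sqrt(rss/n).  Undefined when n ≤ tr(S) + 2.
    """
    if n <= trS + 2:
        raise LocalModelError(f"AICc undefined: n={n} <= trS+2={trS + 2}")
    if rss == 0:  # perfect interpolation: the criterion diverges to −inf
        return float("-inf")
    sigma = np.sqrt(rss / n)
    return float(2 * n * np.log(sigma) + n * np.log(2 * np.pi) + n * (n + trS) / (n - 2 - trS))


def fit_stwr(ds, cfg: KernelConfig, p_eff_mode: str = "trS") -> LocalFit:
    """Fit a local model over every record of the panel.

    ``cfg.mode`` selects GWR (spatial), TWR (temporal) or GTWR
    (spatiotemporal); ``cfg.k = None`` triggers AICc bandwidth
    selection.  The adjusted R² uses tr(S) as the effective parameter
    count by default (``p_eff_mode="p"`` reverts to the raw count).
    """
    from .diagnostics import fit_metrics

    if cfg.k is None:
        k, tau, _ = select_bandwidth(ds, cfg)
        cfg = KernelConfig(mode=cfg.mode, kernel=cfg.kernel, k=k, tau=tau)
    X = ds.design_matrix()
    y = ds.y
    coords = ds.coords()
    times = ds.times()
    n, p = X.shape
    if cfg.k < p + 2 or cfg.k > n:
        raise LocalModelError(f"k={cfg.k} outside [{p + 2}, {n}]")
    lam, mu = cfg.scales()

    coef = np.empty((n, p))
    fitted = np.empty(n)
    trS = 0.0
    failures = []
    for i in range(n):
        d2 = squared_distances(coords, times, i, lam, mu)
        h = adaptive_bandwidth_from_d2(d2, cfg.k)
        w = kernel_weight(np.sqrt(d2), h, cfg.kernel)
        try:
            beta_i, hat_i = local_wls(X, y, w, X[i], w[i])
        except LocalSingularityError as exc:
            failures.append((i, str(exc)))
            continue
        coef[i] = beta_i
        fitted[i] = X[i] @ beta_i
        trS += hat_i
    if failures:
        raise LocalSingularityError(
            f"{len(failures)} local fits failed: records "
            + ", ".join(str(i) for i, _ in failures[:10])
        )

    residuals = y - fitted
    rss = float(residuals @ residuals)
    p_eff = trS if p_eff_mode == "trS" else float(p)
    if np.ptp(y) == 0:  # constant response: R2 undefined, errors still real
        ra2 = float("nan")
        rmse = float(np.sqrt(np.mean(residuals**2)))
        mae = float(np.mean(np.abs(residuals)))
    else:
        ra2, rmse, mae = fit_metrics(y, fitted, p_eff)
    names = ["Intercept", *ds.predictor_names]
    model = {"spatial": "GWR", "temporal": "TWR", "spatiotemporal": "GTWR"}[cfg.mode]
    fit = LocalFit(
        coef=coef,
        coef_names=names,
        fitted=fitted,
        residuals=residuals,
        trS=trS,
        aicc=model_aicc(rss, n, trS),
        ra2=ra2,
        rmse=rmse,
        mae=mae,
        cfg=cfg,
        model=model,
        data_fingerprint=ds.fingerprint(),
        n=n,
        p=p,
    )
    fit.summary = coefficient_summary(fit)
    return fit


def coefficient_summary(fit: LocalFit) -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max) of each local
    coefficient over the n records; quartiles by linear interpolation."""
    q = np.percentile(fit.coef, [0, 25, 50, 75, 100], axis=0, method="linear")
    return pd.DataFrame(
        q.T, index=fit.coef_names, columns=["min", "q1", "median", "q3", "max"]
    )
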