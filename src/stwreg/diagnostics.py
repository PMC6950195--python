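"""Residual diagnostics and cross-model comparison.

Includes the adjusted-R²/RMSE/MAE metric trio, residual Z scores,
Moran's I of model residuals under binary k-nearest-neighbour weights
(analytic randomization inference or permutation), Moran bandwidth
profiles, the pollutant correlation matrix, and the five-model
comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats


class DiagnosticsError(ValueError):
    pass


# ----------------------------------------------------------------------
# Scalar fit metrics


def fit_metrics(y, yhat, p_eff: float) -> tuple[float, float, float]:
    """(adjusted R², RMSE, MAE) of a fit with p_eff effective parameters.

    Ra² = 1 − (n−1)(1−R²)/(n−p_eff) with R² = 1 − RSS/SST; RMSE and MAE
    use the plain 1/n averages of squared / absolute residuals.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    n = len(y)
    if len(yhat) != n or n <= p_eff + 1:
        raise DiagnosticsError(f"need len(y)=len(yhat)=n > p_eff+1 (n={n}, p_eff={p_eff})")
    e = y - yhat
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise DiagnosticsError("response is constant; R2 undefined")
    r2 = 1.0 - float(e @ e) / sst
    ra2 = 1.0 - (n - 1) * (1.0 - r2) / (n - p_eff)
    rmse = float(np.sqrt(np.mean(e**2)))
    mae = float(np.mean(np.abs(e)))
    return ra2, rmse, mae


def z_scores(y, yhat) -> np.ndarray:
    """Residuals standardized by the sample sd of the fitted values:
    Z_i = (y_i − ŷ_i)/std(ŷ)."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    s = float(np.std(yhat, ddof=1))
    if s == 0:
        raise DiagnosticsError("fitted values are constant; Z scores undefined")
    return (y - yhat) / s


# ----------------------------------------------------------------------
# Moran's I


@dataclass
class KnnWeights:
    """Binary k-nearest-neighbour record weights (not symmetrized, not
    row-standardized).  ``indices[i]`` lists the k nearest records to i
    by spatial distance, self excluded, ties at the k-th distance broken
    by the dataset's (location_id, t) record order."""

    indices: np.ndarray  # n × k
    n: int
    k: int

    @property
    def total(self) -> float:
        """W = Σ_ij w_ij = n·k."""
        return float(self.n * self.k)

    def to_sparse(self) -> sparse.csr_matrix:
        rows = np.repeat(np.arange(self.n), self.k)
        return sparse.csr_matrix(
            (np.ones(self.n * self.k), (rows, self.indices.ravel())),
            shape=(self.n, self.n),
        )


def knn_binary_weights(ds, k: int) -> KnnWeights:
    """k-nearest-neighbour weights on the record spatial coordinates.

    With only a handful of distinct city sites many records are exactly
    coincident; the deterministic tie order makes the neighbour sets
    reproducible regardless.
    """
    coords = ds.coords()
    n = len(coords)
    if not 0 < k < n:
        raise DiagnosticsError(f"need 0 < k < n, got k={k}, n={n}")
    indices = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        d2 = np.sum((coords - coords[i]) ** 2, axis=1)
        d2[i] = np.inf  # self excluded
        order = np.argsort(d2, kind="stable")  # stable => record-order tie-break
        indices[i] = order[:k]
    return KnnWeights(indices=indices, n=n, k=k)


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_two_tailed: float
    k: int
    method: str


def _moran_stat(z: np.ndarray, w: KnnWeights) -> float:
    num = float(np.sum(z * np.sum(z[w.indices], axis=1)))
    den = float(z @ z)
    return (w.n / w.total) * num / den


def morans_i(
    e: np.ndarray,
    weights: KnnWeights,
    method: str = "analytic",
    n_perm: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Moran's I of residuals e under binary k-NN weights.

        I = (n/W)·ΣΣ w_ij (e_i−ē)(e_j−ē) / Σ(e_i−ē)²,  E(I) = −1/(n−1).

    ``method="analytic"`` uses the randomization (fourth-moment)
    variance with a two-tailed normal p-value; ``method="permutation"``
    shuffles the residuals ``n_perm`` times and reports a two-tailed
    empirical p-value.
    """
    e = np.asarray(e, float)
    n = len(e)
    z = e - e.mean()
    if float(z @ z) == 0:
        raise DiagnosticsError("residuals are constant; Moran's I undefined")
    I = _moran_stat(z, weights)
    expected = -1.0 / (n - 1)

    if method == "analytic" and n < 4:
        # fourth-moment randomization variance needs n >= 4
        return MoranResult(
            I=float(I), expected=expected, variance=float("nan"), z=float("nan"),
            p_two_tailed=float("nan"), k=weights.k, method=method,
        )
    if method == "analytic":
        W = weights.total
        Wmat = weights.to_sparse()
        mutual = float(Wmat.multiply(Wmat.T).sum())
        S1 = W + mutual  # ½ΣΣ(w_ij+w_ji)² for binary weights
        row = np.asarray(Wmat.sum(axis=1)).ravel()
        col = np.asarray(Wmat.sum(axis=0)).ravel()
        S2 = float(np.sum((row + col) ** 2))
        m2 = float(np.mean(z**2))
        b2 = float(np.mean(z**4)) / m2**2
        num = n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * W * W) - b2 * (
            (n * n - n) * S1 - 2 * n * S2 + 6 * W * W
        )
        den = (n - 1) * (n - 2) * (n - 3) * W * W
        variance = num / den - expected**2
        if variance > 0:
            zscore = (I - expected) / np.sqrt(variance)
            p = 2 * stats.norm.sf(abs(zscore))
        else:  # e.g. the complete graph, where I is deterministic
            zscore, p = float("nan"), float("nan")
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        sims = np.empty(n_perm)
        for b in range(n_perm):
            sims[b] = _moran_stat(z[rng.permutation(n)], weights)
        variance = float(np.var(sims, ddof=1))
        zscore = (I - expected) / np.sqrt(variance) if variance > 0 else np.nan
        ge = int(np.sum(sims >= I))
        le = int(np.sum(sims <= I))
        p = min(1.0, 2.0 * (1 + min(ge, le)) / (n_perm + 1))
    else:
        raise DiagnosticsError(f"unknown method {method!r}")
    return MoranResult(
        I=float(I),
        expected=expected,
        variance=float(variance),
        z=float(zscore),
        p_two_tailed=float(p),
        k=weights.k,
        method=method,
    )


def moran_curve(e, ds, k_grid, method: str = "analytic", n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Moran's I of residuals across a grid of neighbour counts.

    Supports the diagnostic that residual autocorrelation decays toward
    the null expectation as the neighbourhood widens.
    """
    k_grid = list(k_grid)
    if any(b <= a for a, b in zip(k_grid, k_grid[1:])):
        raise DiagnosticsError("k_grid must be strictly increasing")
    rows = []
    for k in k_grid:
        w = knn_binary_weights(ds, int(k))
        res = morans_i(e, w, method=method, n_perm=n_perm, seed=seed)
        rows.append({"k": int(k), "I": res.I, "z": res.z, "p": res.p_two_tailed})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Correlation matrix


def corr_matrix(ds) -> pd.DataFrame:
    """Pairwise Pearson correlations of the five predictors and the
    response (6 × 6, symmetric, unit diagonal)."""
    cols = [*ds.predictor_names, ds.response_name]
    if ds.n < 3:
        raise DiagnosticsError("need at least 3 records")
    data = ds.records[cols]
    sd = data.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise DiagnosticsError(f"zero-variance column(s): {zero}")
    return data.corr(method="pearson")


# ----------------------------------------------------------------------
# Model comparison


@dataclass
class ComparisonTable:
    table: pd.DataFrame

    def to_dict(self) -> dict:
        return {row["model"]: {k: v for k, v in row.items() if k != "model"}
                for row in self.table.to_dict(orient="records")}


def compare_models(fits: list, ds) -> ComparisonTable:
    """Assemble the cross-model metric table.

    One row per fit: AICc, adjusted R² (conditional R² for the mixed
    model), RMSE, MAE, mean and sd of the residual Z scores, the
    neighbour count for local fits, and the percentage RMSE/MAE
    reduction relative to the OLS row when one is present.
    """
    fp = ds.fingerprint()
    rows = []
    for fit in fits:
        if getattr(fit, "data_fingerprint", fp) != fp:
            raise DiagnosticsError(
                f"fit {getattr(fit, 'model', '?')} was produced from a different dataset"
            )
        z = z_scores(ds.y, fit.fitted)
        rows.append(
            {
                "model": fit.model,
                "n_neighbors": getattr(getattr(fit, "cfg", None), "k", None),
                "aicc": float(fit.aicc),
                "r2a": float(fit.rc2) if hasattr(fit, "rc2") else float(fit.ra2),
                "rmse": float(fit.rmse),
                "mae": float(fit.mae),
                "z_mean": float(np.mean(z)),
                "z_std": float(np.std(z, ddof=1)),
            }
        )
    table = pd.DataFrame(rows)
    ols = table[table["model"] == "OLS"]
    if len(ols):
        base_rmse = float(ols["rmse"].iloc[0])
        base_mae = float(ols["mae"].iloc[0])
        table["rmse_reduction_pct"] = 100.0 * (1.0 - table["rmse"] / base_rmse)
        table["mae_reduction_pct"] = 100.0 * (1.0 - table["mae"] / base_mae)
    return ComparisonTable(table=table)
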