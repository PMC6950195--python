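"""Space-time distances, kernel weights and adaptive bandwidths.

The squared space-time separation of two records is

    d²_ST = λ·[(u_i − u_j)² + (v_i − v_j)²] + μ·(t_i − t_j)²

with λ, μ ≥ 0 the spatial and temporal scale factors.  Purely spatial
weighting (GWR) is the μ = 0 special case and purely temporal weighting
(TWR) is λ = 0.  Only the ratio τ = μ/λ matters jointly with an
adaptive bandwidth, so λ is fixed at 1 and τ is the free scale.

Bandwidths are adaptive: the kernel radius at a focal record is the
distance to its k-th nearest record (the focal record itself counts as
one of the k, at distance 0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

MODES = ("spatial", "temporal", "spatiotemporal")
KERNELS = ("bisquare", "gaussian", "exponential", "uniform")


class KernelError(ValueError):
    pass


class DegenerateBandwidthError(KernelError):
    """k records coincide with the focal record; increase k."""


@dataclass
class KernelConfig:
    """Weighting scheme for a local fit.

    mode selects which distances enter (spatial → GWR, temporal → TWR,
    spatiotemporal → GTWR); ``k`` is the adaptive neighbour count; for
    spatiotemporal mode ``tau`` = μ/λ balances weeks against coordinate
    units.
    """

    mode: str = "spatiotemporal"
    kernel: str = "gaussian"
    k: int | None = None
    tau: float = 1.0
    #: explicit scale overrides; when None the mode supplies them
    lam: float | None = None
    mu: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise KernelError(f"unknown mode {self.mode!r}")
        if self.kernel not in KERNELS:
            raise KernelError(f"unknown kernel {self.kernel!r}")
        if self.tau < 0:
            raise KernelError("tau must be >= 0")
        lam, mu = self.scales()
        if lam < 0 or mu < 0:
            raise KernelError("scale factors must be >= 0")
        if lam == 0 and mu == 0:
            raise KernelError("lambda and mu cannot both be 0")

    def scales(self) -> tuple[float, float]:
        """(λ, μ) in effect: spatial → (1, 0), temporal → (0, 1),
        spatiotemporal → (1, τ) unless overridden explicitly."""
        if self.mode == "spatial":
            return 1.0, 0.0
        if self.mode == "temporal":
            return 0.0, 1.0
        lam = 1.0 if self.lam is None else self.lam
        mu = self.tau if self.mu is None else self.mu
        return lam, mu


def default_kernel(mode: str) -> str:
    """Package default pairing: compact bi-square for purely spatial
    weighting, gaussian decay when time is involved."""
    return "bisquare" if mode == "spatial" else "gaussian"


# ----------------------------------------------------------------------


def st_squared_distance(rec_i, rec_j, lam: float, mu: float) -> float:
    """Squared space-time separation of two (u, v, t) records."""
    if lam < 0 or mu < 0:
        raise KernelError("scale factors must be >= 0")
    du = rec_i[0] - rec_j[0]
    dv = rec_i[1] - rec_j[1]
    dt = rec_i[2] - rec_j[2]
    return lam * (du * du + dv * dv) + mu * dt * dt


def squared_distances(
    coords: np.ndarray, times: np.ndarray, focal: int, lam: float, mu: float
) -> np.ndarray:
    """Vector of squared distances from record ``focal`` to all records."""
    if lam < 0 or mu < 0:
        raise KernelError("scale factors must be >= 0")
    d2 = np.zeros(len(times))
    if lam:
        diff = coords - coords[focal]
        d2 += lam * (diff[:, 0] ** 2 + diff[:, 1] ** 2)
    if mu:
        d2 += mu * (times - times[focal]) ** 2
    return d2


def adaptive_bandwidth_from_d2(d2: np.ndarray, k: int) -> float:
    """Bandwidth = sqrt of the k-th smallest squared distance.

    The focal record contributes distance 0 and is counted among the k.
    """
    if k < 1 or k > len(d2):
        raise KernelError(f"k={k} out of range for n={len(d2)}")
    h2 = np.partition(d2, k - 1)[k - 1]
    if h2 <= 0:
        raise DegenerateBandwidthError(
            f"{k} records coincide with the focal record; increase k"
        )
    return float(np.sqrt(h2))


def adaptive_bandwidth(focal: int, ds, cfg: KernelConfig) -> float:
    """Adaptive bandwidth at a focal record of a panel dataset."""
    lam, mu = cfg.scales()
    d2 = squared_distances(ds.coords(), ds.times(), focal, lam, mu)
    return adaptive_bandwidth_from_d2(d2, cfg.k)


def kernel_weight(d, h: float, kernel: str = "bisquare"):
    """Distance-decay weight in [0, 1]; weight(0) = 1 for every kernel.

    bisquare: [1 − (d/h)²]² for d < h, else 0 (compact support);
    gaussian: exp(−d²/h²); exponential: exp(−d/h); uniform: 1 for d ≤ h.
    """
    if h <= 0:
        raise KernelError("bandwidth must be > 0")
    d = np.asarray(d, float)
    if kernel == "bisquare":
        u = d / h
        w = np.where(u < 1.0, (1.0 - u * u) ** 2, 0.0)
    elif kernel == "gaussian":
        w = np.exp(-(d * d) / (h * h))
    elif kernel == "exponential":
        w = np.exp(-d / h)
    elif kernel == "uniform":
        w = np.where(d <= h, 1.0, 0.0)
    else:
        raise KernelError(f"unknown kernel {kernel!r}")
    return w if w.shape else float(w)


def weight_vector(focal: int, ds, cfg: KernelConfig) -> np.ndarray:
    """Kernel weights of all records relative to one focal record."""
    lam, mu = cfg.scales()
    d2 = squared_distances(ds.coords(), ds.times(), focal, lam, mu)
    h = adaptive_bandwidth_from_d2(d2, cfg.k)
    return kernel_weight(np.sqrt(d2), h, cfg.kernel)


# ----------------------------------------------------------------------
# AICc-driven bandwidth selection


def _k_grid(p: int, n: int, n_points: int = 25) -> np.ndarray:
    lo, hi = p + 2, n
    grid = np.unique(np.round(np.geomspace(lo, hi, n_points)).astype(int))
    return grid[(grid >= lo) & (grid <= hi)]


def select_bandwidth(ds, cfg: KernelConfig, search_opts: dict | None = None):
    """Choose (k, τ) minimizing the corrected AIC of the local fit.

    A coarse grid (≤ 25 neighbour counts, log-spaced; for
    spatiotemporal mode crossed with a log-spaced τ grid) is scanned
    first, then the neighbour count is refined by integer golden-section
    search around the coarse minimum.  Returns ``(k, tau, trace)`` with
    ``trace`` a list of (k, tau, aicc) tuples actually evaluated;
    deterministic for fixed inputs.
    """
    from .local_models import LocalSingularityError, fit_stwr

    opts = search_opts or {}
    n, p = ds.n, ds.p
    kgrid = opts.get("k_grid")
    if kgrid is None:
        kgrid = _k_grid(p, n, opts.get("n_k", 25))
    kgrid = np.asarray(sorted(set(int(k) for k in kgrid)))
    if cfg.mode == "spatiotemporal":
        taus = np.asarray(opts.get("tau_grid", np.logspace(-2, 2, 9)))
    else:
        taus = np.asarray([cfg.tau])

    trace: list[tuple[int, float, float]] = []
    cache: dict[tuple[int, float], float] = {}

    def aicc_at(k: int, tau: float) -> float:
        key = (int(k), float(tau))
        if key not in cache:
            try:
                fit = fit_stwr(ds, replace(cfg, k=int(k), tau=float(tau)))
                val = fit.aicc
            except (LocalSingularityError, DegenerateBandwidthError, KernelError):
                val = np.inf
            cache[key] = val
            trace.append((int(k), float(tau), val))
        return cache[key]

    results = [(aicc_at(k, tau), int(k), float(tau)) for k in kgrid for tau in taus]
    best = min(results, key=lambda r: (r[0], r[1]))
    if not np.isfinite(best[0]):
        raise KernelError(
            "bandwidth selection failed at every grid point; "
            f"failures: {[(k, t) for a, k, t in results]}"
        )
    _, k_best, tau_best = best

    # integer golden-section refinement between the neighbours of the
    # coarse minimum on the k axis, tau held fixed
    i = int(np.searchsorted(kgrid, k_best))
    lo = int(kgrid[max(i - 1, 0)])
    hi = int(kgrid[min(i + 1, len(kgrid) - 1)])
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    while b - a > 2:
        c = int(round(b - phi * (b - a)))
        d = int(round(a + phi * (b - a)))
        if c == d:
            d += 1
        if aicc_at(c, tau_best) <= aicc_at(d, tau_best):
            b = d
        else:
            a = c
    cand = [(aicc_at(k, tau_best), k) for k in range(a, b + 1)]
    cand.append((aicc_at(k_best, tau_best), k_best))
    _, k_star = min(cand, key=lambda r: (r[0], r[1]))
    return int(k_star), float(tau_best), trace
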