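"""Synthetic space-time pollution panels with known ground truth.

The generator emulates the structure of a weekly 13-city criteria-
pollutant panel: seasonal cycles in every pollutant, a shared
"heating season" latent factor that raises SO2/NO2/PM10/CO and lowers
O3 (inducing the observed correlation sign pattern), city-level random
effects, and first-order temporal autocorrelation in the errors.  Two
response modes are provided:

``mixed``
    y = Xβ + Zγ + ε with variance-component random effects γ drawn once
    per city and an AR(1) error process per city — the data-generating
    process a linear mixed model assumes.

``varying``
    y_i = Σ_k β_k(u_i, v_i, t_i) x_ik + white noise, with coefficient
    surfaces that drift smoothly over space and time — the process the
    GWR/TWR/GTWR family targets.

Every draw also returns a :class:`SimTruth` so parameter-recovery tests
can compare estimates against the exact generative values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_core import PREDICTORS, RESPONSE, Location, PanelDataset


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the 13 × 210 weekly design.

    ``mean_levels`` default to pollutant means characteristic of weekly
    city-level monitoring in a heating-dominated region (µg/m³ except
    CO in mg/m³); ``beta`` to global-regression coefficients with the
    characteristic sign pattern (O3 negative); ``re_sd`` and ``ar1_r``
    to city-level variance components and a weekly error
    autocorrelation of realistic magnitude for such panels.
    """

    n_locations: int = 13
    n_times: int = 210
    seed: int = 0
    mode: str = "mixed"  # "mixed" | "varying"
    period: float = 52.0  # weeks per seasonal cycle

    # predictor process -------------------------------------------------
    mean_levels: tuple[float, ...] = (16.48, 22.95, 58.67, 0.72, 72.16)
    seasonal_loadings: tuple[float, ...] = (8.0, 6.0, 20.0, 0.20, -18.0)
    #: loadings of the shared heating-season latent factor
    heat_loadings: tuple[float, ...] = (4.0, 3.0, 12.0, 0.12, -8.0)
    #: marginal sd of the per-predictor AR(1) noise
    predictor_noise_sd: tuple[float, ...] = (5.0, 4.0, 15.0, 0.15, 10.0)
    #: sd of time-constant city offsets, as a fraction of the mean level
    city_offset_frac: float = 0.10

    # response process --------------------------------------------------
    beta: tuple[float, ...] = (-4.398, 0.081, 0.380, 0.520, 5.640, -0.086)
    re_sd: tuple[float, ...] = (8.837, 0.148, 0.286, 0.095, 12.530, 0.032)
    ar1_r: float = 0.552
    resid_sd: float = 8.667
    nonstat_space: float = 0.3
    nonstat_time: float = 0.6

    def __post_init__(self) -> None:
        if self.n_locations < 2:
            raise ConfigError("need at least 2 locations")
        if self.n_times < 3:
            raise ConfigError("need at least 3 time periods")
        if not abs(self.ar1_r) < 1:
            raise ConfigError("|ar1_r| must be < 1")
        if self.resid_sd < 0 or any(s < 0 for s in self.re_sd):
            raise ConfigError("standard deviations must be >= 0")
        if self.mode not in ("mixed", "varying"):
            raise ConfigError(f"unknown response mode {self.mode!r}")


@dataclass
class SimTruth:
    """Generative ground truth attached to every simulated panel."""

    beta_global: np.ndarray
    gamma: np.ndarray | None  # S × p random effects (mixed mode)
    beta_local: np.ndarray  # n × p coefficients actually used per record
    variance_components: dict = field(default_factory=dict)


# ----------------------------------------------------------------------


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _ar1_series(rng: np.random.Generator, T: int, r: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series of length T with marginal sd ``sd``."""
    if sd == 0:
        return np.zeros(T)
    x = np.empty(T)
    w = rng.standard_normal(T)
    x[0] = sd * w[0]
    c = sd * np.sqrt(1.0 - r * r)
    for t in range(1, T):
        x[t] = r * x[t - 1] + c * w[t]
    return x


def gen_locations(S: int, seed: int) -> list[Location]:
    """S distinct city sites drawn uniformly in the unit square."""
    if S < 2:
        raise ConfigError("need at least 2 locations")
    rng = _rng(seed, 0)
    xy = rng.random((S, 2))
    return [Location(i, f"city{i + 1:02d}", float(u), float(v)) for i, (u, v) in enumerate(xy)]


def gen_predictors(cfg: SimConfig, locations: list[Location]) -> np.ndarray:
    """Pollutant predictor panel, shape (S·T) × 5, (location, t) order.

    Each predictor is mean level + seasonal sinusoid + heating-factor
    loading + city offset + AR(1) noise, floored at a small positive
    value.  The heating factor is one AR(1) latent series per city that
    loads positively on SO2/NO2/PM10/CO and negatively on O3, which is
    what makes those four co-vary positively with the response while O3
    co-varies negatively.
    """
    S, T = len(locations), cfg.n_times
    rng = _rng(cfg.seed, 1)
    t = np.arange(1, T + 1, dtype=float)
    season = np.sin(2 * np.pi * t / cfg.period)

    means = np.asarray(cfg.mean_levels, float)
    loads = np.asarray(cfg.seasonal_loadings, float)
    heat = np.asarray(cfg.heat_loadings, float)
    nsd = np.asarray(cfg.predictor_noise_sd, float)

    out = np.empty((S * T, 5))
    for s in range(S):
        offsets = rng.standard_normal(5) * cfg.city_offset_frac * np.abs(means)
        heat_factor = _ar1_series(rng, T, 0.7, 1.0)
        block = (
            means
            + np.outer(season, loads)
            + np.outer(heat_factor, heat)
            + offsets
        )
        for j in range(5):
            block[:, j] += _ar1_series(rng, T, 0.3, nsd[j])
        out[s * T : (s + 1) * T] = block
    floor = np.maximum(0.01 * np.abs(means), 1e-3)
    return np.maximum(out, floor)


def _design(Xpanel: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(Xpanel)), Xpanel])


def gen_response_mixed(
    cfg: SimConfig, locations: list[Location], Xpanel: np.ndarray
) -> tuple[np.ndarray, SimTruth]:
    """Mixed-model response: y = Xβ + Zγ + AR(1) errors per city."""
    S, T = len(locations), cfg.n_times
    rng = _rng(cfg.seed, 2)
    X = _design(Xpanel)
    beta = np.asarray(cfg.beta, float)
    re_sd = np.asarray(cfg.re_sd, float)

    gamma = rng.standard_normal((S, len(beta))) * re_sd
    eps = np.concatenate(
        [_ar1_series(rng, T, cfg.ar1_r, cfg.resid_sd) for _ in range(S)]
    )
    loc_idx = np.repeat(np.arange(S), T)
    beta_local = beta + gamma[loc_idx]
    y = np.einsum("ij,ij->i", X, beta_local) + eps
    truth = SimTruth(
        beta_global=beta,
        gamma=gamma,
        beta_local=beta_local,
        variance_components={
            "sigma2": [float(s * s) for s in re_sd],
            "r": cfg.ar1_r,
            "resid_var": cfg.resid_sd**2,
        },
    )
    return y, truth


def gen_response_varying(
    cfg: SimConfig, locations: list[Location], Xpanel: np.ndarray
) -> tuple[np.ndarray, SimTruth]:
    """Varying-coefficient response with smooth space-time drift.

    β_k(u, v, t) = β_k · (1 + a_s·g(u, v) + a_t·h(t)) with g a centred
    linear surface in the coordinates and h a centred seasonal sinusoid.
    """
    S, T = len(locations), cfg.n_times
    rng = _rng(cfg.seed, 3)
    X = _design(Xpanel)
    beta = np.asarray(cfg.beta, float)

    xy = np.array([(loc.x, loc.y) for loc in locations])
    g_loc = (xy[:, 0] - xy[:, 0].mean()) + (xy[:, 1] - xy[:, 1].mean())
    t = np.arange(1, T + 1, dtype=float)
    h_t = np.sin(2 * np.pi * t / cfg.period)
    h_t = h_t - h_t.mean()

    g = np.repeat(g_loc, T)
    h = np.tile(h_t, S)
    scale = 1.0 + cfg.nonstat_space * g + cfg.nonstat_time * h
    beta_local = np.outer(scale, beta)
    y = np.einsum("ij,ij->i", X, beta_local) + rng.standard_normal(len(X)) * cfg.resid_sd
    truth = SimTruth(
        beta_global=beta,
        gamma=None,
        beta_local=beta_local,
        variance_components={"resid_var": cfg.resid_sd**2},
    )
    return y, truth


def simulate(cfg: SimConfig | None = None) -> tuple[PanelDataset, SimTruth]:
    """Generate a complete panel plus its ground truth.

    The default configuration yields the 13-location × 210-week design
    (2730 records) in mixed mode.
    """
    cfg = cfg or SimConfig()
    locations = gen_locations(cfg.n_locations, cfg.seed)
    Xpanel = gen_predictors(cfg, locations)
    if cfg.mode == "mixed":
        y, truth = gen_response_mixed(cfg, locations, Xpanel)
    else:
        y, truth = gen_response_varying(cfg, locations, Xpanel)

    loc_idx = np.repeat(np.arange(cfg.n_locations), cfg.n_times)
    records = pd.DataFrame(
        {
            "location_id": [locations[i].id for i in loc_idx],
            "t": np.tile(np.arange(1, cfg.n_times + 1), cfg.n_locations),
        }
    )
    for j, name in enumerate(PREDICTORS):
        records[name] = Xpanel[:, j]
    records[RESPONSE] = y
    return PanelDataset(locations=locations, records=records), truth
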