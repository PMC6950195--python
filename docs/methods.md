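# Methods

This note records the statistical models implemented in `stwreg`, the
assumptions behind them, the design choices made where the
methodological literature leaves options open, and what the synthetic
generator does and does not emulate.

## Data model

A panel holds one record per (city, week): planar coordinates
(u, v), an integer week index t, five predictors (SO2, NO2, PM10, O3
in µg/m³; CO in mg/m³) and the PM2.5 response (µg/m³). Coordinates
are taken as Euclidean in any consistent length unit; the package does
not project geographic coordinates, because all spatial quantities
enter only through squared coordinate differences. Time is a 1-based
consecutive week index; calendar parsing is out of scope. Records with
missing values are dropped (and counted), not imputed.

## Global models

**OLS.** `β̂ = (XᵀX)⁻¹XᵀY` with classical standard errors, two-sided
t tests on n − p degrees of freedom, and standardized estimates
`β̂_k·sd(X_k)/sd(Y)`. Solved by `lstsq`, with a rank check that names
collinear columns.

**Linear mixed model.** `y = Xβ + Zγ + ε` where every city carries a
random deviation of all six coefficients: `Var(γ) = G = diag(σ1²…σ6²)`
(variance-components structure, no random-effect correlations) and the
within-city errors are AR(1): `Var(ε)` block-diagonal with blocks
`σ²·[r^|i−j|]`. Estimation is REML. The −2 restricted log-likelihood
is profiled over β and optimized over
`θ = (log σ1²…log σ6², artanh r, log σ²)`; the transform enforces
positivity and |r| < 1 without constrained optimization. Each city
block of `V = ZGZᵀ + R` is handled by whitening with the AR(1)
innovations transform followed by a rank-6 Woodbury update, so the
objective costs O(T·q²) per city and no T × T factorization occurs; a
dense whole-matrix evaluation is kept in the test suite as the oracle.

The optimizer is L-BFGS-B from three deterministic starts (an
OLS-residual-based start whose r comes from the pooled lag-1
autocorrelation of the OLS residuals, a near-zero-variance start, and
a moderate-variance start). Each random-effect variance start is
scaled by the mean square of its design column so that slope and
intercept components are comparable. Overflowing parameter points
return an infinite sentinel from the public objective; the optimizer
sees a large finite penalty instead so its line searches can recover.

Reported quantities: fixed effects with standard errors from
`(XᵀV̂⁻¹X)⁻¹` and t tests on S − 1 denominator degrees of freedom
(a deliberately conservative containment choice, since the reference
method for mixed-model degrees of freedom is not settled); BLUPs
`γ̂_c = ĜZ_cᵀV̂_c⁻¹(y_c − X_cβ̂)`; per-city coefficient tables
`β̂ + γ̂_c`; the conditional
`Rc² = (σ_f² + σ_r²)/(σ_f² + σ_r² + σ_ε²)` with σ_f² the variance of
Xβ̂ over records, σ_r² the mean of `z_iᵀĜz_i`, σ_ε² the marginal AR(1)
variance σ². The AICc reported for the mixed model uses the ML
log-likelihood evaluated at the REML-optimal variance parameters with
parameter count p + 8, which keeps it comparable with the OLS value;
the REML criterion itself is exposed separately.

## Local models

GWR, TWR and GTWR share one engine. The combined squared distance is

    d²_ST = λ·[(u_i−u_j)² + (v_i−v_j)²] + μ·(t_i−t_j)²

and kernels receive `d = √d²_ST`. This squared-combination reading is
the only one under which the Gaussian separability identity
`exp(−d²_ST/h²_ST) = exp(−d²_S/h²_S)·exp(−d²_T/h²_T)` (with
`h²_S = h²_ST/λ`, `h²_T = h²_ST/μ`) holds exactly, and the package
asserts it to 1e−12. Only the ratio τ = μ/λ is identifiable jointly
with an adaptive bandwidth (scaling all distances rescales the
bandwidth identically), so λ is fixed at 1 and τ is searched on a
log grid (default 10⁻²…10², 9 points). Explicit λ/μ overrides exist
for the exact special-case reductions: μ = 0 recovers GWR, λ = 0
recovers TWR, bit-for-bit in the tests.

Bandwidths are adaptive: `h_i` is the distance to the k-th nearest
record, the focal record counting as one of the k at distance 0.
Ties at the k-th distance include all tied records; the bi-square
kernel assigns them weight 0 at d = h regardless. Temporal distance is
the symmetric raw week difference — no causal windowing. Because all
records of one city share a spatial point, purely spatial weighting
needs k larger than the per-city record count, and the degenerate
h = 0 case raises an error that says so. Kernels: bi-square (default
for purely spatial weighting, matching common practice), Gaussian
(default when time is involved), exponential, and uniform (which at
k = n reproduces OLS exactly, including tr(S) = p and the AICc — the
engine's reduction test). The local solves use Cholesky factorization
of `XᵀW X` with a condition-number guard at 1e10; the textbook inverse
is notation only.

Neighbour-count selection minimizes
`AICc = 2n·ln σ̂ + n·ln 2π + n·(n + tr S)/(n − 2 − tr S)` where tr S
accumulates the focal hat diagonals `x_iᵀ(XᵀW_iX)⁻¹x_i·w_ii`. A coarse
log-spaced grid (≤ 25 points, crossed with the τ grid for GTWR) is
scanned, then the count is refined by integer golden-section search
around the coarse minimum; candidates whose local fits fail are scored
+inf rather than aborting the search. The adjusted R² of local models
uses p_eff = tr(S) — the standard effective-parameter convention for
linear smoothers, consistent with the AICc — configurable back to the
raw p.

## Diagnostics

`Ra² = 1 − (n−1)(1−R²)/(n−p_eff)`, `RMSE = √(Σe²/n)`, `MAE = Σ|e|/n`.
Z scores standardize residuals by the sample (n−1) standard deviation
of the fitted values; the denominator convention is stated because the
defining expression leaves it open. With an intercept the OLS Z scores
average exactly zero.

Moran's I of residuals uses binary k-nearest-neighbour weights on the
record coordinates (self excluded, not symmetrized, not
row-standardized), with ties at the k-th distance broken
deterministically by the dataset's (city, week) record order — with
records stacked on a handful of city sites, ties are pervasive and the
deterministic order makes every neighbour set reproducible.
`I = (n/W)·ΣΣ w_ij z_i z_j / Σz_i²`, `E(I) = −1/(n−1)` exactly.
Inference is either analytic, using the randomization (fourth-moment)
variance with a two-tailed normal p-value, or by permutation with a
two-tailed empirical p — provided because the normal approximation is
dubious under massive distance ties. The analytic variance is
cross-checked against the permutation variance in the tests. Moran
profiles over a neighbour-count grid support the diagnostic that
residual autocorrelation decays toward the null as the neighbourhood
widens.

The comparison table assembles AICc, adjusted (or conditional) R²,
RMSE, MAE, Z-score mean/sd and the neighbour count per model, plus
percentage RMSE/MAE reductions relative to the OLS row, and refuses to
mix fits from different datasets (checked by a content fingerprint).

## Synthetic generator

The generator emulates the weekly 13-city study design (defaults:
S = 13, T = 210, giving 2730 records; city sites uniform in the unit
square). Each predictor is

    mean + seasonal·sin(2πt/52) + heating·f_c(t) + city offset + AR(1) noise,

floored at a small positive value. Mean levels default to values
typical of weekly city-level monitoring in a heating-dominated region
(SO2 16.48, NO2 22.95, PM10 58.67 µg/m³, CO 0.72 mg/m³, O3 72.16
µg/m³). The heating-season factor f_c(t) is one AR(1) latent series
per city loading positively on SO2/NO2/PM10/CO and negatively on O3; a
shared factor is the simplest mechanism that reproduces the
characteristic correlation sign pattern (strong positive PM2.5
correlations with the four combustion-linked pollutants, negative with
O3), which is the generator's calibration target — full marginal
distributions are not emulated. Seasonal and noise amplitudes were
chosen once to give seasonal swings and within-city noise of the same
order as the pollutant spreads such panels show.

The mixed response mode draws γ_c once per city from the diagonal G
and adds a per-city AR(1) error with marginal sd 8.667 and
autocorrelation 0.552 — a realistic weekly persistence for city-level
pollution errors; independence of errors across cities matches the
block-diagonal R of the mixed model. The varying response mode scales
every coefficient by `1 + a_s·g(u,v) + a_t·h(t)` with g a centred
linear surface and h a centred seasonal sinusoid, plus white noise;
the defaults a_s = 0.3, a_t = 0.6 make temporal nonstationarity
dominate spatial, the regime this model family is designed to expose.
All draws are deterministic functions of the configuration including
its seed, and every draw returns the exact per-record coefficients
used, enabling recovery tests.

What passing tests therefore show: the estimators recover the
structure this generator produces — seasonal varying coefficients,
city random effects, AR(1) errors, the documented correlation signs.
What they do not show: behaviour under features of real monitoring
data the generator omits — heavy-tailed pollution episodes,
within-week aggregation noise, cross-city error correlation from
regional transport, irregular missingness — or any specific
monitoring network's exact coefficient magnitudes.

## Numerical choices and limitations

- Local solves: Cholesky with condition guard 1e10; singular local
  fits raise an error naming the focal records and suggesting larger k.
- AICc is undefined for n ≤ tr(S) + 2 and diverges to −inf at zero
  residual sum of squares; both cases are handled explicitly.
- Quartiles use the linear-interpolation convention.
- A constant response makes R² undefined; local fits then report NaN
  Ra² while still returning coefficients and residuals.
- The analytic Moran variance needs n ≥ 4; below that the statistic
  and expectation are still reported, the p-value is NaN.
- The mixed model requires at least 8 records per city and fits only
  the VC + AR(1) covariance family; crossed or correlated random
  effects are out of scope.
- Bandwidth search is deterministic but greedy in τ (coarse grid
  only); the refinement is on the neighbour count alone.
- Desk-scale experiment sizes used in the test suite (e.g. 8 × 60
  panels, 20-seed Monte Carlo) were chosen as the smallest designs at
  which the qualitative claims are stable.
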