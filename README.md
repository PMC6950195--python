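# stwreg

Global and space-time weighted regression models for criteria
air-pollutant panels.

Urban PM2.5 co-varies strongly with the other criteria pollutants
(SO2, NO2, PM10, CO positively; O3 negatively), but the strength of
those relationships drifts across cities and, above all, across the
seasons of a heating-dominated climate. `stwreg` implements the model
family used to quantify that drift on long-format (city, week) panels:

- **OLS** — the global benchmark, `y = Xβ + ε`;
- **LMM** — a linear mixed model `y = Xβ + Zγ + ε` whose six
  coefficients (intercept + 5 pollutant slopes) carry city-level
  random effects with a diagonal variance-components G matrix, and
  whose within-city errors follow an AR(1) covariance
  `R = σ²·[r^|i−j|]`, fitted by REML;
- **GWR / TWR / GTWR** — locally weighted regressions
  `β̂(u_i, v_i, t_i) = (XᵀW_i X)⁻¹ XᵀW_i y` with kernel weights built
  from the combined squared distance `d²_ST = λ·d²_S + μ·d²_T`,
  adaptive k-nearest-neighbour bandwidths, and neighbour counts chosen
  by minimizing the corrected AIC
  `AICc = 2n·ln σ̂ + n·ln 2π + n·(n + tr S)/(n − 2 − tr S)`;
- **Diagnostics** — adjusted/conditional R², RMSE/MAE, residual Z
  scores, Moran's I bandwidth profiles with randomization or
  permutation inference, and a cross-model comparison table.

Because the monitoring data behind this design are not publicly
deposited, the package ships a first-class synthetic generator that
emulates the 13-city × 210-week structure — seasonal pollutant cycles,
a shared heating-season factor that induces the characteristic
correlation signs, city random effects, AR(1) errors, and optionally smooth
space-time-varying coefficients — together with the exact generative
truth, so every estimator is testable by parameter recovery.

## Worked example

```python
import stwreg

# a 13-city x 210-week panel with varying coefficients
ds, truth = stwreg.simulate(stwreg.SimConfig(seed=1, n_locations=8,
                                             n_times=60, mode="varying"))

ols = stwreg.fit_ols(ds)
k, tau, _ = stwreg.select_bandwidth(
    ds, stwreg.KernelConfig(mode="temporal", kernel="gaussian"), {"n_k": 10})
twr = stwreg.fit_stwr(
    ds, stwreg.KernelConfig(mode="temporal", kernel="gaussian", k=k))

table = stwreg.compare_models([ols, twr], ds)
print(table.table[["model", "n_neighbors", "aicc", "r2a", "rmse"]])
```

prints

```
  model  n_neighbors         aicc       r2a       rmse
0   OLS          NaN  3924.203733  0.772970  14.209961
1   TWR         41.0  3598.450501  0.901146   8.787736
```

The TWR row shows what the local model buys on temporally
nonstationary data: the AICc-selected 41-neighbour temporal kernel
raises the adjusted R² from 0.77 to 0.90 and cuts the residual RMSE by
38%, because the weekly regression coefficients are allowed to follow
their seasonal cycle instead of being averaged over it.

The same pipeline is available from the shell:

```sh
stwreg simulate --seed 1 --out run/
stwreg fit --model gtwr --panel run/panel.csv --k auto --out run/gtwr/
stwreg compare --panel run/panel.csv --out run/cmp/
```

Every command writes a manifest (config, seed, version, input
checksum) so runs are reproducible from their artifacts. Coordinates
are treated as planar Euclidean; project geographic coordinates before
building a panel.

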