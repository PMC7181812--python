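# recruitcast

Forecast-skill comparison of standard fisheries stock-recruitment models and
equation-free empirical dynamic modelling (EDM), with a synthetic operating
model that reproduces the *data-circularity* effect in stock assessment.

## The problem

Fisheries recruitment forecasting leans on stock-recruitment relationships
(SRRs) of the form **R = α·S·g(S)**, where *R* is recruitment, *S* is
spawning stock biomass, *α* the maximum rate of reproduction and *g* a
density-dependence term:

| model | g(S) | prediction |
|---|---|---|
| density-independent | 1 | `R = αS` |
| Ricker | `exp(−βS)` | `R = αS·e^{−βS}` |
| Beverton-Holt | `1/(1+βS)` | `R = αS/(1+βS)` |

Many assessment time series are themselves *reconstructed by models that
embed an SRR* (e.g. biomass dynamic models). When such "synthetic data" (SD)
are then predicted with an SRR, the model is partly predicting its own
assumptions, and its apparent skill is inflated relative to "direct data"
(DD: surveys, or sequential population analyses that assume only constant
natural mortality). `recruitcast` makes this circularity measurable:

* **srr** — closed-form and simplex fits of the three SRRs (Ricker and
  Beverton-Holt on the log scale via `y = ln(R/S)`), predictions on the
  original recruitment scale.
* **edm** — multivariate delay embeddings over the six candidate coordinates
  `R_t, R_{t−1}, R_{t−2}, S_t, S_{t−1}, S_{t−2}` (all 63 subsets) and S-map
  locally weighted forecasting with weights `w_i = exp(−θ·d_i/d̄)`; θ = 0 is
  one global linear map, improvement at θ > 0 signals state-dependent
  (nonlinear) dynamics. Skill is the maximum leave-one-out Pearson ρ over
  embeddings × θ.
* **crossval** — the randomized evaluation protocol: 25 target years per
  stock; each SRR fit sees exactly 24 training points (the year before the
  target plus 23 random ones), so sample sizes are identical across stocks
  and models.
* **comparison** — SD/DD classification from assessment-method labels
  (BDM → SD; SPA, DO → DD; SCA excluded), batch evaluation on shared
  per-stock targets, and the mean-ρ ± SE summary with Welch t-tests.
* **simulate** — the synthetic operating model: Ricker dynamics with AR(1)
  environmental forcing, lognormal process/observation noise and a bounded
  harvest walk; "direct" series add observation noise only, "filtered"
  series are re-expressed through a fitted (deliberately misspecified)
  Beverton-Holt curve, injecting the SRR into the data.

## Worked example

```python
import recruitcast as rc

stocks = rc.generate_ensemble(10, 10, seed=42)          # 10 SD + 10 DD stocks
results, skipped = rc.evaluate_collection(rc.ensemble_series(stocks), seed=42)
print(rc.summarize(results).cells.round(3))
```

prints (mean leave-one-out ρ per method × data class):

```
                                mean_rho     se   n
method              data_class
beverton_holt       DD             0.375  0.082  10
                    SD             0.816  0.060  10
density_independent DD             0.392  0.074  10
                    SD             0.830  0.037  10
edm                 DD             0.630  0.069  10
                    SD             0.833  0.032  10
ricker              DD             0.394  0.070  10
                    SD             0.803  0.070  10
```

Every stock-recruitment model loses roughly half its apparent skill when it
must predict direct data instead of model-filtered data (0.82 → 0.39 mean ρ,
a 53% drop), while the equation-free EDM forecast degrades far less
(0.83 → 0.63) and clearly beats every SRR on direct data — the circularity
signature. The narrative scripts in `examples/` walk through each stage
(`01` SRR fits, `02` S-map nonlinearity detection, `03` the evaluation
protocol, `04` this experiment).

A thin CLI mirrors the pipeline:

```sh
recruitcast simulate --n-sd 5 --n-dd 5 --seed 7 -o data/
recruitcast compare data/stocks.csv --seed 7 -o results/
recruitcast report results/
```

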