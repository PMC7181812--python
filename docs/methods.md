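# Methods

## Scope and model

`recruitcast` measures how well recruitment *R* can be forecast from
spawning stock biomass *S* (and their recent histories) and how that skill
depends on the provenance of the data. Two method families are compared on
identical evaluation targets:

1. **Stock-recruitment relationships (SRRs)** — density-independent
   (`R = αS`), Ricker (`R = αS·e^{−βS}`) and Beverton-Holt
   (`R = αS/(1+βS)`). Ricker and Beverton-Holt are fitted on the log scale
   through the survival ratio `y = ln(R/S)`; predictions are always on the
   original recruitment scale.
2. **Empirical dynamic modelling (EDM)** — attractor reconstruction from
   delay coordinates and S-map locally weighted linear forecasting, an
   equation-free alternative that presumes no SRR.

Skill is the Pearson correlation ρ between observed and predicted
recruitment at 25 evaluation targets per stock.

## Fitting the SRRs

* Density-independent: closed-form least squares on the original scale,
  `α = ΣRS/ΣS²`. Whether this model should instead be fitted on the log
  scale (a constant `y`) is genuinely ambiguous; both are implemented
  (`di_log_scale`), with the original scale as default because the log
  transform is specific to the two density-dependent models.
* Ricker: `y = ln α − βS` is a simple linear regression — closed form,
  deterministic. The slope is unconstrained, so β may be negative on noisy
  data (logged as a warning); clamping it would silently change predictions.
* Beverton-Holt: `y = ln α − ln(1+βS)` is minimized over `(ln α, ln β)` —
  the log parameterization enforces positivity — by Nelder-Mead from a
  Ricker-derived start plus four fixed offsets (±0.7 in ln α, ±1 in ln β).
  Convergence: `fatol 1e-12`, `xatol 1e-10`, best of the five starts. The
  fixed offsets make the fit bit-deterministic.
* Pairs with S ≤ 0 or R ≤ 0 are excluded (log undefined) with a logged
  warning, never imputed; fits require ≥ 3 valid pairs and, for β models,
  ≥ 2 distinct S values.

## The evaluation protocol

The shortest admissible series has 25 years, so sample sizes are equalized
across stocks: for longer series, 25 target years are drawn uniformly
without replacement; each SRR fit uses exactly 24 points — the year
preceding the target (when it exists; for the first year the rule is
vacuous and all 24 are random) plus 23 random others, redrawn independently
per target. A 25-year series degenerates to classical leave-one-out. Stocks
with fewer than 20 successfully evaluated targets are flagged unusable;
zero-variance predictions make ρ *undefined* (flagged), never 0.

RNG discipline: one root seed; each stock's stream is
`SeedSequence([root, crc32(stock_id)])`, so adding or removing stocks never
reshuffles the draws of others. Within a stock, the target set and training
sets are drawn once and shared by all four methods — comparisons are paired
within stock.

## EDM: embeddings and the S-map

Candidate coordinates are `R_t, R_{t−1}, R_{t−2}, S_t, S_{t−1}, S_{t−2}`;
all 63 non-empty subsets are tried. The default forecast horizon is one
year (the block's target is `R` at base time + 1); a concurrent mode
(horizon 0) exists for parity with the SRRs, which predict `R_t` from `S_t`
in the same year — there the `R_t` coordinate is excluded from the 31
remaining embeddings to avoid self-prediction.

For each predictee, predictor columns are z-scored with *library* statistics
(the predictee is transformed with the same statistics), making Euclidean
distances scale-free; weights are `w_i = exp(−θ·d_i/d̄)` with `d̄` the mean
distance to the predictee. Exact duplicates of the predictee keep weight 1 —
no special-casing. The weighted regression (with intercept) is solved by a
rank-tolerant minimum-norm least-squares factorization (`rcond 1e-10`); a
fully degenerate design falls back to the weighted mean of the library
targets (logged). θ is maximized over the conventional grid
`{0, 1e-4, 3e-4, 1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3, 0.5, 0.75, 1, 1.5, 2,
3, 4, 6, 8}`; ties break toward the smallest θ, so a series that a global
linear map fits exactly reports θ\* = 0.

The library is full leave-one-out by default (only the predictee's row is
excluded); a matched mode restricting the library to the 24 protocol
training points is available but non-default — the full library is the
standard EDM convention and keeps the nonlinearity diagnostics sharp.
Embeddings that cannot represent at least 20 of the 25 shared targets
(long lags near the series edges) are skipped and reported. The stock's EDM
skill is the maximum ρ over embeddings × θ.

## The synthetic operating model

There is no bundled assessment database; the generator produces an ensemble
with *known* provenance instead. The latent population is

    R_t = α S_t exp(−β S_t + γ E_t + ε_t),   ε_t ~ N(0, σ_p²)
    E_t = φ E_{t−1} + √(1−φ²) η_t
    S_{t+1} = s (1−h_t) S_t + w R_t

with `h_t` a mean-reverting harvest walk (reversion 0.8, clipped to
[0, 0.6]). Defaults: α = 2.5, β = 1.0 (biomass is therefore in units of
1/β), γ = 0.5, φ = 0.7, σ_p = 0.3, adult survival s = 0.7, recruit biomass
weight w = 0.3, harvest mean 0.2 / sd 0.05, 60 years after a 100-year
burn-in. These were chosen once so that direct data are noisy but
forecastable: the deterministic skeleton has a stable fixed point, and the
forcing plus process noise keep ρ of a well-specified model in the 0.3–0.5
range on direct data.

* **Direct data (DD)**: truth × independent lognormal observation noise,
  log-sd σ_obs = 0.2 on both S and R — a survey-like product.
* **Filtered data (SD)**: the direct series re-expressed through an
  assessment emulator: S smoothed by a 3-year centered moving average, a
  Beverton-Holt curve fitted to the direct pairs, and
  `R̃ = prediction(S̃)·exp(λ·r)` with `r` the fit's log residual and
  λ = 0.3 the *residual retention*. λ = 1 with no smoothing reconstructs
  the direct data exactly; λ = 0 puts every point on the fitted curve. The
  filter is Beverton-Holt while the truth is Ricker-generated, so the
  assessment model is misspecified relative to the dynamics — the
  circularity effect does not depend on the filter matching the generator.
  How much residual variance real assessments remove is not quantifiable
  from first principles; λ is exposed as a knob and the residual-variance
  monotonicity in λ is itself under test.
* Ensembles jitter α, β, γ and the harvest mean per stock (lognormal /
  clipped-normal), draw series lengths uniformly in 25–60 years, and derive
  all seeds from one root via `SeedSequence.spawn`; unstable draws are
  retried a bounded number of times.
* A chaotic preset (α = 20, s = 0, w = 1, no forcing/noise/harvest) reduces
  the update to the classic Ricker map `S_{t+1} = 20 S e^{−S}` (Lyapunov
  exponent ≈ +0.38), used to verify that θ optimization detects
  nonlinearity; the growth factor must exceed ≈ e^2.69 for chaos, which is
  why the preset's α differs from the ensemble default.

**What the generator does not emulate**: age structure, catch-at-age
back-calculation, time-varying observation effort, autocorrelated
observation errors, and regime shifts. Passing tests therefore demonstrate
the circularity *mechanism* — filtering through an SRR inflates SRR skill —
not the magnitude of the effect in any real assessment database; headline
skill values from real databases are not reproduction targets here.

## Statistical summary

Per (method × data class) cell: mean ρ and SE = sd/√n (n ≥ 2 required,
else flagged missing). Per method: Welch's unequal-variance unpaired t-test
of SD vs DD ρ (a pooled-variance option exists behind a flag). No
multiple-testing correction is applied — per-model p-values are reported
raw, as is conventional for this four-test summary. The relative skill
change is `100·(mean_SD − mean_DD)/mean_SD`. Stocks with undefined ρ in one
cell are dropped from that cell only.

## Numerical and design notes

* All 1-step predictions, fits and summaries are pure functions of
  (data, seed); two runs with the same config and seed produce
  byte-identical output tables.
* ρ is computed by a two-pass centered formula and clipped to [−1, 1]
  against rounding; it raises rather than returning 0 when undefined.
* Problem sizes: the bundled experiment uses 40 SD + 40 DD stocks of 25–60
  years — large enough for the Welch tests to resolve the SD–DD gap at
  p < 0.05 with margin, and the full four-method evaluation of the
  ensemble completes in a few minutes on one CPU.
* Known limitations: the EDM search maximizes ρ over 63 × 18 candidates
  per stock, so its per-stock skill has a selection-optimism component
  (identical for SD and DD, hence harmless for the contrast); the matched
  24-point library mode is implemented but not the default; surrogate-data
  significance testing for nonlinearity is out of scope.
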