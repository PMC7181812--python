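"""Synthetic operating model for spawner-recruit data and the circularity effect.

A latent population follows Ricker recruitment with autocorrelated
environmental forcing and lognormal process noise,

    R_t = alpha * S_t * exp(-beta * S_t + gamma * E_t + eps_t),
    E_t = phi * E_{t-1} + sqrt(1 - phi^2) * eta_t,
    S_{t+1} = survival * (1 - h_t) * S_t + recruit_weight * R_t,

with h_t a bounded, mean-reverting harvest-rate walk. From the latent truth
two observation products are derived, mirroring the two classes of
assessment data:

* "direct data" (class DD): truth times independent lognormal observation
  noise — what a survey or a statistically denoised reconstruction delivers.
* "filtered data" (class SD): the direct series re-expressed through a fitted
  stock-recruitment curve — spawner biomass smoothed, recruitment replaced by
  the curve's prediction times a damped share of the fit residual. This
  injects the stock-recruitment model into the "data" and reproduces the
  circularity that inflates the apparent skill of such models.

The filtering model defaults to Beverton-Holt while the truth is
Ricker-generated, so the assessment model is deliberately misspecified
relative to the generating dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .series import StockRecruitSeries
from .srr import fit_srr, predict_srr

logger = logging.getLogger(__name__)

#: Mean-reversion rate of the harvest walk toward its long-run mean.
HARVEST_REVERSION = 0.8
HARVEST_BOUNDS = (0.0, 0.6)
FIRST_YEAR = 1960


class UnstableParametersError(RuntimeError):
    """Raised when the simulated population collapses or diverges."""


@dataclass(frozen=True)
class OperatingModelParams:
    """Parameters of the latent population and its harvest.

    Defaults produce noisy-but-forecastable dynamics: moderate density
    dependence, environmental forcing with one-year memory, and a harvest
    rate wandering around 20%.
    """

    alpha: float = 2.5            # max recruits per unit spawner biomass
    beta: float = 1.0             # density dependence (1 / biomass units)
    gamma: float = 0.5            # sensitivity to environmental forcing
    phi: float = 0.7              # AR(1) coefficient of the forcing
    sigma_process: float = 0.3    # lognormal process noise sd (log scale)
    survival: float = 0.7         # annual adult survival
    recruit_weight: float = 0.3   # biomass contribution per recruit
    harvest_mean: float = 0.2     # long-run mean harvest rate
    harvest_sd: float = 0.05      # innovation sd of the harvest walk
    n_years: int = 60
    burn_in: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not -1 < self.phi < 1:
            raise ValueError("phi must lie in (-1, 1)")
        if not 0 <= self.survival < 1:
            raise ValueError("survival must lie in [0, 1)")
        if self.recruit_weight <= 0:
            raise ValueError("recruit_weight must be positive")
        if self.sigma_process < 0 or self.harvest_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if self.n_years < 1 or self.burn_in < 0:
            raise ValueError("n_years >= 1 and burn_in >= 0 required")


#: Deterministic chaotic regime of the recruitment skeleton, used to probe
#: nonlinearity detection: no forcing, no noise, no adult carry-over, so the
#: update collapses to the classic Ricker map S_{t+1} = R_t = 20 S_t e^{-S_t},
#: whose growth factor (ln 20 ~ 3.0) lies beyond the period-doubling cascade.
CHAOTIC_PRESET = OperatingModelParams(
    alpha=20.0,
    beta=1.0,
    gamma=0.0,
    sigma_process=0.0,
    survival=0.0,
    recruit_weight=1.0,
    harvest_mean=0.0,
    harvest_sd=0.0,
)


@dataclass
class SyntheticStock:
    """Latent truth plus its two observation products and full provenance."""

    truth: StockRecruitSeries
    direct: StockRecruitSeries
    filtered: StockRecruitSeries | None
    provenance: dict = field(default_factory=dict)


def simulate_truth(params: OperatingModelParams) -> StockRecruitSeries:
    """Simulate the latent (noise-free observation) spawner-recruit record.

    Runs ``burn_in`` years from a fixed initial state, then records
    ``n_years`` of strictly positive (S, R). Raises
    :class:`UnstableParametersError`, naming the offending year, if the
    population collapses toward zero or diverges.
    """
    rng = np.random.default_rng(params.seed)
    total = params.burn_in + params.n_years
    S = np.empty(total)
    R = np.empty(total)
    s = 1.0 / params.beta  # start near the density-dependence scale
    E = 0.0
    h = params.harvest_mean
    for t in range(total):
        eps = rng.normal(0.0, params.sigma_process) if params.sigma_process else 0.0
        r = params.alpha * s * np.exp(-params.beta * s + params.gamma * E + eps)
        S[t], R[t] = s, r
        s = params.survival * (1.0 - h) * s + params.recruit_weight * r
        if not np.isfinite(s) or s < 1e-8 or s > 1e8:
            raise UnstableParametersError(
                f"population left [1e-8, 1e8] in simulation year {t} (S={s:.3g})"
            )
        E = params.phi * E + np.sqrt(1.0 - params.phi**2) * rng.normal()
        h_next = (
            params.harvest_mean
            + HARVEST_REVERSION * (h - params.harvest_mean)
            + (rng.normal(0.0, params.harvest_sd) if params.harvest_sd else 0.0)
        )
        h = float(np.clip(h_next, *HARVEST_BOUNDS))
    keep = slice(params.burn_in, total)
    years = np.arange(FIRST_YEAR, FIRST_YEAR + params.n_years)
    return StockRecruitSeries(
        stock_id="truth",
        species="synthetic",
        years=years,
        S=S[keep],
        R=R[keep],
        assessment_method="unknown",
        data_class=None,
    )


def make_direct_data(
    truth: StockRecruitSeries, sigma_obs: float, seed: int
) -> StockRecruitSeries:
    """Observe the truth through independent lognormal noise (class DD)."""
    if sigma_obs < 0:
        raise ValueError("sigma_obs must be non-negative")
    rng = np.random.default_rng(seed)
    noise_S = np.exp(rng.normal(0.0, sigma_obs, truth.n_years)) if sigma_obs else 1.0
    noise_R = np.exp(rng.normal(0.0, sigma_obs, truth.n_years)) if sigma_obs else 1.0
    return truth.copy_with(
        S=truth.S * noise_S,
        R=truth.R * noise_R,
        assessment_method="DO",
        data_class="DD",
    )


def make_filtered_data(
    direct: StockRecruitSeries,
    srr_kind: str = "beverton_holt",
    residual_retention: float = 0.3,
    smooth_window: int = 3,
) -> StockRecruitSeries:
    """Re-express a direct series through a fitted stock-recruitment curve (SD).

    Spawner biomass is replaced by a centered moving average; a
    stock-recruitment model of kind ``srr_kind`` is fitted to the direct
    (S, R) pairs, and recruitment becomes the curve's prediction at the
    smoothed S times ``exp(lambda * r_t)``, where ``r_t`` is the fit's
    log-scale residual and ``lambda = residual_retention`` in [0, 1]. At
    lambda = 1 with no smoothing the direct record is reconstructed exactly;
    at lambda = 0 every point lies on the fitted curve.
    """
    if not 0.0 <= residual_retention <= 1.0:
        raise ValueError("residual_retention must lie in [0, 1]")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    if direct.n_years < 25:
        raise ValueError("filtered data requires >= 25 years of direct data")
    params = fit_srr(srr_kind, direct.S, direct.R)
    log_resid = np.log(direct.R) - np.log(predict_srr(params, direct.S))
    S_smooth = (
        pd.Series(direct.S)
        .rolling(smooth_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    R_filtered = predict_srr(params, S_smooth) * np.exp(residual_retention * log_resid)
    return direct.copy_with(
        S=S_smooth,
        R=R_filtered,
        assessment_method="BDM",
        data_class="SD",
    )


def _jittered(base: OperatingModelParams, rng: np.random.Generator, seed: int, n_years: int) -> OperatingModelParams:
    """Per-stock parameter variation around the base operating model."""
    return replace(
        base,
        alpha=base.alpha * float(np.exp(rng.normal(0.0, 0.15))),
        beta=base.beta * float(np.exp(rng.normal(0.0, 0.2))),
        gamma=base.gamma * float(np.exp(rng.normal(0.0, 0.2))),
        harvest_mean=float(np.clip(base.harvest_mean + rng.normal(0.0, 0.05), 0.0, 0.5)),
        n_years=n_years,
        seed=seed,
    )


def generate_ensemble(
    n_sd: int,
    n_dd: int,
    base_params: OperatingModelParams | None = None,
    seed: int = 0,
    *,
    sigma_obs: float = 0.2,
    srr_kind: str = "beverton_holt",
    residual_retention: float = 0.3,
    smooth_window: int = 3,
    year_range: tuple[int, int] = (25, 60),
    max_retries: int = 10,
) -> list[SyntheticStock]:
    """Generate a mixed ensemble of SD and DD stocks with known provenance.

    The first ``n_sd`` stocks are passed through :func:`make_filtered_data`
    (class SD), the rest through :func:`make_direct_data` only (class DD).
    Each stock gets independently jittered operating-model parameters, a
    series length drawn uniformly from ``year_range``, and a derived seed;
    unstable parameter draws are retried a bounded number of times.
    """
    if n_sd < 0 or n_dd < 0:
        raise ValueError("stock counts must be non-negative")
    base = base_params or OperatingModelParams()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_sd + n_dd)
    stocks: list[SyntheticStock] = []
    for i, child in enumerate(children):
        is_sd = i < n_sd
        label = f"{'SD' if is_sd else 'DD'}_{i:03d}"
        rng = np.random.default_rng(child)
        truth = None
        for attempt in range(max_retries):
            n_years = int(rng.integers(year_range[0], year_range[1] + 1))
            sim_seed = int(rng.integers(0, 2**31 - 1))
            params = _jittered(base, rng, sim_seed, n_years)
            try:
                truth = simulate_truth(params)
                break
            except UnstableParametersError as exc:
                logger.warning("%s: unstable draw %d (%s); redrawing", label, attempt, exc)
        if truth is None:
            raise UnstableParametersError(
                f"{label}: no stable parameters after {max_retries} draws"
            )
        truth = truth.copy_with(stock_id=label)
        obs_seed = int(rng.integers(0, 2**31 - 1))
        direct = make_direct_data(truth, sigma_obs, obs_seed)
        filtered = None
        if is_sd:
            filtered = make_filtered_data(
                direct, srr_kind, residual_retention, smooth_window
            )
        stocks.append(
            SyntheticStock(
                truth=truth,
                direct=direct,
                filtered=filtered,
                provenance={
                    "stock_id": label,
                    "class": "SD" if is_sd else "DD",
                    "params": {
                        k: getattr(params, k)
                        for k in OperatingModelParams.__dataclass_fields__
                    },
                    "sigma_obs": sigma_obs,
                    "obs_seed": obs_seed,
                    "srr_kind": srr_kind if is_sd else None,
                    "residual_retention": residual_retention if is_sd else None,
                    "smooth_window": smooth_window if is_sd else None,
                },
            )
        )
    return stocks


def ensemble_series(stocks: list[SyntheticStock]) -> list[StockRecruitSeries]:
    """The observation product of each stock: filtered for SD, direct for DD."""
    return [s.filtered if s.filtered is not None else s.direct for s in stocks]
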