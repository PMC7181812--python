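"""Multivariate delay embedding and S-map locally weighted forecasting.

The state space is reconstructed from lagged copies of recruitment R and
spawner biomass S — the six candidate coordinates R_t, R_{t-1}, R_{t-2},
S_t, S_{t-1}, S_{t-2} — and every non-empty subset (63 embeddings) is tried.
Forecasts use the S-map: for each predictee, library points are weighted by
w_i = exp(-theta * d_i / d_mean) with d_i the Euclidean distance in the
(z-scored) embedding space, and a weighted linear regression with intercept
is solved by a rank-tolerant least-squares factorization. theta = 0 recovers
a single global linear map; improvement at theta > 0 indicates
state-dependence (nonlinearity) of the dynamics. Skill is the maximum
Pearson rho over embeddings and theta under leave-one-out exclusion of the
predicted point.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .crossval import UndefinedSkillError, pearson_rho
from .series import StockRecruitSeries

logger = logging.getLogger(__name__)

#: The candidate embedding coordinates, in canonical order.
CANDIDATE_COORDS: tuple[tuple[str, int], ...] = (
    ("R", 0), ("R", 1), ("R", 2), ("S", 0), ("S", 1), ("S", 2),
)

#: Default theta grid: the conventional S-map localization grid.
DEFAULT_THETA_GRID: tuple[float, ...] = (
    0.0, 1e-4, 3e-4, 1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3, 0.5,
    0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
)

#: Singular-value cutoff for the rank-tolerant least-squares solve.
LSTSQ_RCOND = 1e-10


class EmbeddingError(ValueError):
    """Raised when a series cannot support the requested embedding."""


@dataclass(frozen=True)
class EmbeddingSpec:
    """An ordered set of (variable, lag) coordinates forming the state space."""

    coordinates: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.coordinates:
            raise ValueError("embedding must have at least one coordinate")
        if len(set(self.coordinates)) != len(self.coordinates):
            raise ValueError("duplicate (variable, lag) coordinates")
        for var, lag in self.coordinates:
            if (var, lag) not in CANDIDATE_COORDS:
                raise ValueError(f"unknown coordinate {(var, lag)!r}")

    @property
    def max_lag(self) -> int:
        return max(lag for _, lag in self.coordinates)

    @property
    def dimension(self) -> int:
        return len(self.coordinates)

    def __str__(self) -> str:
        return "+".join(f"{v}(t-{l})" if l else f"{v}(t)" for v, l in self.coordinates)


@dataclass
class SMapConfig:
    """S-map evaluation settings: theta grid, metric, and normalization."""

    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID
    distance: str = "euclidean"
    normalize: bool = True

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.theta_grid)
        if 0.0 not in grid:
            raise ValueError("theta_grid must contain 0")
        if any(t < 0 for t in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("theta_grid must be non-negative and strictly increasing")
        if self.distance != "euclidean":
            raise ValueError("only the Euclidean metric is supported")
        self.theta_grid = grid


@dataclass
class DelayBlock:
    """Aligned predictor/target rows for one embedding and forecast horizon."""

    X: np.ndarray            # (n_rows, dimension) predictor matrix
    y: np.ndarray            # (n_rows,) target: R at base time + horizon
    base_times: np.ndarray   # (n_rows,) base index t of each row
    spec: EmbeddingSpec
    horizon: int

    @property
    def target_times(self) -> np.ndarray:
        return self.base_times + self.horizon

    @property
    def n_rows(self) -> int:
        return len(self.y)


@dataclass
class EdmResult:
    """Best embedding, theta, and skill for one stock."""

    stock_id: str
    best_spec: EmbeddingSpec
    best_theta: float
    rho: float
    target_times: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    n_specs_evaluated: int
    skipped_specs: list = field(default_factory=list)


def enumerate_embeddings(*, include_lag0_R: bool = True) -> list[EmbeddingSpec]:
    """All non-empty subsets of the candidate coordinates (63 embeddings).

    With ``include_lag0_R=False`` (concurrent forecasting, horizon 0) the
    subsets of the remaining five coordinates are returned instead, so the
    predictee never appears among its own predictors.
    """
    coords = [c for c in CANDIDATE_COORDS if include_lag0_R or c != ("R", 0)]
    specs = []
    for r in range(1, len(coords) + 1):
        for combo in itertools.combinations(coords, r):
            specs.append(EmbeddingSpec(combo))
    return specs


def build_block(
    series: StockRecruitSeries, spec: EmbeddingSpec, horizon: int = 1
) -> DelayBlock:
    """Assemble the delay-coordinate block for one embedding.

    One row per base time ``t`` such that every coordinate ``t - lag`` and the
    target ``t + horizon`` fall inside the series; rows are in time order.
    """
    n = series.n_years
    lo = spec.max_lag
    hi = n - horizon  # base times are [lo, hi)
    if hi <= lo:
        raise EmbeddingError(
            f"series of length {n} too short for max lag {spec.max_lag} "
            f"and horizon {horizon}"
        )
    base = np.arange(lo, hi)
    cols = []
    for var, lag in spec.coordinates:
        src = series.R if var == "R" else series.S
        cols.append(src[base - lag])
    return DelayBlock(
        X=np.column_stack(cols),
        y=series.R[base + horizon],
        base_times=base,
        spec=spec,
        horizon=horizon,
    )


def _solve_weighted(Xa: np.ndarray, y: np.ndarray, w: np.ndarray, xa: np.ndarray) -> float:
    """Weighted least squares at one predictee; rank-tolerant, min-norm."""
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(Xa * sw[:, None], y * sw, rcond=LSTSQ_RCOND)
    if rank == 0 or not np.all(np.isfinite(coef)):
        # Degenerate design: fall back to the weighted mean of the targets.
        logger.debug("degenerate design matrix; using weighted mean fallback")
        return float(np.average(y, weights=w))
    return float(xa @ coef)


def _predict_grid(
    block: DelayBlock,
    target_row: int,
    library: np.ndarray,
    theta_grid: tuple[float, ...],
    normalize: bool,
) -> np.ndarray:
    """S-map predictions for one predictee across the whole theta grid.

    Distances (and the library z-scoring) are computed once; only the weights
    and the weighted solve vary with theta.
    """
    Xl = block.X[library]
    yl = block.y[library]
    xq = block.X[target_row]
    if normalize:
        mu = Xl.mean(axis=0)
        sd = Xl.std(axis=0)
        sd[sd == 0] = 1.0  # constant column: contributes nothing to distance
        Xl = (Xl - mu) / sd
        xq = (xq - mu) / sd
    diff = Xl - xq
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    dbar = d.mean()
    Xa = np.column_stack([np.ones(len(library)), Xl])
    xa = np.concatenate([[1.0], xq])
    out = np.empty(len(theta_grid))
    for i, theta in enumerate(theta_grid):
        if theta == 0.0 or dbar == 0.0:
            w = np.ones_like(d)
        else:
            w = np.exp(-theta * d / dbar)
        out[i] = _solve_weighted(Xa, yl, w, xa)
    return out


def smap_predict(
    block: DelayBlock,
    theta: float,
    target_row: int,
    library: np.ndarray,
    *,
    normalize: bool = True,
) -> float:
    """S-map forecast of one row's target from a library of other rows."""
    library = np.asarray(library, dtype=int)
    if len(library) == 0:
        raise ValueError("empty library")
    if target_row in library:
        raise ValueError("target row must not be in its own library")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return float(
        _predict_grid(block, target_row, library, (float(theta),), normalize)[0]
    )


def _libraries_for(
    block: DelayBlock,
    target_rows: np.ndarray,
    library_mode: str,
    training_times: dict[int, np.ndarray] | None,
) -> list[np.ndarray]:
    """Library rows per target: full leave-one-out or the matched 24-point set."""
    all_rows = np.arange(block.n_rows)
    libs = []
    for row in target_rows:
        if library_mode == "loo":
            libs.append(all_rows[all_rows != row])
        elif library_mode == "matched":
            if training_times is None:
                raise ValueError("matched mode requires per-target training times")
            ttimes = training_times[int(block.target_times[row])]
            mask = np.isin(block.target_times, ttimes)
            mask[row] = False
            libs.append(all_rows[mask])
        else:
            raise ValueError(f"unknown library mode {library_mode!r}")
    return libs


def loo_smap_rho(
    block: DelayBlock,
    theta: float,
    target_rows: np.ndarray,
    *,
    library_mode: str = "loo",
    training_times: dict[int, np.ndarray] | None = None,
    normalize: bool = True,
) -> tuple[float, np.ndarray]:
    """Leave-one-out S-map skill at a single theta.

    Each target row is predicted from a library that excludes it; returns the
    Pearson rho over (observed, predicted) and the predictions.
    """
    target_rows = np.asarray(target_rows, dtype=int)
    if len(target_rows) == 0:
        raise ValueError("no target rows")
    libs = _libraries_for(block, target_rows, library_mode, training_times)
    preds = np.array(
        [
            _predict_grid(block, row, lib, (float(theta),), normalize)[0]
            for row, lib in zip(target_rows, libs)
        ]
    )
    rho = pearson_rho(block.y[target_rows], preds)
    return rho, preds


def _rho_over_grid(
    block: DelayBlock,
    target_rows: np.ndarray,
    config: SMapConfig,
    library_mode: str = "loo",
    training_times: dict[int, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """rho per theta and the (n_theta, n_targets) prediction matrix."""
    libs = _libraries_for(block, target_rows, library_mode, training_times)
    preds = np.empty((len(config.theta_grid), len(target_rows)))
    for j, (row, lib) in enumerate(zip(target_rows, libs)):
        preds[:, j] = _predict_grid(
            block, row, lib, config.theta_grid, config.normalize
        )
    obs = block.y[target_rows]
    rhos = np.full(len(config.theta_grid), np.nan)
    for i in range(len(config.theta_grid)):
        try:
            rhos[i] = pearson_rho(obs, preds[i])
        except UndefinedSkillError:
            pass
    return rhos, preds


def optimize_theta(
    block: DelayBlock,
    target_rows: np.ndarray,
    config: SMapConfig | None = None,
    **kwargs,
) -> tuple[float, float]:
    """Grid-maximize leave-one-out rho over theta; ties go to the smallest theta."""
    config = config or SMapConfig()
    rhos, _ = _rho_over_grid(block, np.asarray(target_rows, dtype=int), config, **kwargs)
    if np.all(np.isnan(rhos)):
        raise UndefinedSkillError("rho undefined at every theta")
    best = int(np.nanargmax(rhos))  # first occurrence = smallest theta on ties
    return config.theta_grid[best], float(rhos[best])


def best_edm_rho(
    series: StockRecruitSeries,
    config: SMapConfig | None = None,
    *,
    target_times: np.ndarray | None = None,
    horizon: int = 1,
    library_mode: str = "loo",
    training_times: dict[int, np.ndarray] | None = None,
    min_valid_targets: int = 20,
) -> EdmResult:
    """Maximize leave-one-out skill over all embeddings and theta for one stock.

    ``target_times`` are series indices of the years whose recruitment is
    predicted (shared with the stock-recruitment-model protocol so method
    comparisons are paired within stock); embeddings that cannot represent at
    least ``min_valid_targets`` of them are skipped and reported.
    """
    config = config or SMapConfig()
    specs = enumerate_embeddings(include_lag0_R=horizon != 0)
    if target_times is None:
        max_lag = max(lag for _, lag in CANDIDATE_COORDS)
        target_times = np.arange(max_lag + horizon, series.n_years)
    target_times = np.asarray(target_times, dtype=int)

    best = None  # (rho, spec_index, theta_index, rows, preds_row)
    skipped: list[tuple[str, str]] = []
    n_evaluated = 0
    for si, spec in enumerate(specs):
        try:
            block = build_block(series, spec, horizon)
        except EmbeddingError as exc:
            skipped.append((str(spec), str(exc)))
            continue
        # Map requested target times onto this block's rows.
        pos = {int(t): i for i, t in enumerate(block.target_times)}
        rows = np.array([pos[t] for t in target_times if int(t) in pos], dtype=int)
        if len(rows) < min_valid_targets:
            skipped.append((str(spec), f"only {len(rows)} representable targets"))
            continue
        if len(block.y) - 1 < block.X.shape[1] + 2:
            skipped.append((str(spec), "library smaller than dimension + 2"))
            continue
        rhos, preds = _rho_over_grid(
            block, rows, config, library_mode=library_mode, training_times=training_times
        )
        n_evaluated += 1
        if np.all(np.isnan(rhos)):
            skipped.append((str(spec), "rho undefined at every theta"))
            continue
        ti = int(np.nanargmax(rhos))
        if best is None or rhos[ti] > best[0]:
            best = (float(rhos[ti]), si, ti, rows, preds[ti], block)
    if best is None:
        raise EmbeddingError(
            f"{series.stock_id}: no embedding admitted "
            f">= {min_valid_targets} evaluation targets"
        )
    for spec_name, reason in skipped:
        logger.debug("%s: skipped %s (%s)", series.stock_id, spec_name, reason)
    rho, si, ti, rows, preds, block = best
    return EdmResult(
        stock_id=series.stock_id,
        best_spec=specs[si],
        best_theta=config.theta_grid[ti],
        rho=rho,
        target_times=block.target_times[rows],
        observed=block.y[rows],
        predicted=preds,
        n_specs_evaluated=n_evaluated,
        skipped_specs=skipped,
    )
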