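"""Randomized 25-target leave-one-out evaluation protocol and the skill metric.

Forecast skill is the Pearson correlation (rho) between observed and predicted
recruitment at 25 evaluation targets per stock. For a series of exactly 25
years every point is a target and each fit uses the other 24; for longer
series, 25 targets are drawn uniformly without replacement and each fit uses
the point one step before the target plus 23 further random points, so every
model sees exactly 24 training observations regardless of series length.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .series import StockRecruitSeries
from .srr import SRRFitError, fit_srr, predict_srr

logger = logging.getLogger(__name__)

#: Below this many successfully evaluated targets a stock-model cell is
#: flagged unusable.
MIN_SUCCESSFUL_TARGETS = 20


class ProtocolError(ValueError):
    """Raised when a series cannot be evaluated under the protocol."""


class UndefinedSkillError(ValueError):
    """Raised when Pearson rho is undefined (zero variance or too few pairs)."""


@dataclass(frozen=True)
class EvaluationProtocol:
    """Constants of the randomized leave-one-out design."""

    n_targets: int = 25
    n_training: int = 24
    include_predecessor: bool = True

    def __post_init__(self) -> None:
        if self.n_targets < 3:
            raise ValueError("n_targets must be >= 3")
        if self.n_training < 2:
            raise ValueError("n_training must be >= 2")


@dataclass
class PredictionResult:
    """Observed vs. predicted recruitment at the evaluation targets."""

    stock_id: str
    method: str
    data_class: str | None
    target_times: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    rho: float
    n_targets_used: int
    usable: bool = True
    notes: list = field(default_factory=list)


def stock_rng(root_seed: int, stock_id: str) -> np.random.Generator:
    """Per-stock RNG stream derived from a root seed and a stable id hash.

    Streams are independent across stocks, so adding or removing one stock
    never reshuffles the draws of another.
    """
    tag = zlib.crc32(stock_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, tag]))


def pearson_rho(observed, predicted) -> float:
    """Pearson product-moment correlation between observations and predictions.

    Raises :class:`UndefinedSkillError` when either input has zero variance or
    fewer than 3 pairs, rather than silently returning 0.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-d arrays of equal length")
    if len(obs) < 3:
        raise UndefinedSkillError(f"need >= 3 pairs, got {len(obs)}")
    do = obs - obs.mean()
    dp = pred - pred.mean()
    denom = np.sqrt((do @ do) * (dp @ dp))
    if denom == 0 or not np.isfinite(denom):
        raise UndefinedSkillError("zero variance in observed or predicted values")
    return float(np.clip((do @ dp) / denom, -1.0, 1.0))


def select_targets(
    series_length: int, protocol: EvaluationProtocol, rng: np.random.Generator
) -> np.ndarray:
    """Choose the evaluation target indices (0-based) for one stock.

    All points are targets when the series has exactly ``n_targets`` points;
    otherwise ``n_targets`` indices are drawn uniformly without replacement.
    """
    if series_length < protocol.n_targets:
        raise ProtocolError(
            f"series length {series_length} below the minimum of {protocol.n_targets}"
        )
    if series_length == protocol.n_targets:
        return np.arange(series_length)
    return np.sort(rng.choice(series_length, size=protocol.n_targets, replace=False))


def training_set(
    target: int,
    series_length: int,
    protocol: EvaluationProtocol,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices used to fit model parameters when predicting ``target``.

    Contains the point one step before the target (when it exists), never the
    target itself, topped up with uniformly drawn points to ``n_training``
    total. A length-(n_training + 1) series degenerates to classical
    leave-one-out: all non-target points.
    """
    if not 0 <= target < series_length:
        raise ProtocolError(f"target {target} outside series of length {series_length}")
    others = np.setdiff1d(np.arange(series_length), [target])
    if len(others) <= protocol.n_training:
        return others
    fixed = []
    if protocol.include_predecessor and target - 1 >= 0:
        fixed = [target - 1]
    pool = np.setdiff1d(others, fixed)
    extra = rng.choice(pool, size=protocol.n_training - len(fixed), replace=False)
    return np.sort(np.concatenate([fixed, extra]).astype(int))


def loocv_sfm(
    series: StockRecruitSeries,
    model_kind: str,
    protocol: EvaluationProtocol,
    rng: np.random.Generator,
    *,
    targets: np.ndarray | None = None,
    training_sets: dict[int, np.ndarray] | None = None,
) -> PredictionResult:
    """Evaluate one stock-recruitment model on one stock under the protocol.

    For each target, the model is refitted on that target's 24-point training
    set and recruitment is predicted from the target year's S on the original
    scale. ``targets`` and ``training_sets`` may be supplied to share the
    design across methods (paired comparisons); otherwise they are drawn from
    ``rng``.
    """
    n = series.n_years
    if targets is None:
        targets = select_targets(n, protocol, rng)
    notes: list[str] = []
    obs, pred, used_times = [], [], []
    for t in targets:
        t = int(t)
        if training_sets is not None:
            train = training_sets[t]
        else:
            train = training_set(t, n, protocol, rng)
        if series.S[t] <= 0 or series.R[t] <= 0:
            notes.append(f"target {t}: nonpositive S or R, skipped")
            continue
        try:
            params = fit_srr(model_kind, series.S[train], series.R[train])
            pred.append(float(predict_srr(params, float(series.S[t]))))
        except (SRRFitError, ValueError) as exc:
            notes.append(f"target {t}: fit failed ({exc})")
            continue
        obs.append(float(series.R[t]))
        used_times.append(t)
    for msg in notes:
        logger.warning("%s [%s/%s]: %s", series.stock_id, model_kind, "sfm", msg)
    obs = np.asarray(obs)
    pred = np.asarray(pred)
    usable = len(obs) >= MIN_SUCCESSFUL_TARGETS
    try:
        rho = pearson_rho(obs, pred) if usable else float("nan")
    except UndefinedSkillError as exc:
        notes.append(f"rho undefined: {exc}")
        rho, usable = float("nan"), False
    return PredictionResult(
        stock_id=series.stock_id,
        method=model_kind,
        data_class=series.data_class,
        target_times=np.asarray(used_times, dtype=int),
        observed=obs,
        predicted=pred,
        rho=rho,
        n_targets_used=len(obs),
        usable=usable,
        notes=notes,
    )
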