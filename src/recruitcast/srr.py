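"""Standard stock-recruitment models: density-independent, Ricker, Beverton-Holt.

All three models share the form ``R = alpha * S * g(S)`` with ``alpha`` the
maximum rate of reproduction and ``g`` a density-dependence term:

* density-independent: ``g(S) = 1``
* Ricker:              ``g(S) = exp(-beta * S)``
* Beverton-Holt:       ``g(S) = 1 / (1 + beta * S)``

The Ricker and Beverton-Holt models are fitted on the log scale via the
survival ratio ``y = ln(R / S)``; the density-independent model is fitted by
closed-form least squares on the original scale (a log-scale variant is
available behind a flag). Predictions are always returned on the original
recruitment scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

MODEL_KINDS = ("density_independent", "ricker", "beverton_holt")

# Deterministic multi-start offsets, in (ln alpha, ln beta) space, applied to
# the Ricker-derived initial guess for the Beverton-Holt simplex search.
_BH_START_OFFSETS = (
    (0.0, 0.0),
    (0.7, 0.0),
    (-0.7, 0.0),
    (0.0, 1.0),
    (0.0, -1.0),
)


class SRRFitError(RuntimeError):
    """Raised when a stock-recruitment fit is impossible or fails to converge."""


@dataclass(frozen=True)
class SRRParams:
    """Fitted stock-recruitment parameters.

    ``beta`` is ``None`` for the density-independent model. The closed-form
    Ricker fit is an unconstrained regression, so its ``beta`` may come out
    negative on noisy data (inverse density dependence); Beverton-Holt is
    optimized in log space and its ``beta`` is always positive.
    """

    model_kind: str
    alpha: float
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.model_kind == "density_independent":
            if self.beta is not None:
                raise ValueError("density_independent has no beta")
        else:
            if self.beta is None or not np.isfinite(self.beta):
                raise ValueError(f"{self.model_kind} requires a finite beta")


def _validate_pairs(S, R) -> tuple[np.ndarray, np.ndarray]:
    S = np.asarray(S, dtype=float)
    R = np.asarray(R, dtype=float)
    if S.shape != R.shape or S.ndim != 1:
        raise ValueError("S and R must be 1-d arrays of equal length")
    valid = np.isfinite(S) & np.isfinite(R) & (S > 0) & (R > 0)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("excluding %d pair(s) with nonpositive or non-finite S/R", n_bad)
    if not valid.any():
        raise SRRFitError("no usable (S, R) pairs: all invalid")
    return S[valid], R[valid]


def log_survival_ratio(S, R) -> np.ndarray:
    """Log survival ratio ``y = ln(R / S)`` over the valid pairs.

    Pairs with nonpositive S or R are excluded (the log is undefined there);
    the returned array is aligned with the retained pairs.
    """
    S, R = _validate_pairs(S, R)
    return np.log(R / S)


def fit_srr(model_kind: str, S, R, *, di_log_scale: bool = False) -> SRRParams:
    """Fit a stock-recruitment model to (S, R) pairs.

    Parameters
    ----------
    model_kind
        ``density_independent``, ``ricker`` or ``beverton_holt``.
    S, R
        Spawner and recruit observations; nonpositive pairs are dropped.
    di_log_scale
        Fit the density-independent model on the log scale (``ln alpha`` =
        mean of ``y``) instead of the default original-scale least squares.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    S, R = _validate_pairs(S, R)
    if len(S) < 3:
        raise SRRFitError(f"need >= 3 valid pairs, got {len(S)}")
    if model_kind != "density_independent" and np.ptp(S) == 0:
        raise SRRFitError("degenerate S (all values equal): cannot estimate beta")

    y = np.log(R / S)

    if model_kind == "density_independent":
        if di_log_scale:
            alpha = float(np.exp(np.mean(y)))
        else:
            alpha = float(np.sum(R * S) / np.sum(S * S))
        return SRRParams("density_independent", alpha)

    if model_kind == "ricker":
        # y = ln(alpha) - beta * S: simple linear regression, closed form.
        slope, intercept = np.polyfit(S, y, 1)
        beta = float(-slope)
        if beta < 0:
            logger.warning("Ricker fit gave beta=%.4g < 0 (inverse density dependence)", beta)
        return SRRParams("ricker", float(np.exp(intercept)), beta)

    # Beverton-Holt: y = ln(alpha) - ln(1 + beta * S), minimized over
    # (ln alpha, ln beta) by Nelder-Mead from a Ricker-derived start plus
    # deterministic perturbations.
    slope, intercept = np.polyfit(S, y, 1)
    # For small beta*S, ln(1 + beta*S) ~ beta*S, so the Ricker slope seeds beta.
    beta0 = -slope if -slope > 0 else 1.0 / float(np.median(S))
    x0 = np.array([intercept, np.log(beta0)])

    def objective(params: np.ndarray) -> float:
        ln_a, ln_b = params
        resid = y - (ln_a - np.log1p(np.exp(ln_b) * S))
        return float(resid @ resid)

    best = None
    for da, db in _BH_START_OFFSETS:
        res = minimize(
            objective,
            x0 + [da, db],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise SRRFitError("Beverton-Holt optimization failed for all starts")
    ln_a, ln_b = best.x
    return SRRParams("beverton_holt", float(np.exp(ln_a)), float(np.exp(ln_b)))


def predict_srr(params: SRRParams, S) -> np.ndarray | float:
    """Predicted recruitment at spawner abundance ``S``, original scale."""
    scalar = np.isscalar(S)
    S = np.asarray(S, dtype=float)
    if np.any(S <= 0) or not np.all(np.isfinite(S)):
        raise ValueError("S must be positive and finite")
    if params.model_kind == "density_independent":
        out = params.alpha * S
    elif params.model_kind == "ricker":
        out = params.alpha * S * np.exp(-params.beta * S)
    else:
        out = params.alpha * S / (1.0 + params.beta * S)
    return float(out) if scalar else out
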