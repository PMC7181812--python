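"""Per-stock spawner-recruit time series container.

A stock's record is an annual, gap-free sequence of spawning stock biomass
``S`` and recruitment ``R``, tagged with the assessment method that produced
it (BDM, SPA, DO, SCA) and, once classified, with a data class:

* ``SD`` ("synthetic data") -- series reconstructed by an assessment model
  that embeds an explicit stock-recruitment relationship.
* ``DD`` ("direct data") -- survey observations or statistically denoised
  estimates produced without such an assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Minimum joint (S, R) coverage, in years, for a stock to enter the analysis.
MIN_YEARS = 25


class SeriesValidationError(ValueError):
    """Raised when a stock record violates the series invariants."""


@dataclass
class StockRecruitSeries:
    """One stock's aligned yearly (S, R) record plus provenance labels.

    Parameters
    ----------
    stock_id
        Unique identifier of the stock.
    species
        Species name (free text; informational only).
    years
        Strictly increasing, consecutive calendar years.
    S
        Spawning stock biomass per year (stock units).
    R
        Recruitment per year (stock units).
    assessment_method
        One of ``BDM``, ``SPA``, ``DO``, ``SCA`` or ``unknown``.
    data_class
        ``SD``, ``DD`` or ``None`` (derived from the assessment method by
        :func:`recruitcast.comparison.classify_assessment`).
    """

    stock_id: str
    species: str
    years: np.ndarray
    S: np.ndarray
    R: np.ndarray
    assessment_method: str = "unknown"
    data_class: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.S = np.asarray(self.S, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        n = len(self.years)
        if len(self.S) != n or len(self.R) != n:
            raise SeriesValidationError(
                f"{self.stock_id}: years/S/R lengths differ "
                f"({n}/{len(self.S)}/{len(self.R)})"
            )
        if n == 0:
            raise SeriesValidationError(f"{self.stock_id}: empty series")
        if n > 1 and not np.all(np.diff(self.years) == 1):
            raise SeriesValidationError(
                f"{self.stock_id}: years must be strictly increasing with an "
                "annual step"
            )
        if not (np.all(np.isfinite(self.S)) and np.all(np.isfinite(self.R))):
            raise SeriesValidationError(f"{self.stock_id}: non-finite S or R")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pairs usable for log-scale fitting (S > 0, R > 0)."""
        return (self.S > 0) & (self.R > 0)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def includable(self, min_years: int = MIN_YEARS) -> bool:
        """Whether the stock meets the minimum-coverage inclusion rule."""
        return self.n_valid >= min_years

    def copy_with(self, **kwargs) -> "StockRecruitSeries":
        data = dict(
            stock_id=self.stock_id,
            species=self.species,
            years=self.years.copy(),
            S=self.S.copy(),
            R=self.R.copy(),
            assessment_method=self.assessment_method,
            data_class=self.data_class,
        )
        data.update(kwargs)
        return StockRecruitSeries(**data)
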