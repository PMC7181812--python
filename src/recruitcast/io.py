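"""Delimited stock tables, run configuration, and result writing.

Stock collections travel as long-format CSV: one row per stock-year with
columns ``stock_id, species, year, ssb, recruits, assessment_method``.
Runs are described by a serializable :class:`RunConfig` whose content hash
is embedded in the JSON run report, so any run is reproducible from its
report alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .comparison import ComparisonSummary
from .crossval import PredictionResult
from .series import SeriesValidationError, StockRecruitSeries

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("stock_id", "species", "year", "ssb", "recruits", "assessment_method")


@dataclass
class RunConfig:
    """Fully serializable description of one evaluation run."""

    seed: int = 0
    n_targets: int = 25
    n_training: int = 24
    theta_grid: tuple = tuple()
    horizon: int = 1
    library_mode: str = "loo"
    di_log_scale: bool = False
    methods: tuple = ("density_independent", "ricker", "beverton_holt", "edm")
    ensemble: dict = field(default_factory=dict)
    input_path: str | None = None
    output_path: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        data["theta_grid"] = tuple(data.get("theta_grid", ()))
        data["methods"] = tuple(data.get("methods", cls.methods))
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_stock_table(path: str | Path) -> tuple[list[StockRecruitSeries], list[tuple[str, str]]]:
    """Read a long-format stock-year CSV into per-stock series.

    Rows are grouped by ``stock_id`` and sorted by year. Stocks violating the
    series invariants are collected into the returned failure list; valid
    stocks are returned regardless.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    bad_numeric = df[["year", "ssb", "recruits"]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad_rows = bad_numeric.isna().any(axis=1) & df[["year", "ssb", "recruits"]].notna().any(axis=1)
    if bad_rows.any():
        lines = (df.index[bad_rows] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"non-numeric year/ssb/recruits at line(s) {lines}")
    df[["year", "ssb", "recruits"]] = bad_numeric

    series: list[StockRecruitSeries] = []
    failures: list[tuple[str, str]] = []
    for stock_id, grp in df.groupby("stock_id", sort=True):
        grp = grp.sort_values("year")
        try:
            series.append(
                StockRecruitSeries(
                    stock_id=str(stock_id),
                    species=str(grp["species"].iloc[0]),
                    years=grp["year"].to_numpy(dtype=int),
                    S=grp["ssb"].to_numpy(dtype=float),
                    R=grp["recruits"].to_numpy(dtype=float),
                    assessment_method=str(grp["assessment_method"].iloc[0]),
                )
            )
        except SeriesValidationError as exc:
            logger.warning("skipping stock %s: %s", stock_id, exc)
            failures.append((str(stock_id), str(exc)))
    return series, failures


def write_stock_table(stocks: list[StockRecruitSeries], path: str | Path) -> None:
    """Write per-stock series to the long-format CSV (inverse of the reader)."""
    frames = [
        pd.DataFrame(
            {
                "stock_id": s.stock_id,
                "species": s.species,
                "year": s.years,
                "ssb": s.S,
                "recruits": s.R,
                "assessment_method": s.assessment_method,
            }
        )
        for s in stocks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def write_results(
    summary: ComparisonSummary,
    results: list[PredictionResult],
    outdir: str | Path,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write the summary table, per-stock skill table, and JSON run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": outdir / "summary.csv",
        "per_stock": outdir / "per_stock_rho.csv",
        "report": outdir / "run_report.json",
    }
    summary.cells.reset_index().to_csv(paths["summary"], index=False, float_format="%.10g")
    summary.per_stock.sort_values(["stock_id", "method"]).to_csv(
        paths["per_stock"], index=False, float_format="%.10g"
    )
    config = config or RunConfig()
    report = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "tests": summary.tests.reset_index().replace({np.nan: None}).to_dict("records"),
        "skipped": summary.skipped,
        "n_results": len(results),
    }
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return paths


def read_summary(path: str | Path) -> pd.DataFrame:
    """Re-read a written summary table with its (method, data_class) index."""
    return pd.read_csv(path).set_index(["method", "data_class"]).sort_index()
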