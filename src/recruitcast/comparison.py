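"""Stock classification, batch evaluation, and the method-by-class skill summary.

Stocks are classified by the assessment method that produced their series:
biomass dynamic models (BDM) embed an explicit stock-recruitment curve and
yield class SD; sequential population analysis (SPA) and direct observation
(DO) do not and yield class DD; statistical catch-at-age (SCA) records are
excluded because their assumptions about the stock-recruitment relationship
are not documented. Each included stock is evaluated with the three
stock-recruitment models and with EDM on a shared target set, and the
results are summarized as mean rho +/- SE per (method x class) cell with a
Welch unpaired t-test of SD vs DD per method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crossval import (
    EvaluationProtocol,
    PredictionResult,
    UndefinedSkillError,
    loocv_sfm,
    pearson_rho,
    select_targets,
    stock_rng,
    training_set,
)
from .edm import SMapConfig, best_edm_rho
from .series import StockRecruitSeries

logger = logging.getLogger(__name__)

SFM_METHODS = ("density_independent", "ricker", "beverton_holt")
ALL_METHODS = SFM_METHODS + ("edm",)

_CLASS_BY_LABEL = {"BDM": "SD", "SPA": "DD", "DO": "DD", "SCA": "excluded"}


@dataclass
class ComparisonSummary:
    """Mean skill per (method x data class) plus per-method SD-vs-DD tests."""

    cells: pd.DataFrame   # index (method, data_class); columns mean_rho, se, n
    tests: pd.DataFrame   # index method; columns t_statistic, p_value, n_sd, n_dd
    per_stock: pd.DataFrame  # one row per (stock, method) with rho
    skipped: list = field(default_factory=list)


def classify_assessment(method_label: str) -> str:
    """Map an assessment-method label to a data class (SD, DD or excluded)."""
    cls = _CLASS_BY_LABEL.get(method_label)
    if cls is None:
        logger.warning("unknown assessment method %r: stock excluded", method_label)
        return "excluded"
    return cls


def evaluate_collection(
    stocks: list[StockRecruitSeries],
    config: SMapConfig | None = None,
    protocol: EvaluationProtocol | None = None,
    *,
    seed: int = 0,
    methods: tuple[str, ...] = ALL_METHODS,
    horizon: int = 1,
    library_mode: str = "loo",
) -> tuple[list[PredictionResult], list[tuple[str, str]]]:
    """Evaluate every includable stock with every requested method.

    Per stock, one target set and one family of training sets are drawn from
    that stock's RNG stream and shared across all methods, so comparisons are
    paired within stock. Excluded or failing stocks land in the skip list;
    per-stock failures never abort the batch.
    """
    config = config or SMapConfig()
    protocol = protocol or EvaluationProtocol()
    results: list[PredictionResult] = []
    skipped: list[tuple[str, str]] = []
    for series in stocks:
        cls = series.data_class or classify_assessment(series.assessment_method)
        if cls == "excluded":
            skipped.append((series.stock_id, f"assessment method {series.assessment_method!r} excluded"))
            continue
        if series.n_years < protocol.n_targets or not series.includable(protocol.n_targets):
            skipped.append(
                (series.stock_id, f"fewer than {protocol.n_targets} usable years")
            )
            continue
        series = series.copy_with(data_class=cls)
        rng = stock_rng(seed, series.stock_id)
        targets = select_targets(series.n_years, protocol, rng)
        training_sets = {
            int(t): training_set(int(t), series.n_years, protocol, rng)
            for t in targets
        }
        for method in methods:
            try:
                if method == "edm":
                    edm_res = best_edm_rho(
                        series,
                        config,
                        target_times=targets,
                        horizon=horizon,
                        library_mode=library_mode,
                        training_times={
                            t: series_times for t, series_times in training_sets.items()
                        },
                    )
                    results.append(
                        PredictionResult(
                            stock_id=series.stock_id,
                            method="edm",
                            data_class=cls,
                            target_times=edm_res.target_times,
                            observed=edm_res.observed,
                            predicted=edm_res.predicted,
                            rho=edm_res.rho,
                            n_targets_used=len(edm_res.observed),
                            usable=True,
                            notes=[
                                f"best_spec={edm_res.best_spec}",
                                f"best_theta={edm_res.best_theta}",
                            ],
                        )
                    )
                else:
                    results.append(
                        loocv_sfm(
                            series,
                            method,
                            protocol,
                            rng,
                            targets=targets,
                            training_sets=training_sets,
                        )
                    )
            except Exception as exc:  # noqa: BLE001 - isolate per-stock failures
                logger.warning("%s/%s failed: %s", series.stock_id, method, exc)
                skipped.append((series.stock_id, f"{method}: {exc}"))
    return results, skipped


def summarize(
    results: list[PredictionResult],
    *,
    pooled_variance: bool = False,
    skipped: list | None = None,
) -> ComparisonSummary:
    """Aggregate per-stock skill into the method-by-class table with t-tests.

    Cells need >= 2 stocks for a standard error and each method needs >= 2
    stocks per class for its Welch (or, optionally, pooled-variance) t-test;
    undersized statistics are reported as NaN. Stocks whose rho is undefined
    in a cell are dropped from that cell only.
    """
    rows = [
        {
            "stock_id": r.stock_id,
            "method": r.method,
            "data_class": r.data_class,
            "rho": r.rho,
            "n_targets_used": r.n_targets_used,
            "usable": r.usable,
        }
        for r in results
    ]
    per_stock = pd.DataFrame(rows)
    if per_stock.empty:
        raise ValueError("no results to summarize")
    ok = per_stock[per_stock["usable"] & per_stock["rho"].notna()]

    cell_rows = []
    for (method, cls), grp in ok.groupby(["method", "data_class"], sort=True):
        vals = grp["rho"].to_numpy()
        cell_rows.append(
            {
                "method": method,
                "data_class": cls,
                "mean_rho": float(np.mean(vals)),
                "se": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                if len(vals) >= 2
                else float("nan"),
                "n": len(vals),
            }
        )
    cells = pd.DataFrame(cell_rows).set_index(["method", "data_class"]).sort_index()

    test_rows = []
    for method, grp in ok.groupby("method"):
        sd = grp.loc[grp["data_class"] == "SD", "rho"].to_numpy()
        dd = grp.loc[grp["data_class"] == "DD", "rho"].to_numpy()
        if len(sd) >= 2 and len(dd) >= 2:
            t, p = stats.ttest_ind(sd, dd, equal_var=pooled_variance)
            t, p = float(t), float(p)
        else:
            t, p = float("nan"), float("nan")
        test_rows.append(
            {"method": method, "t_statistic": t, "p_value": p, "n_sd": len(sd), "n_dd": len(dd)}
        )
    tests = pd.DataFrame(test_rows).set_index("method").sort_index()
    return ComparisonSummary(
        cells=cells, tests=tests, per_stock=per_stock, skipped=list(skipped or [])
    )


def relative_skill_change(mean_sd: float, mean_dd: float) -> float:
    """Percent change in mean skill going from SD to DD: 100*(SD - DD)/SD.

    Positive values are a loss of skill on direct data; negative values an
    improvement.
    """
    if mean_sd == 0:
        raise ZeroDivisionError("mean skill on SD is zero; relative change undefined")
    return 100.0 * (mean_sd - mean_dd) / mean_sd


def recompute_rho(result: PredictionResult) -> float:
    """Recompute Pearson rho from a result's stored pairs (consistency check)."""
    try:
        return pearson_rho(result.observed, result.predicted)
    except UndefinedSkillError:
        return float("nan")
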