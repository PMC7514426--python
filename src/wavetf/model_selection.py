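"""Goodness-of-fit metrics and the filter x resolution-level grid search.

Candidate time-varying models are compared over a grid of Daubechies filter
orders (1..10) crossed with resolution-level subsets.  The default level grid
is every non-empty subset of levels {1..5} — 31 combinations, hence 310
candidate fits per transfer function with all ten filters.  Each candidate is
scored on a six-metric panel (RMSE, MAE, R^2, Pearson, Spearman, Kendall) for
the fit phase and, where a held-out window is supplied, the forecast phase.

Selection needs a total order: "minimise RMSE and MAE while maximising R"
does not define one, so the default rule is lexicographic — maximise fit-phase
R^2, break ties by smaller MAE, then smaller level set, then lower filter
order — and every candidate's panel is retained so any other rule can be
re-applied offline.  Forecast-phase metrics never participate in selection:
selecting on the held-out window would leak it into the model choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .wavelet_basis import WaveletBasisSpec
from . import wavelet_tf

__all__ = [
    "MetricPanel",
    "GridResult",
    "compute_metrics",
    "default_level_sets",
    "grid_search",
    "two_stage_grid_search",
]


@dataclass(frozen=True)
class MetricPanel:
    """Six-metric comparison of predicted against observed values."""

    rmse: float
    mae: float
    r2: float
    pearson: float
    spearman: float
    kendall: float
    phase: str = "fit"

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse, "mae": self.mae, "r2": self.r2,
            "pearson": self.pearson, "spearman": self.spearman,
            "kendall": self.kendall, "phase": self.phase,
        }


def compute_metrics(
    observed: Sequence[float], predicted: Sequence[float], phase: str = "fit"
) -> MetricPanel:
    """RMSE, MAE, R^2 and the three correlation coefficients.

    Fit-phase R^2 is 1 - SSE/SST.  Forecast-phase R^2 is the squared Pearson
    correlation between forecasts and held-out observations (the "variance
    explained" reading used when the forecast need not be mean-unbiased).
    Rank correlations use average ranks for ties.  Constant observed values
    leave R^2 undefined and raise.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-d of equal length")
    if len(obs) < 3:
        raise ValueError("metrics need at least 3 points")
    if np.any(np.isnan(obs)) or np.any(np.isnan(pred)):
        raise ValueError("missing values are not allowed")
    err = obs - pred
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed series has zero variance: R^2 undefined")
    if np.allclose(pred, pred[0], rtol=0.0, atol=1e-13 * max(1.0, float(np.abs(pred).max()))):
        pearson = 0.0  # degenerate forecast carries no linear association
        spearman = 0.0
        kendall = 0.0
    else:
        pearson = float(stats.pearsonr(obs, pred).statistic)
        spearman = float(stats.spearmanr(obs, pred).statistic)
        kendall = float(stats.kendalltau(obs, pred).statistic)
    if phase == "fit":
        r2 = 1.0 - float(np.sum(err**2)) / sst
    elif phase == "forecast":
        r2 = pearson**2
    else:
        raise ValueError(f"phase must be 'fit' or 'forecast', got {phase!r}")
    return MetricPanel(rmse, mae, r2, pearson, spearman, kendall, phase)


def default_level_sets(levels: Sequence[int] = (1, 2, 3, 4, 5)) -> list[tuple[int, ...]]:
    """All non-empty subsets of the given levels: 31 sets for five levels."""
    levels = tuple(levels)
    out: list[tuple[int, ...]] = []
    for size in range(1, len(levels) + 1):
        out.extend(combinations(levels, size))
    return out


def _selection_key(rec: dict):
    """Lexicographic rule: max fit R^2, then min MAE, smaller level set, lower order.

    R^2 and MAE are rounded to 9 decimals so that numerically tied candidates
    (e.g. every superset of a perfectly fitting level set) fall through to the
    parsimony tie-breaks instead of being ranked by floating-point dust.
    """
    p = rec["fit_panel"]
    return (-round(p.r2, 9), round(p.mae, 9), len(rec["levels"]), rec["levels"],
            rec["filter_order"])


@dataclass
class GridResult:
    """All candidate panels plus the selected candidate under the stated rule."""

    records: list[dict]
    selected: dict
    rule: str = "max fit r2; ties: min mae, smaller level set, lower filter order"
    stage: int = 1

    @property
    def n_candidates(self) -> int:
        return len(self.records)

    def best_by(self, metric: str, maximize: bool) -> dict:
        """Optimum under a single fit-phase metric (e.g. min-MAE vs max-R^2)."""
        key = lambda r: getattr(r["fit_panel"], metric)
        return (max if maximize else min)(self.records, key=key)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {
                "filter_order": rec["filter_order"],
                "levels": ":".join(map(str, rec["levels"])),
                "stage": rec["stage"],
                "sse": rec["sse"],
                "selected": rec is self.selected,
            }
            row.update({f"fit_{k}": v for k, v in rec["fit_panel"].to_dict().items()
                        if k != "phase"})
            if rec.get("forecast_panel") is not None:
                row.update({f"forecast_{k}": v for k, v in rec["forecast_panel"].to_dict().items()
                            if k != "phase"})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "rule": self.rule,
            "stage": self.stage,
            "selected": {
                "filter_order": self.selected["filter_order"],
                "levels": list(self.selected["levels"]),
            },
            "records": [
                {
                    "filter_order": r["filter_order"],
                    "levels": list(r["levels"]),
                    "stage": r["stage"],
                    "sse": r["sse"],
                    "fit": {k: v for k, v in r["fit_panel"].to_dict().items() if k != "phase"},
                    "forecast": (
                        {k: v for k, v in r["forecast_panel"].to_dict().items() if k != "phase"}
                        if r.get("forecast_panel") is not None else None
                    ),
                }
                for r in self.records
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _fit_candidate(y, x, m, n, basis, stage, stage1_model):
    if stage == 1:
        return wavelet_tf.fit_stage1(y, x, m, n, basis)
    return wavelet_tf.fit_stage2(stage1_model, y, x, basis2=basis)


def grid_search(
    y: Sequence[float],
    x: Sequence[float],
    m: int,
    n: int,
    filter_orders: Sequence[int] = tuple(range(1, 11)),
    level_sets: Optional[Sequence[Sequence[int]]] = None,
    stage: int = 1,
    stage1_model=None,
    y_test: Optional[Sequence[float]] = None,
    x_test: Optional[Sequence[float]] = None,
    max_level: Optional[int] = None,
) -> GridResult:
    """Fit every (filter order, level set) candidate and select deterministically.

    When ``y_test``/``x_test`` are given, one-step forecast panels are computed
    for reporting only — selection always uses fit-phase metrics.  With
    ``stage=2`` all candidates refit around the supplied ``stage1_model``.
    Candidates that fail to fit are collected; if every candidate fails, the
    aggregated causes are raised.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if level_sets is None:
        level_sets = default_level_sets()
    level_sets = [tuple(sorted(ls)) for ls in level_sets]
    if not len(filter_orders) or not len(level_sets):
        raise ValueError("candidate lists must be non-empty")
    if max_level is None:
        needed = max(max(ls) for ls in level_sets) + 1
        max_level = max(needed, int(np.floor(np.log2(len(y)))))
        max_level = min(max_level, int(np.floor(np.log2(len(y)))))
        if max_level < needed:
            raise ValueError(
                f"T={len(y)} supports max_level {max_level} < required {needed}"
            )
    records: list[dict] = []
    failures: list[str] = []
    for order in filter_orders:
        for ls in level_sets:
            basis = WaveletBasisSpec(order, max_level, ls)
            try:
                model = _fit_candidate(y, x, m, n, basis, stage, stage1_model)
            except Exception as exc:  # aggregate; a single bad candidate is not fatal
                failures.append(f"D{order} levels {ls}: {exc}")
                continue
            rec = {
                "filter_order": order,
                "levels": ls,
                "stage": stage,
                "model": model,
                "sse": float(np.sum(model.residuals**2)),
                "fit_panel": compute_metrics(y[model.v :], model.fitted, "fit"),
                "forecast_panel": None,
            }
            if y_test is not None and x_test is not None:
                fc = wavelet_tf.predict(
                    model, np.concatenate([y, y_test]), np.concatenate([x, x_test]),
                    mode="one_step",
                )
                rec["forecast_panel"] = compute_metrics(y_test, fc, "forecast")
            records.append(rec)
    if not records:
        raise RuntimeError("all grid candidates failed to fit:\n" + "\n".join(failures))
    selected = min(records, key=_selection_key)
    return GridResult(records=records, selected=selected, stage=stage)


def two_stage_grid_search(
    y, x, m, n,
    filter_orders: Sequence[int] = tuple(range(1, 11)),
    level_sets: Optional[Sequence[Sequence[int]]] = None,
    y_test=None, x_test=None,
) -> tuple[GridResult, GridResult]:
    """Stage-1 search over filters x level sets, then stage-2 over level sets.

    Stage 2 keeps the stage-1 winner's filter and refits its model over the
    level-set grid, mirroring the two-stage workflow (10 x 31 = 310 candidates
    in stage 1, 31 more in stage 2 with the default grid).
    """
    stage1 = grid_search(
        y, x, m, n, filter_orders, level_sets, stage=1,
        y_test=y_test, x_test=x_test,
    )
    winner = stage1.selected
    stage2 = grid_search(
        y, x, m, n, [winner["filter_order"]], level_sets, stage=2,
        stage1_model=winner["model"], y_test=y_test, x_test=x_test,
    )
    return stage1, stage2
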