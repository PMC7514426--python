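"""End-to-end workflow: transform -> chronological split -> fit -> forecast -> report.

A run is fully described by one YAML config (:class:`RunConfig`): the input
table (CSV path or a simulation spec), the response and explanatory columns,
the transformation per column (standardize / anomalize, with optional log),
the split date, the model families to fit, the candidate grid and the seed.
All transformation statistics are computed on the training window only, so no
held-out value can leak into parameters or model selection; rerunning the same
config and seed reproduces the report byte-for-byte (timestamps aside).

Outputs per run: a metric panel per fitted model (fit + forecast phases), the
selected best model per family and overall, fitted/forecast/residual series as
CSV, serialized models, and a JSON manifest recording versions, seed and the
stage-by-stage log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .transforms import (
    MonthlySeries,
    anomalize,
    log_transform,
    read_monthly_csv,
    standardize,
)
from .polynomial_tf import (
    cross_correlation,
    ccf_report_to_csv,
    fit_input_arma,
    fit_polytf,
    identify_lags,
    predict_poly,
    prewhiten,
)
from .model_selection import compute_metrics, default_level_sets, two_stage_grid_search
from .synthetic import generate_fisheries_like
from .wavelet_tf import predict

log = logging.getLogger("wavetf")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce one comparison run.

    ``transforms`` maps column -> one of ``standardize`` (N), ``anomalize``
    (A), ``log_standardize``, ``log_anomalize`` or ``raw``.  ``split`` is the
    last training month (ISO year-month).  ``models`` lists families to fit:
    ``wavelet`` and/or ``poly``.
    """

    response: str
    explanatory: list[str]
    input_csv: Optional[str] = None
    simulate: bool = False
    transforms: dict = field(default_factory=dict)
    split: str = "2005-08"
    models: list[str] = field(default_factory=lambda: ["wavelet", "poly"])
    m: int = 1
    n: int = 0
    lags: dict = field(default_factory=dict)  # explanatory column -> delay
    filter_orders: list[int] = field(default_factory=lambda: list(range(1, 11)))
    level_sets: Optional[list] = None
    poly_orders: dict = field(default_factory=lambda: {"p": 1, "q": 0, "s": 0, "r": 1})
    forecast_mode: str = "one_step"
    seed: int = 0
    outdir: str = "wavetf_run"

    def to_yaml(self, path=None) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the config seed (documented scheme)."""
        return int(np.random.SeedSequence([self.seed, abs(hash(stage)) % 2**31]).generate_state(1)[0] % 2**31)


def _apply_transform(series: MonthlySeries, kind: str, base: tuple[int, int]) -> MonthlySeries:
    if kind in ("raw", None):
        return series
    if kind == "standardize":
        return standardize(series, base)
    if kind == "anomalize":
        return anomalize(series, base)
    if kind == "log_standardize":
        return standardize(log_transform(series), base)
    if kind == "log_anomalize":
        return anomalize(log_transform(series), base)
    raise ValueError(f"unknown transformation {kind!r}")


def run(config: RunConfig) -> dict:
    """Execute the full workflow and write the comparison report.

    Returns the report dict (also written to ``<outdir>/report.json``).
    Failures are wrapped in :class:`StageError` naming the stage; partial
    outputs written before the failure are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": yaml.safe_load(config.to_yaml()), "stages": [], "models": {}}

    # ---- load ------------------------------------------------------------
    try:
        if config.simulate or config.input_csv is None:
            frame = generate_fisheries_like(seed=config.stage_seed("simulate"))
            table = {c: MonthlySeries(frame[c]) for c in frame.columns}
        else:
            table = read_monthly_csv(config.input_csv)
        for c in [config.response] + list(config.explanatory):
            if c not in table:
                raise KeyError(f"column {c!r} not in input table")
    except Exception as exc:
        raise StageError("load", exc) from exc
    report["stages"].append("load")

    # ---- transform (training-window statistics only) ---------------------
    try:
        split = pd.Period(config.split, freq="M")
        any_series = table[config.response].values
        # month-resolution base: statistics come from the training window only
        base = (str(any_series.index[0]), str(split))
        transformed: dict[str, MonthlySeries] = {}
        for c in [config.response] + list(config.explanatory):
            kind = config.transforms.get(c, "standardize")
            transformed[c] = _apply_transform(table[c], kind, base)
        n_train = int((any_series.index <= split).sum())
        n_test = len(any_series) - n_train
        if n_test <= 0:
            raise ValueError(f"split {config.split} leaves no test window")
        report["n_train"], report["n_test"] = n_train, n_test
        log.info("transform: base period %s, %d train / %d test months", base, n_train, n_test)
    except Exception as exc:
        raise StageError("transform", exc) from exc
    report["stages"].append("transform")

    y_all = transformed[config.response].to_numpy()
    y_tr, y_te = y_all[:n_train], y_all[n_train:]

    # ---- lag identification (training window, prewhitened CCF) ----------
    try:
        ccf_reports = []
        delays = {}
        for c in config.explanatory:
            x_tr = transformed[c].to_numpy()[:n_train]
            if c in config.lags:
                delays[c] = int(config.lags[c])
                continue
            arma = fit_input_arma(x_tr, config.poly_orders.get("p", 1), config.poly_orders.get("q", 0))
            w, y_t = prewhiten(y_tr, x_tr, arma)
            rep = identify_lags(
                cross_correlation(y_t, w), T=n_train, variable=c,
                transformation=config.transforms.get(c, "standardize"),
            )
            ccf_reports.append(rep)
            delays[c] = rep.proposed_delay if rep.proposed_delay is not None else 0
        ccf_report_to_csv(ccf_reports, outdir / "ccf_report.csv")
        report["delays"] = delays
        log.info("lag identification: %s", delays)
    except Exception as exc:
        raise StageError("identify_lags", exc) from exc
    report["stages"].append("identify_lags")

    # first explanatory column drives the single-input model families
    xcol = config.explanatory[0]
    x_all = transformed[xcol].to_numpy()
    x_tr, x_te = x_all[:n_train], x_all[n_train:]

    # ---- wavelet family --------------------------------------------------
    if "wavelet" in config.models:
        try:
            level_sets = config.level_sets if config.level_sets is not None else default_level_sets()
            g1, g2 = two_stage_grid_search(
                y_tr, x_tr, config.m, config.n,
                filter_orders=config.filter_orders, level_sets=level_sets,
                y_test=y_te, x_test=x_te,
            )
            g1.to_csv(outdir / "grid_stage1.csv")
            g2.to_csv(outdir / "grid_stage2.csv")
            best = g2.selected
            model = best["model"]
            model.to_json(outdir / "wavelet_model.json")
            fc = predict(model, y_all, x_all, mode=config.forecast_mode)
            fit_panel = best["fit_panel"]
            forecast_panel = compute_metrics(y_te, fc, "forecast")
            pd.DataFrame(
                {"fitted": model.fitted, "residual": model.residuals}
            ).to_csv(outdir / "wavelet_fit_series.csv", index=False)
            pd.DataFrame({"forecast": fc, "observed": y_te}).to_csv(
                outdir / "wavelet_forecast_series.csv", index=False
            )
            report["models"]["wavelet"] = {
                "filter_order": best["filter_order"],
                "levels": list(best["levels"]),
                "n_candidates_stage1": g1.n_candidates,
                "n_candidates_stage2": g2.n_candidates,
                "fit": {k: v for k, v in fit_panel.to_dict().items() if k != "phase"},
                "forecast": {k: v for k, v in forecast_panel.to_dict().items() if k != "phase"},
            }
            log.info("wavelet: D%d levels %s, %d + %d candidates",
                     best["filter_order"], best["levels"], g1.n_candidates, g2.n_candidates)
        except Exception as exc:
            raise StageError("fit_wavelet", exc) from exc
        report["stages"].append("fit_wavelet")

    # ---- polynomial family ----------------------------------------------
    if "poly" in config.models:
        try:
            orders = dict(config.poly_orders)
            orders.setdefault("d", delays.get(xcol, 0))
            model_p, _ = fit_polytf(y_tr, x_tr, orders)
            model_p.to_json(outdir / "poly_model.json")
            off = model_p.offset
            fit_panel = compute_metrics(y_tr[off:], model_p.fitted, "fit")
            fc = predict_poly(
                model_p, y_all, [x_all], start=n_train + 1,
                horizon=n_test, mode=config.forecast_mode,
            )
            forecast_panel = compute_metrics(y_te, fc, "forecast")
            pd.DataFrame(
                {"fitted": model_p.fitted, "residual": model_p.residuals}
            ).to_csv(outdir / "poly_fit_series.csv", index=False)
            pd.DataFrame({"forecast": fc, "observed": y_te}).to_csv(
                outdir / "poly_forecast_series.csv", index=False
            )
            report["models"]["poly"] = {
                "orders": {k: orders[k] for k in ("p", "q", "s", "r", "d") if k in orders},
                "fit": {k: v for k, v in fit_panel.to_dict().items() if k != "phase"},
                "forecast": {k: v for k, v in forecast_panel.to_dict().items() if k != "phase"},
            }
            log.info("poly: orders %s", report["models"]["poly"]["orders"])
        except Exception as exc:
            raise StageError("fit_poly", exc) from exc
        report["stages"].append("fit_poly")

    # ---- compare ---------------------------------------------------------
    if report["models"]:
        best_name = max(report["models"], key=lambda k: report["models"][k]["fit"]["r2"])
        report["best_model"] = best_name
    report["manifest"] = {"wavetf_version": __version__, "seed": config.seed,
                          "numpy_version": np.__version__}
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
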