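"""Variance-stabilising transformations for monthly series, with exact inverses.

Monthly ecological and climate series are rarely modelled raw.  Before fitting
a transfer function the series are brought to a common scale by one of:

* **anomalization** — remove the monthly climatology: subtract each calendar
  month's mean over a base period and divide by that month's sample standard
  deviation (n-1 denominator), so every calendar month has base-period mean 0
  and sd 1;
* **standardization** — subtract the global base-period mean and divide by the
  global base-period sample sd;
* **log then standardize** — for positive, multiplicative series (landings).

Statistics are always computed over the declared *base period* only; values
outside it (e.g. a held-out test window) are transformed with the base-period
statistics so that forecasts remain comparable across a chronological split.
Every transform records its parameters so forecasts can be mapped back to the
original scale exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MonthlySeries",
    "DegenerateMonthError",
    "anomalize",
    "standardize",
    "log_transform",
    "log_then_standardize",
    "invert",
    "read_monthly_csv",
    "write_monthly_csv",
]


class DegenerateMonthError(ValueError):
    """A calendar month (or the whole series) has zero variance over the base period."""


@dataclass(frozen=True)
class MonthlySeries:
    """A real-valued monthly series with a contiguous year-month index.

    ``values`` is a pandas Series indexed by a monthly ``PeriodIndex`` with no
    gaps.  ``transform_tag`` records the exact composition of transformations
    applied (e.g. ``"log_standardized"``); ``transform_steps`` holds the
    parameters of each step, newest last, so :func:`invert` can undo them.
    ``base_period`` is the (start_year, end_year) climatology window.
    """

    values: pd.Series
    transform_tag: str = "raw"
    base_period: Optional[tuple[int, int]] = None
    transform_steps: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v.index, pd.PeriodIndex) or v.index.freqstr not in ("M", "ME"):
            raise ValueError("MonthlySeries requires a monthly PeriodIndex")
        if len(v) == 0:
            raise ValueError("empty series")
        diffs = np.diff(v.index.asi8)
        if len(v) > 1 and not np.all(diffs == 1):
            raise ValueError("monthly index must be gap-free and strictly increasing")
        if v.isna().any():
            raise ValueError("missing months are rejected; impute upstream or trim")

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @classmethod
    def from_values(
        cls, values, start: str, transform_tag: str = "raw", **kw
    ) -> "MonthlySeries":
        """Build from a plain array and a start month like ``"1963-01"``."""
        idx = pd.period_range(start=start, periods=len(values), freq="M")
        return cls(pd.Series(np.asarray(values, dtype=float), index=idx), transform_tag, **kw)

    def _base_mask(self, base_period: tuple) -> np.ndarray:
        """Boolean mask of the base period.

        Bounds are either years (ints: whole calendar years) or year-months
        (strings like ``"2005-08"``, inclusive), so a chronological split that
        falls mid-year can be expressed exactly.
        """
        lo, hi = base_period
        idx = self.values.index
        if isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer)):
            if lo > hi:
                raise ValueError(f"base period {base_period} is reversed")
            if lo < idx[0].year or hi > idx[-1].year:
                raise ValueError(
                    f"base period {base_period} outside series range "
                    f"{idx[0].year}-{idx[-1].year}"
                )
            p0 = max(pd.Period(f"{lo}-01", freq="M"), idx[0])
            p1 = min(pd.Period(f"{hi}-12", freq="M"), idx[-1])
        else:
            p0 = pd.Period(str(lo), freq="M")
            p1 = pd.Period(str(hi), freq="M")
            if p0 > p1:
                raise ValueError(f"base period {base_period} is reversed")
            if p0 < idx[0] or p1 > idx[-1]:
                raise ValueError(
                    f"base period {base_period} outside series range {idx[0]}-{idx[-1]}"
                )
        return np.asarray((idx >= p0) & (idx <= p1))


def _default_base(series: MonthlySeries) -> tuple[int, int]:
    years = series.values.index.year
    return int(years.min()), int(years.max())


def anomalize(
    series: MonthlySeries, base_period: Optional[tuple[int, int]] = None
) -> MonthlySeries:
    """Remove the monthly climatology computed over ``base_period``.

    For calendar month i with base-period observations X_{i,1..n_i}, each value
    is mapped to (x - mean_i) / sd_i with the sample (n_i - 1) standard
    deviation.  A 49-year base therefore divides each month's squared
    deviations by 48.  Requires at least two base-period observations of every
    calendar month; a zero monthly sd raises :class:`DegenerateMonthError`.
    """
    base = base_period if base_period is not None else _default_base(series)
    if len(series) < 24:
        raise ValueError("anomalization needs >= 24 months (2 per calendar month)")
    mask = series._base_mask(base)
    v = series.values
    months = v.index.month
    means = np.empty(13)
    sds = np.empty(13)
    for mo in range(1, 13):
        sel = v.to_numpy()[mask & (months == mo)]
        if len(sel) < 2:
            raise ValueError(
                f"base period {base} has {len(sel)} observation(s) of month {mo}; need >= 2"
            )
        means[mo] = sel.mean()
        sds[mo] = sel.std(ddof=1)
        if sds[mo] <= 0.0:
            raise DegenerateMonthError(
                f"calendar month {mo} has zero variance over base period {base}"
            )
    out = (v.to_numpy() - means[months]) / sds[months]
    step = {
        "op": "anomalize",
        "base_period": list(base),
        "monthly_means": means[1:].tolist(),
        "monthly_sds": sds[1:].tolist(),
    }
    tag = "anomalized" if series.transform_tag == "raw" else series.transform_tag + "+anomalized"
    return MonthlySeries(
        pd.Series(out, index=v.index),
        transform_tag=tag,
        base_period=tuple(base),
        transform_steps=series.transform_steps + (step,),
    )


def standardize(
    series: MonthlySeries, base_period: Optional[tuple[int, int]] = None
) -> MonthlySeries:
    """Centre and scale by the global base-period mean and sample sd.

    A 588-month base divides the squared deviations by 587.  A constant base
    window raises :class:`DegenerateMonthError`.
    """
    base = base_period if base_period is not None else _default_base(series)
    mask = series._base_mask(base)
    v = series.values
    sel = v.to_numpy()[mask]
    mean = sel.mean()
    sd = sel.std(ddof=1)
    if sd <= 0.0:
        raise DegenerateMonthError(f"series is constant over base period {base}")
    out = (v.to_numpy() - mean) / sd
    step = {"op": "standardize", "base_period": list(base), "mean": float(mean), "sd": float(sd)}
    tag = "standardized" if series.transform_tag == "raw" else series.transform_tag + "+standardized"
    if series.transform_tag == "log":
        tag = "log_standardized"
    return MonthlySeries(
        pd.Series(out, index=v.index),
        transform_tag=tag,
        base_period=tuple(base),
        transform_steps=series.transform_steps + (step,),
    )


def log_transform(series: MonthlySeries) -> MonthlySeries:
    """Natural log; all values must be strictly positive."""
    arr = series.to_numpy()
    if np.any(arr <= 0.0):
        bad = int(np.argmax(arr <= 0.0))
        raise ValueError(
            f"log transform requires positive values; found {arr[bad]} at {series.values.index[bad]}"
        )
    tag = "log" if series.transform_tag == "raw" else series.transform_tag + "+log"
    return MonthlySeries(
        pd.Series(np.log(arr), index=series.values.index),
        transform_tag=tag,
        base_period=series.base_period,
        transform_steps=series.transform_steps + ({"op": "log"},),
    )


def log_then_standardize(
    series: MonthlySeries, base_period: Optional[tuple[int, int]] = None
) -> MonthlySeries:
    """Log transform followed by standardization — the treatment for landings series."""
    return standardize(log_transform(series), base_period)


def invert(series: MonthlySeries) -> MonthlySeries:
    """Undo every recorded transformation step, newest first.

    ``invert(transform(x))`` recovers x to floating-point accuracy.
    """
    arr = series.to_numpy().copy()
    months = series.values.index.month
    for step in reversed(series.transform_steps):
        op = step["op"]
        if op == "standardize":
            arr = arr * step["sd"] + step["mean"]
        elif op == "anomalize":
            sds = np.asarray(step["monthly_sds"])
            means = np.asarray(step["monthly_means"])
            arr = arr * sds[months - 1] + means[months - 1]
        elif op == "log":
            arr = np.exp(arr)
        else:  # pragma: no cover - guards corrupted sidecars
            raise ValueError(f"unknown transform step {op!r}")
    return MonthlySeries(
        pd.Series(arr, index=series.values.index), transform_tag="raw"
    )


# ---------------------------------------------------------------------------
# CSV + JSON-sidecar round trip


def write_monthly_csv(path, table: dict[str, MonthlySeries] | MonthlySeries) -> None:
    """Write series to CSV (column ``date`` as ISO year-month) with a JSON sidecar.

    The sidecar ``<path>.params.json`` stores each column's transform tag and
    step parameters so the transformation is invertible after a round trip.
    """
    if isinstance(table, MonthlySeries):
        table = {"value": table}
    path = Path(path)
    frame = pd.DataFrame({name: s.values for name, s in table.items()})
    out = frame.copy()
    out.insert(0, "date", frame.index.strftime("%Y-%m"))
    out.to_csv(path, index=False)
    sidecar = {
        name: {
            "transform_tag": s.transform_tag,
            "base_period": list(s.base_period) if s.base_period else None,
            "transform_steps": list(s.transform_steps),
        }
        for name, s in table.items()
    }
    Path(str(path) + ".params.json").write_text(json.dumps(sidecar, indent=1))


def read_monthly_csv(path) -> dict[str, MonthlySeries]:
    """Read a monthly CSV (and its JSON sidecar, if present) back into series."""
    path = Path(path)
    frame = pd.read_csv(path)
    if "date" not in frame.columns:
        raise ValueError(f"{path} has no 'date' column")
    idx = pd.PeriodIndex(frame.pop("date"), freq="M")
    sidecar_path = Path(str(path) + ".params.json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    out = {}
    for name in frame.columns:
        meta = sidecar.get(name, {})
        out[name] = MonthlySeries(
            pd.Series(frame[name].to_numpy(dtype=float), index=idx),
            transform_tag=meta.get("transform_tag", "raw"),
            base_period=tuple(meta["base_period"]) if meta.get("base_period") else None,
            transform_steps=tuple(meta.get("transform_steps", ())),
        )
    return out
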