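"""Synthetic monthly series with the statistical structure the estimators assume.

Three generators cover the data-generating processes the package models:

* :func:`generate_tvtf` — a response driven by lagged inputs and its own lags
  through smooth time-varying coefficient curves on rescaled time u = t/T,
  with i.i.d. Gaussian innovations;
* :func:`generate_polytf` — a constant-coefficient rational (Box-Jenkins)
  transfer function, delta(B) B^d / omega(B), plus ARMA noise;
* :func:`generate_fisheries_like` — a full 1963-2011 style monthly table (588
  records) of climate proxies and two positive landings series, wired so the
  whole pipeline (anomalize/standardize, lag identification, both model
  families) can be exercised end to end without any external data.

All generators are deterministic under their seed.  Gaussian innovations are a
modelling choice for testability; the time-varying model itself assumes only
i.i.d. (0, sigma^2) errors.  A 100-sample burn-in removes initialisation
transients before the emitted window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .transforms import MonthlySeries

__all__ = [
    "CurveSpec",
    "SimSpec",
    "curve_function",
    "generate_tvtf",
    "generate_polytf",
    "generate_fisheries_like",
]

BURN_IN = 100


class StabilityError(ValueError):
    """The requested data-generating process is explosive."""


@dataclass(frozen=True)
class CurveSpec:
    """A named parametric coefficient curve on u in [0, 1].

    kinds: ``constant`` (a), ``linear`` (a + b*u), ``cosine``
    (a + b*cos(2*pi*freq*u)), ``step`` (a for u < at, b after).
    """

    kind: str
    a: float = 0.0
    b: float = 0.0
    freq: float = 1.0
    at: float = 0.5

    def __call__(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.kind == "constant":
            return np.full_like(u, self.a)
        if self.kind == "linear":
            return self.a + self.b * u
        if self.kind == "cosine":
            return self.a + self.b * np.cos(2.0 * np.pi * self.freq * u)
        if self.kind == "step":
            return np.where(u < self.at, self.a, self.b)
        raise ValueError(f"unknown curve kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "a": self.a, "b": self.b, "freq": self.freq, "at": self.at}


def curve_function(spec: CurveSpec | Callable | dict) -> Callable:
    if isinstance(spec, CurveSpec):
        return spec
    if isinstance(spec, dict):
        return CurveSpec(**spec)
    return spec


@dataclass
class SimSpec:
    """Fully serialisable description of one simulated dataset.

    ``delta`` / ``omega`` list the coefficient curves for response lags
    1..m and input lags 0..n.  The input is AR(1)/ARMA (``input_ar``,
    ``input_ma``, ``input_sd``) or a seasonal climatology (``seasonal_means``,
    ``seasonal_sds`` of length 12, anomalies AR(1) with ``input_ar``).
    ``noise_sd`` is the innovation sd of the response equation.
    """

    T_train: int = 512
    T_test: int = 76
    delta: list = field(default_factory=list)
    omega: list = field(default_factory=lambda: [CurveSpec("constant", a=1.0)])
    input_ar: list = field(default_factory=lambda: [0.5])
    input_ma: list = field(default_factory=list)
    input_sd: float = 1.0
    seasonal_means: Optional[list] = None
    seasonal_sds: Optional[list] = None
    noise_sd: float = 0.1
    seed: int = 0

    @property
    def T(self) -> int:
        return self.T_train + self.T_test

    def to_yaml(self, path=None) -> str:
        d = {
            **{k: getattr(self, k) for k in (
                "T_train", "T_test", "input_ar", "input_ma", "input_sd",
                "seasonal_means", "seasonal_sds", "noise_sd", "seed")},
            "delta": [c.to_dict() if isinstance(c, CurveSpec) else c for c in self.delta],
            "omega": [c.to_dict() if isinstance(c, CurveSpec) else c for c in self.omega],
        }
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path) -> "SimSpec":
        from pathlib import Path

        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = yaml.safe_load(text)
        d["delta"] = [CurveSpec(**c) for c in d.get("delta", [])]
        d["omega"] = [CurveSpec(**c) for c in d.get("omega", [])]
        return cls(**d)


def _simulate_arma(rng, T, ar, ma, sd):
    """ARMA sample via lfilter with burn-in discarded."""
    ar = np.asarray(ar, dtype=float)
    ma = np.asarray(ma, dtype=float)
    eps = rng.normal(0.0, sd, size=T + BURN_IN)
    a = np.concatenate([[1.0], -ar]) if len(ar) else np.array([1.0])
    b = np.concatenate([[1.0], ma]) if len(ma) else np.array([1.0])
    return signal.lfilter(b, a, eps)[BURN_IN:]


def _simulate_input(rng, spec: SimSpec, T: int, start_month: int = 1) -> np.ndarray:
    if spec.seasonal_means is not None:
        means = np.asarray(spec.seasonal_means, dtype=float)
        sds = np.asarray(spec.seasonal_sds if spec.seasonal_sds is not None else np.ones(12))
        anom = _simulate_arma(rng, T, spec.input_ar, spec.input_ma, spec.input_sd)
        months = (start_month - 1 + np.arange(T)) % 12
        return means[months] + sds[months] * anom
    return _simulate_arma(rng, T, spec.input_ar, spec.input_ma, spec.input_sd)


def generate_tvtf(
    spec: SimSpec, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Simulate the time-varying transfer-function recursion.

    Returns ``(y, x, true_curves)`` of length ``spec.T``; ``true_curves`` maps
    ``"delta_1"..``, ``"omega_0"..`` to the generating curves sampled on the
    grid u = t/T.  The burn-in uses the curves frozen at u = 0.  Explosive
    specifications (sup_u sum_i |delta_i(u)| >= 1) are rejected.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    T = spec.T
    deltas = [curve_function(c) for c in spec.delta]
    omegas = [curve_function(c) for c in spec.omega]
    m, n = len(deltas), len(omegas) - 1
    if n < 0:
        raise ValueError("at least one input-lag curve omega_0 is required")
    uu = np.linspace(0.0, 1.0, 2049)
    if m and np.max(np.sum([np.abs(d(uu)) for d in deltas], axis=0)) >= 1.0:
        raise StabilityError("sup_u sum_i |delta_i(u)| >= 1: explosive recursion rejected")

    x = _simulate_input(rng, spec, T + BURN_IN)
    eps = rng.normal(0.0, spec.noise_sd, size=T + BURN_IN) if spec.noise_sd > 0 else np.zeros(T + BURN_IN)
    u_full = np.concatenate([np.zeros(BURN_IN), np.arange(1, T + 1) / T])
    dvals = np.column_stack([d(u_full) for d in deltas]) if m else np.empty((T + BURN_IN, 0))
    ovals = np.column_stack([o(u_full) for o in omegas])
    y = np.zeros(T + BURN_IN)
    for t in range(T + BURN_IN):
        acc = eps[t]
        for i in range(1, m + 1):
            if t - i >= 0:
                acc += dvals[t, i - 1] * y[t - i]
        for j in range(n + 1):
            if t - j >= 0:
                acc += ovals[t, j] * x[t - j]
        y[t] = acc
    grid = np.arange(1, T + 1) / T
    true_curves = {f"delta_{i+1}": deltas[i](grid) for i in range(m)}
    true_curves.update({f"omega_{j}": omegas[j](grid) for j in range(n + 1)})
    return y[BURN_IN:], x[BURN_IN:], true_curves


def implied_impulse_weights(delta, omega, d, n_weights=21):
    """Impulse-response weights alpha_0..alpha_{n-1} of delta(B) B^d / omega(B).

    ``delta`` = (delta_0..delta_s) numerator, ``omega`` = (omega_1..omega_r)
    denominator of 1 - omega_1 B - ... - omega_r B^r.
    """
    num = np.concatenate([np.zeros(d), np.asarray(delta, dtype=float)])
    den = np.concatenate([[1.0], -np.asarray(omega, dtype=float)]) if len(omega) else np.array([1.0])
    impulse = np.zeros(n_weights)
    impulse[0] = 1.0
    return signal.lfilter(num, den, impulse)


def generate_polytf(
    spec: SimSpec,
    delta: Sequence[float],
    omega: Sequence[float] = (),
    d: int = 0,
    noise_ar: Sequence[float] = (),
    noise_ma: Sequence[float] = (),
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate the constant-coefficient rational transfer function plus ARMA noise.

    y_t = [delta(B) B^d / omega(B)] x_t + eta_t with eta ARMA(noise_ar,
    noise_ma) with innovation sd ``spec.noise_sd``.  Returns ``(y, x, truth)``
    where ``truth`` carries the generating orders, coefficients and the implied
    impulse weights alpha_0..alpha_20.  Denominator roots inside the unit
    circle are rejected.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    omega = np.asarray(omega, dtype=float)
    if len(omega):
        den = np.concatenate([[1.0], -omega])
        roots = np.roots(den[::-1])  # roots of 1 - w1 z - ... - wr z^r
        if np.any(np.abs(roots) <= 1.0):
            raise StabilityError("denominator root on or inside the unit circle")
    T = spec.T
    x = _simulate_input(rng, spec, T + BURN_IN)
    num = np.concatenate([np.zeros(d), np.asarray(delta, dtype=float)])
    den = np.concatenate([[1.0], -omega]) if len(omega) else np.array([1.0])
    signal_part = signal.lfilter(num, den, x)
    eta = _simulate_arma(rng, T + BURN_IN, noise_ar, noise_ma, spec.noise_sd) if spec.noise_sd > 0 else np.zeros(T + BURN_IN)
    y = signal_part + eta
    truth = {
        "delta": np.asarray(delta, dtype=float),
        "omega": omega,
        "d": d,
        "noise_ar": np.asarray(noise_ar, dtype=float),
        "noise_ma": np.asarray(noise_ma, dtype=float),
        "alpha": implied_impulse_weights(delta, omega, d),
    }
    return y[BURN_IN:], x[BURN_IN:], truth


# ---------------------------------------------------------------------------
# Fisheries-like monthly table


_CLIMATE_COLUMNS = ("SST", "TI", "MSL", "MEI", "PDO", "N12", "N34", "SOI", "CTI")


def generate_fisheries_like(seed: int = 0) -> pd.DataFrame:
    """A 588-row monthly table (1963-01 .. 2011-12) shaped like a fisheries register.

    Nine climate proxies (seasonal climatology + AR(1) anomalies, with N34/N12
    strongly correlated the way neighbouring Pacific SST indices are) and two
    positive landings series:

    * ``DANC`` — anchovy-like landings driven by lagged TI and N12 anomalies
      through a time-varying coefficient recursion, then exponentiated;
    * ``DSAR`` — sardine-like landings whose log follows a constant-coefficient
      two-input transfer function of lagged SST, TI and log(DANC) with AR(1)
      noise.

    Coefficient magnitudes are set so prewhitened cross-correlations land in
    the 0.1-0.6 band, exercising realistic significance thresholds.  Fully
    deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    idx = pd.period_range("1963-01", "2011-12", freq="M")
    T = len(idx)
    months = idx.month.to_numpy() - 1
    out = {}
    anomalies = {}
    # (annual-cycle amplitude, mean level, anomaly AR(1) coefficient, anomaly sd)
    params = {
        "SST": (3.0, 16.0, 0.7, 0.6),
        "TI": (40.0, 180.0, 0.5, 25.0),
        "MSL": (6.0, 705.0, 0.6, 3.0),
        "MEI": (0.2, 0.0, 0.85, 0.5),
        "PDO": (0.3, 0.0, 0.9, 0.4),
        "N12": (1.5, 22.0, 0.8, 0.8),
        "SOI": (0.4, 0.0, 0.6, 0.9),
        "CTI": (0.5, 0.0, 0.8, 0.5),
    }
    phase = {"SST": 1.0, "TI": 4.0, "MSL": 2.5, "MEI": 0.0, "PDO": 0.0, "N12": 1.5,
             "SOI": 0.0, "CTI": 0.5}
    for name, (amp, level, phi, sd) in params.items():
        clim = level + amp * np.cos(2.0 * np.pi * (months - phase[name]) / 12.0)
        anom = _simulate_arma(rng, T, [phi], [], sd)
        anomalies[name] = anom
        out[name] = clim + anom
    # N34 rides on N12's anomaly (the two Nino zones overlap spatially)
    n34_anom = 0.8 * anomalies["N12"] + _simulate_arma(rng, T, [0.8], [], 0.35)
    out["N34"] = 27.0 + 1.0 * np.cos(2.0 * np.pi * (months - 1.5) / 12.0) + n34_anom
    anomalies["N34"] = n34_anom

    # anchovy: time-varying response to standardized TI (lag 2) and N12 (lag 5)
    ti_z = (anomalies["TI"] - anomalies["TI"].mean()) / anomalies["TI"].std(ddof=1)
    n12_z = (anomalies["N12"] - anomalies["N12"].mean()) / anomalies["N12"].std(ddof=1)
    u = np.arange(1, T + 1) / T
    d1 = 0.55 + 0.15 * np.cos(2.0 * np.pi * u)
    w_ti = -0.35 + 0.15 * u
    w_n12 = -0.25 - 0.10 * np.cos(2.0 * np.pi * u)
    seas = 0.9 * np.cos(2.0 * np.pi * (months - 3.0) / 12.0)
    eps = rng.normal(0.0, 0.35, size=T)
    core = np.zeros(T)
    for t in range(T):
        core[t] = eps[t] + seas[t]
        if t >= 1:
            core[t] += d1[t] * (core[t - 1] - seas[t - 1])
        if t >= 2:
            core[t] += w_ti[t] * ti_z[t - 2]
        if t >= 5:
            core[t] += w_n12[t] * n12_z[t - 5]
    out["DANC"] = np.exp(9.5 + 0.8 * core)  # tonnes, strictly positive

    # sardine: constant-coefficient transfer of lagged SST, TI and log-anchovy
    ldanc = np.log(out["DANC"])
    ldanc_z = (ldanc - ldanc.mean()) / ldanc.std(ddof=1)
    sst_z = (anomalies["SST"] - anomalies["SST"].mean()) / anomalies["SST"].std(ddof=1)
    eta = _simulate_arma(rng, T, [0.6], [], 0.30)
    lsar = np.zeros(T)
    for t in range(T):
        lsar[t] = eta[t]
        if t >= 1:
            lsar[t] += 0.45 * lsar[t - 1]
        if t >= 15:
            lsar[t] += 0.22 * sst_z[t - 15]
        if t >= 18:
            lsar[t] += 0.25 * ti_z[t - 18]
        if t >= 7:
            lsar[t] += -0.20 * ldanc_z[t - 7]
    out["DSAR"] = np.exp(8.0 + 0.9 * lsar)

    frame = pd.DataFrame(out, index=idx)
    return frame[list(_CLIMATE_COLUMNS) + ["DANC", "DSAR"]]


def fisheries_series(frame: pd.DataFrame, column: str) -> MonthlySeries:
    """Wrap one column of the fisheries-like table as a MonthlySeries."""
    return MonthlySeries(frame[column])
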