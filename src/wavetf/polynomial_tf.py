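"""Constant-coefficient Box-Jenkins transfer-function modelling.

The model is the lagged regression  y_t = alpha(B) x_t + eta_t  with a rational
transfer function  alpha(B) = delta(B) B^d / omega(B),  where
delta(B) = delta_0 + delta_1 B + ... + delta_s B^s,
omega(B) = 1 - omega_1 B - ... - omega_r B^r,  d is the pure delay and the
noise eta_t is a stationary ARMA process.  Fitting follows the classical
five-step sequential procedure:

  (i)   fit an ARMA(p, q) model to the input series x;
  (ii)  prewhiten: apply phi(B)/Theta(B) to both x (giving white W_t) and y
        (giving y~_t);
  (iii) the cross-correlation of y~ with W is proportional to the impulse
        weights alpha_h — use its significant lags to pick (s, d, r);
  (iv)  estimate (omega_1..omega_r, delta_0..delta_s) by linearising the
        rational form as a finite lagged regression;
  (v)   fit an ARMA model to the step-(iv) residuals as the noise model.

ARMA estimation is delegated to statsmodels; the transfer-function regression
and the prewhitening filters are linear-algebra on lagged series.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "InputARMA",
    "CCFReport",
    "PolyTFModel",
    "fit_input_arma",
    "prewhiten",
    "cross_correlation",
    "identify_lags",
    "fit_transfer_regression",
    "fit_noise_arma",
    "fit_polytf",
    "predict_poly",
]


@dataclass
class InputARMA:
    """Fitted ARMA(p, q) filter phi(B) x_t = Theta(B) W_t for an input series."""

    ar: np.ndarray  # phi_1..phi_p
    ma: np.ndarray  # theta_1..theta_q
    sigma2: float
    residuals: np.ndarray

    @property
    def ar_poly(self) -> np.ndarray:
        return np.concatenate([[1.0], -self.ar]) if len(self.ar) else np.array([1.0])

    @property
    def ma_poly(self) -> np.ndarray:
        return np.concatenate([[1.0], self.ma]) if len(self.ma) else np.array([1.0])


def _check_convergence(res) -> None:
    retvals = getattr(res, "mle_retvals", None)
    if retvals and not retvals.get("converged", True):
        raise RuntimeError(f"ARMA estimation did not converge: {retvals}")


def fit_input_arma(x: Sequence[float], p: int, q: int) -> InputARMA:
    """Step (i): maximum-likelihood ARMA(p, q) fit to the input series.

    With p = q = 0 the filter is the identity and the residuals are the input
    itself.  The fitted model must be causal and invertible; non-convergence
    raises with the optimiser diagnostics attached.
    """
    x = np.asarray(x, dtype=float)
    if p == 0 and q == 0:
        return InputARMA(np.array([]), np.array([]), float(np.mean(x**2)), x.copy())
    from statsmodels.tsa.arima.model import ARIMA

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ARIMA(x, order=(p, 0, q), trend="n").fit()
    _check_convergence(res)
    ar = np.asarray(res.arparams) if p else np.array([])
    ma = np.asarray(res.maparams) if q else np.array([])
    if len(ma) and np.any(np.abs(np.roots(np.concatenate([[1.0], ma])[::-1])) <= 1.0 + 1e-8):
        warnings.warn("fitted MA polynomial is on/inside the unit circle; prewhitening may be unstable")
    return InputARMA(ar, ma, float(res.params[-1]), np.asarray(res.resid))


def prewhiten(
    y: Sequence[float], x: Sequence[float], input_arma: InputARMA
) -> tuple[np.ndarray, np.ndarray]:
    """Step (ii): apply the input's ARMA operator phi(B)/Theta(B) to x and y.

    Returns ``(w, y_tilde)``: ``w`` is the prewhitened input and ``y_tilde``
    the identically filtered output.  The cross-covariance of y~ with W at lag
    h is sigma_W^2 * alpha_h, which is what makes step (iii) work.
    """
    ma_poly = input_arma.ma_poly
    if len(ma_poly) > 1 and np.any(np.abs(np.roots(ma_poly[::-1])) <= 1.0):
        raise ValueError("non-invertible MA polynomial: prewhitening filter unstable")
    w = signal.lfilter(input_arma.ar_poly, ma_poly, np.asarray(x, dtype=float))
    y_t = signal.lfilter(input_arma.ar_poly, ma_poly, np.asarray(y, dtype=float))
    return w, y_t


def cross_correlation(
    a: Sequence[float], b: Sequence[float], max_lag: int = 24
) -> pd.Series:
    """Sample CCF(a, b)(h) = corr(a_t, b_{t-h}) for h = -max_lag..max_lag.

    Positive lags mean b leads a — for (y~, w) pairs the CCF at lag h
    estimates the impulse weight alpha_h up to the sigma_W^2 scale.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    T = len(a)
    a0 = a - a.mean()
    b0 = b - b.mean()
    denom = T * a0.std() * b0.std()
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.empty(len(lags))
    for i, h in enumerate(lags):
        if h >= 0:
            vals[i] = np.dot(a0[h:], b0[: T - h]) / denom
        else:
            vals[i] = np.dot(a0[: T + h], b0[-h:]) / denom
    return pd.Series(vals, index=lags, name="ccf")


@dataclass
class CCFReport:
    """Lags whose cross-correlation exceeds the significance bound.

    ``flagged`` holds (lag, ccf) pairs; ``proposed_delay`` is the smallest
    flagged non-negative lag (negative lags are reported but never proposed —
    a causal transfer function cannot act before its input).
    """

    flagged: list[tuple[int, float]]
    bound: float
    T: int
    variable: str = ""
    transformation: str = ""

    @property
    def proposed_delay(self) -> Optional[int]:
        nonneg = [lag for lag, _ in self.flagged if lag >= 0]
        return min(nonneg) if nonneg else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable,
                "transformation": self.transformation,
                "lag": [l for l, _ in self.flagged],
                "ccf": [c for _, c in self.flagged],
            }
        )


def identify_lags(
    ccf: pd.Series,
    T: int,
    bound_policy: str = "2/sqrt(T)",
    variable: str = "",
    transformation: str = "",
) -> CCFReport:
    """Step (iii): flag significant CCF lags and propose the delay d.

    The default large-sample bound is 2/sqrt(T) (e.g. 0.0884 at T = 512).  An
    empty report is a legitimate outcome, not an error.
    """
    if bound_policy == "2/sqrt(T)":
        bound = 2.0 / np.sqrt(T)
    else:
        bound = float(bound_policy)
    flagged = [(int(h), float(c)) for h, c in ccf.items() if abs(c) > bound]
    return CCFReport(flagged=flagged, bound=bound, T=T,
                     variable=variable, transformation=transformation)


def ccf_report_to_csv(reports: Sequence[CCFReport], path) -> None:
    """Write flagged CCF lags for several variables/transformations to one CSV."""
    frames = [r.to_frame() for r in reports if r.flagged]
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["variable", "transformation", "lag", "ccf"]
    )
    table.to_csv(path, index=False)


@dataclass
class TransferBranch:
    """One input's rational-lag branch: delay d, numerator delta_0..delta_s."""

    d: int
    delta: np.ndarray
    r: int = 0

    @property
    def s(self) -> int:
        return len(self.delta) - 1


@dataclass
class PolyTFModel:
    """Assembled constant-coefficient transfer-function model.

    ``omega`` are the common output-lag (denominator) coefficients of
    1 - omega_1 B - ... - omega_r B^r; each :class:`TransferBranch` carries one
    input's delay and numerator.  ``noise_ar``/``noise_ma`` describe the ARMA
    noise fitted to the regression residuals.
    """

    omega: np.ndarray
    branches: list[TransferBranch]
    noise_ar: np.ndarray = field(default_factory=lambda: np.array([]))
    noise_ma: np.ndarray = field(default_factory=lambda: np.array([]))
    noise_sigma2: float = np.nan
    input_arma: Optional[InputARMA] = None
    fitted: np.ndarray = field(default_factory=lambda: np.array([]))
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    offset: int = 0  # rows dropped at the head of the training window

    @property
    def r(self) -> int:
        return len(self.omega)

    def check_stability(self) -> bool:
        """True if the denominator roots lie outside the unit circle."""
        if not len(self.omega):
            return True
        poly = np.concatenate([[1.0], -self.omega])
        return bool(np.all(np.abs(np.roots(poly[::-1])) > 1.0))

    def to_dict(self) -> dict:
        return {
            "omega": self.omega.tolist(),
            "branches": [
                {"d": b.d, "delta": b.delta.tolist()} for b in self.branches
            ],
            "noise_ar": self.noise_ar.tolist(),
            "noise_ma": self.noise_ma.tolist(),
            "noise_sigma2": self.noise_sigma2,
            "offset": self.offset,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, dct: dict) -> "PolyTFModel":
        return cls(
            omega=np.asarray(dct["omega"], dtype=float),
            branches=[
                TransferBranch(d=b["d"], delta=np.asarray(b["delta"], dtype=float))
                for b in dct["branches"]
            ],
            noise_ar=np.asarray(dct["noise_ar"], dtype=float),
            noise_ma=np.asarray(dct["noise_ma"], dtype=float),
            noise_sigma2=dct["noise_sigma2"],
            offset=dct.get("offset", 0),
        )

    @classmethod
    def from_json(cls, path) -> "PolyTFModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_transfer_regression(
    y: Sequence[float],
    inputs: Sequence[tuple[Sequence[float], int, int, int]],
    r: int = 0,
) -> PolyTFModel:
    """Step (iv): least-squares fit of the linearised rational-lag regression.

    ``inputs`` is a sequence of ``(x, s, d, r_branch)`` tuples; the rational
    denominator is linearised as y-lags 1..r with r = max over the requested
    branch orders (and the explicit ``r`` argument).  The regression is

        y_t = sum_{i=1}^r omega_i y_{t-i}
              + sum_inputs sum_{j=0}^{s} delta_j x_{t-d-j} + u_t.

    Raises a conditioning error when the lag design is numerically collinear.
    """
    y = np.asarray(y, dtype=float)
    T = len(y)
    r_eff = max([r] + [int(br) for (_, _, _, br) in inputs])
    max_lag = max([r_eff] + [int(d) + int(s) for (_, s, d, _) in inputs])
    if T <= max_lag + 1:
        raise ValueError(f"series too short (T={T}) for maximum lag {max_lag}")
    rows = np.arange(max_lag, T)
    cols = []
    for i in range(1, r_eff + 1):
        cols.append(y[rows - i])
    for (x, s, d, _) in inputs:
        x = np.asarray(x, dtype=float)
        if x.shape != y.shape:
            raise ValueError("input series length must match the response")
        for j in range(0, s + 1):
            cols.append(x[rows - d - j])
    design = np.column_stack(cols) if cols else np.empty((len(rows), 0))
    target = y[rows]
    beta, _, rank, sv = np.linalg.lstsq(design, target, rcond=None)
    if design.shape[1] and rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"collinear lag design: rank {rank} < {design.shape[1]} "
            f"(condition number {sv[0] / max(sv[-1], 1e-300):.3g})"
        )
    fitted = design @ beta
    omega = beta[:r_eff]
    branches = []
    pos = r_eff
    for (x, s, d, _) in inputs:
        branches.append(TransferBranch(d=int(d), delta=beta[pos : pos + s + 1], r=r_eff))
        pos += s + 1
    model = PolyTFModel(
        omega=omega, branches=branches, fitted=fitted,
        residuals=target - fitted, offset=max_lag,
    )
    if not model.check_stability():
        warnings.warn("fitted denominator polynomial has a root on/inside the unit circle")
    return model


def fit_noise_arma(
    residuals: Sequence[float], order: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Step (v): ARMA fit to the transfer-regression residuals.

    Returns ``(phi_eta, theta_eta, sigma2_Z)``.  Order (0, 0) reduces to the
    residual mean square.
    """
    arma = fit_input_arma(np.asarray(residuals, dtype=float), *order)
    return arma.ar, arma.ma, arma.sigma2


def fit_polytf(
    y: Sequence[float],
    x: Sequence[float],
    orders: dict,
) -> tuple[PolyTFModel, CCFReport]:
    """Run the whole five-step procedure for a single input.

    ``orders`` keys: ``p``, ``q`` (input ARMA), ``s``, ``r`` (transfer), and
    optionally ``d`` (delay; identified from the prewhitened CCF when absent),
    ``noise_p``, ``noise_q`` (noise ARMA, default 0), ``max_lag`` (CCF window,
    default 24).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    arma = fit_input_arma(x, orders.get("p", 1), orders.get("q", 0))
    w, y_t = prewhiten(y, x, arma)
    ccf = cross_correlation(y_t, w, max_lag=orders.get("max_lag", 24))
    report = identify_lags(ccf, T=len(y))
    d = orders.get("d")
    if d is None:
        d = report.proposed_delay
        if d is None:
            raise ValueError(
                "no significant cross-correlation lag found; pass an explicit delay 'd'"
            )
    model = fit_transfer_regression(
        y, [(x, orders.get("s", 0), d, orders.get("r", 0))], r=orders.get("r", 0)
    )
    np_, nq = orders.get("noise_p", 0), orders.get("noise_q", 0)
    ar, ma, s2 = fit_noise_arma(model.residuals, (np_, nq))
    model.noise_ar, model.noise_ma, model.noise_sigma2 = ar, ma, s2
    model.input_arma = arma
    return model, report


def predict_poly(
    model: PolyTFModel,
    y: Sequence[float],
    inputs: Sequence[Sequence[float]],
    start: Optional[int] = None,
    horizon: Optional[int] = None,
    mode: str = "one_step",
) -> np.ndarray:
    """Forecast via the fitted difference equation.

    Mirrors the time-varying predictor: ``start`` is the 1-based index of the
    first forecast (default: right after ``y``), inputs must cover the span,
    ``one_step`` uses observed lagged responses, ``recursive`` feeds forecasts
    back.  The noise forecast is its unconditional mean, zero.
    """
    if mode not in ("one_step", "recursive"):
        raise ValueError(f"mode must be 'one_step' or 'recursive', got {mode!r}")
    y = np.asarray(y, dtype=float)
    xs = [np.asarray(x, dtype=float) for x in inputs]
    if len(xs) != len(model.branches):
        raise ValueError(f"model has {len(model.branches)} input branches, got {len(xs)} inputs")
    if start is None:
        start = len(y) + 1
    if horizon is None:
        horizon = min(len(x) for x in xs) - (start - 1)
    if horizon <= 0:
        raise ValueError("empty forecast horizon")
    for x in xs:
        if start - 1 + horizon > len(x):
            raise ValueError("input series do not cover the forecast span")
    if mode == "one_step" and model.r > 0 and start - 1 + horizon > len(y):
        raise ValueError("one_step mode requires observed responses over the forecast span")
    if mode == "recursive":
        work = np.concatenate([y[: start - 1], np.zeros(horizon)])
    else:
        work = y
    out = np.empty(horizon)
    for h in range(horizon):
        t = start + h  # 1-based
        acc = 0.0
        for i in range(1, model.r + 1):
            acc += model.omega[i - 1] * work[t - i - 1]
        for x, br in zip(xs, model.branches):
            for j in range(br.s + 1):
                idx = t - br.d - j - 1
                if idx >= 0:
                    acc += br.delta[j] * x[idx]
        out[h] = acc
        if mode == "recursive":
            work[t - 1] = acc
    return out
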