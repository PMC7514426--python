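"""Time-varying transfer-function models with wavelet-expanded coefficients.

The model for a response series Y and an exogenous input X observed at
t = 1..T is

    Y_t = sum_{i=1}^m delta_i(t/T) Y_{t-i} + sum_{j=0}^n omega_j(t/T) X_{t-j} + eps_t,

with i.i.d. (0, sigma^2) errors.  The coefficient curves delta_i(u), omega_j(u)
live on rescaled time u = t/T in [0, 1] (the locally stationary asymptotic
device) and are expanded in a truncated periodized Daubechies wavelet series.
Substituting the expansions turns the model into a linear regression whose
unknowns are the wavelet coefficients; these are estimated by least squares in
two stages:

* **stage 1** regresses Y_t on observed lagged responses and inputs;
* **stage 2** refits with the lagged responses replaced by the stage-1 fitted
  values.  For m = 1 the stage-2 error is a locally stationary MA(2),
  e2_t = eps_t - delta_1^2(t/T) eps_{t-2}, which the model exposes as a
  whitening filter.

The curves are recovered from the estimated wavelet coefficients by evaluating
the basis expansion back on the time grid (the inverse wavelet reconstruction).

Least squares is solved by an orthogonal-decomposition (SVD) minimum-norm
solve rather than explicit normal-equations inversion: the level-complete
design is square (e.g. 512 x 512) and its Gram matrix is too ill-conditioned
to invert stably.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .wavelet_basis import WaveletBasisSpec, basis_matrix, build_design_matrices

__all__ = [
    "TVTFModel",
    "ConditioningError",
    "fit_stage1",
    "fit_stage2",
    "reconstruct_curve",
    "predict",
]


class ConditioningError(ValueError):
    """Design matrix numerically rank-deficient under the strict-rank policy."""


@dataclass
class TVTFModel:
    """A fitted time-varying transfer-function model.

    ``delta_coefs[i-1]`` / ``omega_coefs[j]`` hold the wavelet coefficient
    vector of delta_i / omega_j (scaling coefficient first); ``delta_curves``
    and ``omega_curves`` are the reconstructions on the training grid
    u = t/T, t = v+1..T.  ``stage`` records whether lagged responses were
    observed (1) or stage-1 fitted values (2).
    """

    m: int
    n: int
    basis: WaveletBasisSpec
    delta_coefs: list[np.ndarray]
    omega_coefs: list[np.ndarray]
    delta_curves: list[np.ndarray]
    omega_curves: list[np.ndarray]
    u_grid: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    T: int
    stage: int = 1
    rank: int = 0
    condition_number: float = np.nan
    stage1: Optional["TVTFModel"] = None
    innovations: Optional[np.ndarray] = field(default=None, repr=False)
    innovations_exact: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def v(self) -> int:
        """Number of leading observations dropped: max(m, n)."""
        return max(self.m, self.n)

    def coefficient_at(self, u: float) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate (delta_1..m, omega_0..n) at a single rescaled time u."""
        B = basis_matrix(self.basis, [min(max(u, 0.0), 1.0)]).matrix[0]
        deltas = np.array([float(B @ c) for c in self.delta_coefs])
        omegas = np.array([float(B @ c) for c in self.omega_coefs])
        return deltas, omegas

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "n": self.n,
            "T": self.T,
            "stage": self.stage,
            "basis": self.basis.to_dict(),
            "delta_coefs": [c.tolist() for c in self.delta_coefs],
            "omega_coefs": [c.tolist() for c in self.omega_coefs],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "TVTFModel":
        basis = WaveletBasisSpec.from_dict(d["basis"])
        m, n, T = d["m"], d["n"], d["T"]
        v = max(m, n)
        u = np.arange(v + 1, T + 1) / T
        B = basis_matrix(basis, u).matrix
        dc = [np.asarray(c) for c in d["delta_coefs"]]
        oc = [np.asarray(c) for c in d["omega_coefs"]]
        return cls(
            m=m, n=n, basis=basis, delta_coefs=dc, omega_coefs=oc,
            delta_curves=[B @ c for c in dc], omega_curves=[B @ c for c in oc],
            u_grid=u, fitted=np.array([]), residuals=np.array([]),
            T=T, stage=d["stage"],
        )

    @classmethod
    def from_json(cls, path) -> "TVTFModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _solve(design: np.ndarray, target: np.ndarray, strict_rank: bool):
    """Minimum-norm least squares via SVD; optionally error on rank deficiency."""
    coefs, _, rank, sv = np.linalg.lstsq(design, target, rcond=None)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    if rank < design.shape[1]:
        msg = (
            f"design matrix rank {rank} < {design.shape[1]} columns "
            f"(condition number {cond:.3g})"
        )
        if strict_rank:
            raise ConditioningError(msg)
        warnings.warn(msg + "; returning the minimum-norm solution", stacklevel=3)
    if design.shape[0] < design.shape[1]:
        warnings.warn(
            f"under-determined fit: {design.shape[0]} rows < {design.shape[1]} columns; "
            "minimum-norm solution returned",
            stacklevel=3,
        )
    return coefs, rank, cond


def _assemble(y, x, m, n, basis, lag_source, strict_rank, stage):
    """Shared stage-1/stage-2 fitting: build design, solve, reconstruct curves."""
    y = np.asarray(y, dtype=float)
    psi_y, psi_x, _, u = build_design_matrices(lag_source, x, basis, m, n)
    # response lags come from lag_source; the target and x columns are observed
    design = np.hstack([psi_y, psi_x]) if m > 0 else psi_x
    T = len(y)
    v = max(m, n)
    target = y[v:]
    coefs, rank, cond = _solve(design, target, strict_rank)
    K = basis.n_columns
    delta_coefs = [coefs[(i - 1) * K : i * K] for i in range(1, m + 1)]
    omega_coefs = [coefs[m * K + j * K : m * K + (j + 1) * K] for j in range(n + 1)]
    B = basis_matrix(basis, u).matrix
    fitted = design @ coefs
    return TVTFModel(
        m=m, n=n, basis=basis,
        delta_coefs=delta_coefs, omega_coefs=omega_coefs,
        delta_curves=[B @ c for c in delta_coefs],
        omega_curves=[B @ c for c in omega_coefs],
        u_grid=u, fitted=fitted, residuals=target - fitted,
        T=T, stage=stage, rank=rank, condition_number=cond,
    )


def fit_stage1(
    y: Sequence[float],
    x: Sequence[float],
    m: int,
    n: int,
    basis: WaveletBasisSpec,
    strict_rank: bool = False,
) -> TVTFModel:
    """Stage-1 fit: least squares on observed lagged responses and inputs.

    Minimises  sum_{t=v+1}^T (Y_t - sum_i delta_i(t/T) Y_{t-i}
    - sum_j omega_j(t/T) X_{t-j})^2  over the wavelet coefficients of the
    expanded curves.  With a scaling-only basis this reduces exactly to OLS of
    Y_t on the lagged regressors.
    """
    y = np.asarray(y, dtype=float)
    return _assemble(y, x, m, n, basis, lag_source=y, strict_rank=strict_rank, stage=1)


def fit_stage2(
    stage1: TVTFModel,
    y: Sequence[float],
    x: Sequence[float],
    basis2: Optional[WaveletBasisSpec] = None,
    strict_rank: bool = False,
) -> TVTFModel:
    """Stage-2 refit with lagged responses replaced by stage-1 fitted values.

    The observed Y_{t-i} in the response-lag blocks are swapped for the stage-1
    fitted values (observed values are kept for the first v time points, where
    no fitted value exists).  The resulting residual vector e2 follows, for
    m = 1, a locally stationary MA(2): e2_t = eps_t - delta_1^2(t/T) eps_{t-2}.
    The implied innovations eps_t, recovered by inverting that filter with the
    stage-2 coefficient curve, are stored in ``model.innovations``; their lag-2
    autocorrelation should be indistinguishable from zero when the model is
    correctly specified.
    """
    if stage1.stage != 1 or len(stage1.fitted) == 0:
        raise ValueError("fit_stage2 requires a fitted stage-1 model")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != stage1.T:
        raise ValueError(f"stage-1 model was fitted on T={stage1.T}, got {len(y)} observations")
    basis2 = basis2 if basis2 is not None else stage1.basis
    yhat_full = y.copy()
    yhat_full[stage1.v :] = stage1.fitted
    model = _assemble(
        y, x, stage1.m, stage1.n, basis2, lag_source=yhat_full,
        strict_rank=strict_rank, stage=2,
    )
    model.stage1 = stage1
    if stage1.m == 1:
        # classical reduction: treat e2 as the locally stationary MA(2)
        # e2_t = eps_t - delta_1^2(u_t) eps_{t-2} and invert that filter
        d1sq = model.delta_curves[0] ** 2
        e2 = model.residuals
        eps = e2.copy()
        for t in range(2, len(e2)):
            eps[t] = e2[t] + d1sq[t] * eps[t - 2]
        model.innovations = eps
        # exact one-step decomposition: substituting Yhat_{t-1} = Y_{t-1} - e1_{t-1}
        # into the stage-2 regression gives e2_t = eps_t + delta_1(u_t) e1_{t-1},
        # so subtracting the lagged stage-1 residual recovers the innovation.
        d1 = model.delta_curves[0]
        exact = e2.copy()
        exact[1:] = e2[1:] - d1[1:] * stage1.residuals[:-1]
        model.innovations_exact = exact
    return model


def reconstruct_curve(
    coefs: Sequence[float], basis: WaveletBasisSpec, grid: Sequence[float]
) -> np.ndarray:
    """Inverse wavelet reconstruction of a coefficient curve on ``grid``.

    ``curve(u) = alpha_{0,0} + sum_{j,k} beta_{j,k} psi~_{j,k}(u)`` with the
    coefficient vector ordered as the basis columns (scaling first).
    """
    coefs = np.asarray(coefs, dtype=float)
    if len(coefs) != basis.n_columns:
        raise ValueError(
            f"coefficient vector length {len(coefs)} != basis column count {basis.n_columns}"
        )
    return basis_matrix(basis, grid).matrix @ coefs


def predict(
    model: TVTFModel,
    y: Sequence[float],
    x: Sequence[float],
    start: Optional[int] = None,
    horizon: Optional[int] = None,
    mode: str = "one_step",
) -> np.ndarray:
    """Forecast with the fitted model.

    ``y`` and ``x`` are aligned series covering history and, for ``x``, the
    forecast span; ``start`` is the 1-based time index of the first forecast
    (default: right after the training window).  Coefficient curves are
    evaluated at u = t/T_train, clipped at u = 1 beyond the training window
    (boundary freeze; the curves have support [0, 1]).

    ``mode="one_step"`` uses observed lagged responses from ``y`` (which must
    then cover the forecast span); on the training window this reproduces the
    stored fitted values.  ``mode="recursive"`` feeds forecasts back in as
    lagged responses once t exceeds the observed history.
    """
    if mode not in ("one_step", "recursive"):
        raise ValueError(f"mode must be 'one_step' or 'recursive', got {mode!r}")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    T = model.T
    v = model.v
    if start is None:
        start = T + 1
    if horizon is None:
        horizon = len(x) - (start - 1)
    if horizon <= 0:
        raise ValueError("empty forecast horizon")
    if start - 1 + horizon > len(x):
        raise ValueError(
            f"exogenous series too short: need {start - 1 + horizon} values, have {len(x)}"
        )
    if start <= v:
        raise ValueError(f"forecasts start at t >= v+1 = {v + 1}")
    if mode == "one_step" and model.m > 0 and start - 1 + horizon > len(y):
        raise ValueError("one_step mode requires observed responses over the forecast span")

    u = np.minimum(np.arange(start, start + horizon) / T, 1.0)
    B = basis_matrix(model.basis, u).matrix
    deltas = np.column_stack([B @ c for c in model.delta_coefs]) if model.m else np.empty((horizon, 0))
    omegas = np.column_stack([B @ c for c in model.omega_coefs])

    if mode == "recursive":
        # observed history up to start-1, forecasts fed back in thereafter
        work = np.concatenate([y[: start - 1], np.zeros(horizon)])
    else:
        work = y
    out = np.empty(horizon)
    for h in range(horizon):
        t = start + h  # 1-based
        acc = 0.0
        for i in range(1, model.m + 1):
            acc += deltas[h, i - 1] * work[t - i - 1]
        for j in range(model.n + 1):
            acc += omegas[h, j] * x[t - j - 1]
        out[h] = acc
        if mode == "recursive":
            work[t - 1] = acc
    return out
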