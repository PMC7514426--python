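"""Periodized Daubechies wavelet bases on [0, 1] and lagged-regression design matrices.

Time-varying transfer-function coefficients are expanded in an orthonormal
wavelet series on rescaled time u = t/T.  The basis is the periodized
Daubechies family: the scaling function and mother wavelet are wrapped onto
the unit interval by summing all integer translates,

    phi~_{j,k}(u) = sum_n phi_{j,k}(u - n),    psi~_{j,k}(u) = sum_n psi_{j,k}(u - n),

with phi_{j,k}(x) = 2^{j/2} phi(2^j x - k) and likewise for psi.  At the
coarsest scale the periodized scaling function is the constant 1, so the
expansion of a coefficient curve f on [0, 1] truncated at maximum level J is

    f(u) ~= alpha_{0,0} + sum_{j=0}^{J-1} sum_{k=0}^{2^j - 1} beta_{j,k} psi~_{j,k}(u).

A basis specification selects the Daubechies order (1 = Haar ... 10) and the
subset of resolution levels retained; the implied number of basis columns is
1 + sum_{j in levels} 2^j, reaching 2^J when all levels 0..J-1 are kept.

Non-Haar Daubechies functions have no closed form; they are realised by the
cascade algorithm on a dyadic grid of 2^12 points per unit interval and
linearly interpolated to arbitrary u.  Haar is evaluated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pywt

__all__ = [
    "WaveletBasisSpec",
    "BasisEvaluation",
    "evaluate_periodized",
    "basis_matrix",
    "build_design_matrices",
]

_CASCADE_DEPTH = 12  # dyadic refinement of the cascade evaluation


class LevelCapacityError(ValueError):
    """Raised when the requested maximum level exceeds what T observations support."""


@dataclass(frozen=True)
class WaveletBasisSpec:
    """Specification of a truncated periodized Daubechies basis.

    Parameters
    ----------
    daubechies_order:
        Order of the Daubechies filter, 1 (Haar) through 10.
    max_level:
        Maximum level J of the expansion; retained levels live in {0, ..., J-1}.
    levels:
        Ordered subset of {0, ..., J-1} kept in the expansion.  The periodized
        scaling function (a constant) is always included.  Defaults to all
        levels 0..J-1.
    """

    daubechies_order: int
    max_level: int
    levels: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 1 <= self.daubechies_order <= 10:
            raise ValueError(f"daubechies_order must be in 1..10, got {self.daubechies_order}")
        if self.max_level < 0:
            raise ValueError(f"max_level must be >= 0, got {self.max_level}")
        if self.levels is None:
            object.__setattr__(self, "levels", tuple(range(self.max_level)))
        else:
            lv = tuple(sorted(int(j) for j in self.levels))
            if len(set(lv)) != len(lv):
                raise ValueError(f"duplicate levels in {self.levels}")
            if any(j < 0 or j >= self.max_level for j in lv):
                raise ValueError(f"levels {lv} not a subset of 0..{self.max_level - 1}")
            object.__setattr__(self, "levels", lv)

    @property
    def n_columns(self) -> int:
        """Number of basis columns: scaling constant plus 2^j per retained level."""
        return 1 + sum(2**j for j in self.levels)

    def column_labels(self) -> list[tuple]:
        """Stable column ordering: scaling first, then (level, shift) ascending."""
        labels: list[tuple] = [("phi", 0, 0)]
        for j in self.levels:
            labels.extend(("psi", j, k) for k in range(2**j))
        return labels

    def to_dict(self) -> dict:
        return {
            "daubechies_order": self.daubechies_order,
            "max_level": self.max_level,
            "levels": list(self.levels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WaveletBasisSpec":
        return cls(d["daubechies_order"], d["max_level"], tuple(d["levels"]))


@dataclass(frozen=True)
class BasisEvaluation:
    """Sampled basis: ``matrix[r, c]`` is column ``labels[c]`` at ``grid[r]``."""

    grid: np.ndarray
    matrix: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.grid), len(self.labels)):
            raise ValueError("basis matrix shape does not match grid/labels")


@lru_cache(maxsize=16)
def _cascade(order: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mother scaling/wavelet samples (phi, psi, x) for Daubechies ``order``.

    Support is [0, 2*order - 1] in pywt's convention; an integer shift of the
    mother function only relabels the periodized shifts k mod 2^j, so the
    spanned spaces are unchanged.
    """
    phi, psi, x = pywt.Wavelet(f"db{order}").wavefun(level=_CASCADE_DEPTH)
    return np.asarray(phi), np.asarray(psi), np.asarray(x)


def _mother(order: int, points: np.ndarray, kind: str) -> np.ndarray:
    """Evaluate the (non-periodized) mother phi or psi at arbitrary points."""
    if order == 1:  # Haar, exact
        if kind == "phi":
            return ((points >= 0.0) & (points < 1.0)).astype(float)
        return np.where(
            (points >= 0.0) & (points < 0.5),
            1.0,
            np.where((points >= 0.5) & (points < 1.0), -1.0, 0.0),
        )
    phi, psi, x = _cascade(order)
    y = phi if kind == "phi" else psi
    return np.interp(points, x, y, left=0.0, right=0.0)


def evaluate_periodized(
    spec: WaveletBasisSpec,
    j: int,
    k: int,
    points: Sequence[float],
    kind: str = "psi",
) -> np.ndarray:
    """Evaluate the periodized wavelet psi~_{j,k} (or scaling phi~_{j,k}) at ``points``.

    Points are taken modulo 1 (the periodized functions are 1-periodic).  The
    level-0 periodized scaling function is the constant 1 and is returned
    exactly.
    """
    if kind not in ("psi", "phi"):
        raise ValueError(f"kind must be 'psi' or 'phi', got {kind!r}")
    if j < 0:
        raise IndexError(f"level j must be >= 0, got {j}")
    if not 0 <= k <= 2**j - 1:
        raise IndexError(f"shift k={k} out of range 0..{2**j - 1} for level j={j}")
    u = np.mod(np.asarray(points, dtype=float), 1.0)
    if kind == "phi" and j == 0:
        # partition of unity: sum_n phi(x - n) = 1 for all Daubechies orders
        return np.ones_like(u)
    # psi~_{j,k}(u) = 2^{j/2} sum_n psi(2^j u - k - 2^j n); finitely many n hit
    # the compact support [0, 2*order - 1].
    s = (2.0**j) * u - k
    support_len = 2 * spec.daubechies_order - 1
    n_lo = int(np.floor((s.min() - support_len) / 2.0**j))
    n_hi = int(np.ceil(s.max() / 2.0**j))
    out = np.zeros_like(u)
    for n in range(n_lo, n_hi + 1):
        out += _mother(spec.daubechies_order, s - n * 2.0**j, kind)
    return (2.0 ** (j / 2.0)) * out


def basis_matrix(spec: WaveletBasisSpec, grid: Sequence[float]) -> BasisEvaluation:
    """Sample every retained basis function on ``grid``.

    Columns are ordered scaling first, then wavelet levels ascending with
    shifts ascending within each level.
    """
    grid = np.asarray(grid, dtype=float)
    labels = spec.column_labels()
    cols = np.empty((len(grid), len(labels)))
    cols[:, 0] = 1.0
    c = 1
    for j in spec.levels:
        for k in range(2**j):
            cols[:, c] = evaluate_periodized(spec, j, k, grid, kind="psi")
            c += 1
    return BasisEvaluation(grid=grid, matrix=cols, labels=tuple(labels))


def build_design_matrices(
    y: Sequence[float],
    x: Sequence[float],
    spec: WaveletBasisSpec,
    m: int,
    n: int,
) -> tuple[np.ndarray, np.ndarray, list[tuple], np.ndarray]:
    """Assemble the stacked least-squares design for the time-varying model.

    The regression runs over t = v+1, ..., T with v = max(m, n).  For response
    lag i the block columns are  basis_col(t/T) * y_{t-i};  for input lag j
    they are  basis_col(t/T) * x_{t-j}.  Returns ``(Psi_Y, Psi_X, labels,
    u_grid)`` where labels name each column ``(series, lag, basis_label)`` and
    ``u_grid`` holds the rescaled times t/T of the retained rows.

    Raises
    ------
    LevelCapacityError
        If T < 2**max_level (more dyadic shifts than observations).
    ValueError
        If y and x differ in length.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError(f"y and x must be 1-d of equal length, got {y.shape} vs {x.shape}")
    T = len(y)
    if T < 2**spec.max_level:
        raise LevelCapacityError(
            f"T={T} observations cannot support max_level={spec.max_level} "
            f"(needs T >= {2**spec.max_level})"
        )
    v = max(m, n)
    if T <= v:
        raise ValueError(f"series too short: T={T} with v=max(m,n)={v}")
    t = np.arange(v + 1, T + 1)  # 1-based time of retained rows
    u = t / T
    B = basis_matrix(spec, u).matrix
    K = B.shape[1]
    basis_labels = spec.column_labels()

    psi_y = np.empty((len(t), m * K))
    labels: list[tuple] = []
    for i in range(1, m + 1):
        psi_y[:, (i - 1) * K : i * K] = B * y[t - i - 1][:, None]
        labels.extend(("y", i, lab) for lab in basis_labels)
    psi_x = np.empty((len(t), (n + 1) * K))
    for j in range(0, n + 1):
        psi_x[:, j * K : (j + 1) * K] = B * x[t - j - 1][:, None]
        labels.extend(("x", j, lab) for lab in basis_labels)
    return psi_y, psi_x, labels, u
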