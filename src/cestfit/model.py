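"""Lorentzian line-shape mathematics for z-spectrum decomposition.

A z-spectrum is the normalized water-signal reduction ``y = 1 - I/I0`` as a
function of the saturation frequency offset ``omega`` (in ppm).  It is modeled
as a sum of ``K`` Lorentzian lines, one per exchangeable proton pool::

    y(omega) = sum_k  a_k / (1 + 4 ((omega - w_k) / s_k)^2)

where ``a_k`` is the pool amplitude (fraction of the unsaturated signal I0),
``w_k`` the center frequency (ppm) and ``s_k`` the full width at half maximum
(ppm): the line attains ``a_k`` at ``omega = w_k`` and ``a_k / 2`` at
``omega = w_k +/- s_k / 2``.

This module provides model evaluation, residuals, the linear design matrix in
the amplitudes, the analytic Jacobian of the model with respect to all
``3K`` parameters, the closed-form line integral, and signal normalization.
The parameter vector layout used throughout is per-pool triplets
``[a_1, w_1, s_1, a_2, w_2, s_2, ...]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PoolSpec",
    "PoolTable",
    "ZSpectrum",
    "normalize",
    "eval_model",
    "residuals",
    "design_matrix",
    "jacobian",
    "pool_integral",
]


@dataclass(frozen=True)
class PoolSpec:
    """One Lorentzian component: start value and box bounds per parameter.

    Parameters
    ----------
    name:
        Unique pool label (e.g. ``"water"``, ``"amide"``).
    a_start, a_lo, a_hi:
        Amplitude start value and bounds, dimensionless fraction of I0,
        restricted to [0, 1].
    w_start, w_lo, w_hi:
        Center frequency start value and bounds, ppm.
    s_start, s_lo, s_hi:
        Width (FWHM) start value and bounds, ppm; the lower bound must be
        strictly positive (a zero-width line is excluded by construction,
        not regularized away).
    """

    name: str
    a_start: float
    a_lo: float
    a_hi: float
    w_start: float
    w_lo: float
    w_hi: float
    s_start: float
    s_lo: float
    s_hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a_lo <= self.a_start <= self.a_hi <= 1.0):
            raise ValueError(
                f"pool {self.name!r}: amplitude must satisfy "
                f"0 <= a_lo <= a_start <= a_hi <= 1 "
                f"(got lo={self.a_lo}, start={self.a_start}, hi={self.a_hi})"
            )
        if not (self.w_lo <= self.w_start <= self.w_hi):
            raise ValueError(
                f"pool {self.name!r}: frequency start {self.w_start} outside "
                f"bounds [{self.w_lo}, {self.w_hi}]"
            )
        if not (self.s_lo <= self.s_start <= self.s_hi):
            raise ValueError(
                f"pool {self.name!r}: width start {self.s_start} outside "
                f"bounds [{self.s_lo}, {self.s_hi}]"
            )
        if not self.s_lo > 0:
            raise ValueError(
                f"pool {self.name!r}: width lower bound must be > 0 "
                f"(got {self.s_lo})"
            )

    @property
    def start(self) -> tuple[float, float, float]:
        return (self.a_start, self.w_start, self.s_start)

    @property
    def lower(self) -> tuple[float, float, float]:
        return (self.a_lo, self.w_lo, self.s_lo)

    @property
    def upper(self) -> tuple[float, float, float]:
        return (self.a_hi, self.w_hi, self.s_hi)


@dataclass(frozen=True)
class PoolTable:
    """Ordered collection of :class:`PoolSpec` with unique names."""

    pools: tuple[PoolSpec, ...]

    def __init__(self, pools: Iterable[PoolSpec]):
        object.__setattr__(self, "pools", tuple(pools))
        if len(self.pools) < 1:
            raise ValueError("pool table must contain at least one pool")
        names = [p.name for p in self.pools]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate pool names in table: {names}")

    def __len__(self) -> int:
        return len(self.pools)

    def __iter__(self):
        return iter(self.pools)

    def __getitem__(self, i: int) -> PoolSpec:
        return self.pools[i]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pools]

    def start_vector(self) -> np.ndarray:
        """Stacked start values ``[a_1, w_1, s_1, a_2, ...]``."""
        return np.array([v for p in self.pools for v in p.start], dtype=float)

    def bound_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([v for p in self.pools for v in p.lower], dtype=float)
        hi = np.array([v for p in self.pools for v in p.upper], dtype=float)
        return lo, hi


@dataclass(frozen=True)
class ZSpectrum:
    """One pixel's z-spectrum: offsets (ppm) and values ``y = 1 - I/I0``."""

    offsets: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "values", values)
        if offsets.ndim != 1 or values.ndim != 1:
            raise ValueError("offsets and values must be 1-D")
        if offsets.shape != values.shape:
            raise ValueError(
                f"offsets ({offsets.shape[0]}) and values ({values.shape[0]}) "
                "differ in length"
            )
        if not np.all(np.diff(offsets) > 0):
            raise ValueError("offsets must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("spectrum values must be finite")

    def __len__(self) -> int:
        return len(self.offsets)

    def check_dof(self, n_pools: int) -> None:
        """Degrees-of-freedom guard: need at least 3 points per pool."""
        if len(self) < 3 * n_pools:
            raise ValueError(
                f"{len(self)} offsets cannot constrain {n_pools} pools "
                f"(need >= {3 * n_pools})"
            )


def normalize(intensities: np.ndarray, i0: float) -> np.ndarray:
    """Convert raw intensities to z-spectrum values ``y = 1 - I/I0``.

    ``I0`` is the signal without pre-saturation; ``y`` is the fractional
    saturation-induced signal reduction, 0 where saturation has no effect.
    """
    if not np.isfinite(i0) or i0 <= 0:
        raise ValueError(f"reference intensity I0 must be finite and > 0, got {i0}")
    intensities = np.asarray(intensities, dtype=float)
    if np.any(intensities < 0):
        raise ValueError("intensities must be non-negative")
    return 1.0 - intensities / i0


def _as_param_array(pools) -> np.ndarray:
    """Coerce pools given as PoolTable, (K,3) array or flat vector to (K,3)."""
    if isinstance(pools, PoolTable):
        arr = pools.start_vector().reshape(-1, 3)
    else:
        arr = np.asarray(pools, dtype=float)
        if arr.ndim == 1:
            if arr.size % 3:
                raise ValueError("flat parameter vector length must be 3K")
            arr = arr.reshape(-1, 3)
        elif arr.ndim == 2 and arr.shape[1] == 3:
            pass
        else:
            raise ValueError("pools must be a (K, 3) array of (a, w, s) rows")
    if arr.size and np.any(arr[:, 2] <= 0):
        raise ValueError("all widths must be > 0")
    return arr


def eval_model(pools, offsets: np.ndarray) -> np.ndarray:
    """Evaluate the sum-of-Lorentzians model on an offset grid.

    ``pools`` may be a :class:`PoolTable` (start values are used), a (K, 3)
    array of ``(a, w, s)`` rows, or a flat length-3K vector.  An empty pool
    list yields zeros.
    """
    arr = _as_param_array(pools)
    offsets = np.asarray(offsets, dtype=float)
    if arr.size == 0:
        return np.zeros_like(offsets)
    # (N, K) broadcast: u = (omega - w_k) / s_k
    u = (offsets[:, None] - arr[None, :, 1]) / arr[None, :, 2]
    return (arr[:, 0] / (1.0 + 4.0 * u * u)).sum(axis=1)


def residuals(pools, spectrum: ZSpectrum) -> np.ndarray:
    """Residual vector ``r_i = y_i - model(omega_i)``.

    The sum of squared residuals is the least-squares objective the fitter
    minimizes.
    """
    return spectrum.values - eval_model(pools, spectrum.offsets)


def design_matrix(pools, offsets: np.ndarray) -> np.ndarray:
    """N x K matrix of unit-amplitude Lorentzian lines.

    The model is linear in the amplitudes: ``eval_model == Psi @ a``.
    """
    arr = _as_param_array(pools)
    offsets = np.asarray(offsets, dtype=float)
    u = (offsets[:, None] - arr[None, :, 1]) / arr[None, :, 2]
    return 1.0 / (1.0 + 4.0 * u * u)


def jacobian(pools, offsets: np.ndarray) -> np.ndarray:
    """Analytic N x 3K Jacobian of the *model* (not the residual).

    Columns are ordered per pool as (d/da_k, d/dw_k, d/ds_k)::

        d/da = 1 / D
        d/dw = 8 a (omega - w) / (s^2 D^2)
        d/ds = 8 a (omega - w)^2 / (s^3 D^2)

    with ``D = 1 + 4 ((omega - w)/s)^2``.  Because the fit residual is
    ``y - model``, the residual Jacobian is the negation of this matrix;
    the sign flip happens at the fitter boundary.
    """
    arr = _as_param_array(pools)
    offsets = np.asarray(offsets, dtype=float)
    n, k = offsets.size, arr.shape[0]
    J = np.empty((n, 3 * k), dtype=float)
    a = arr[:, 0]
    d = offsets[:, None] - arr[None, :, 1]  # omega - w_k
    s = arr[:, 2]
    D = 1.0 + 4.0 * (d / s) ** 2
    D2 = D * D
    J[:, 0::3] = 1.0 / D
    J[:, 1::3] = 8.0 * a * d / (s**2 * D2)
    J[:, 2::3] = 8.0 * a * d * d / (s**3 * D2)
    return J


def pool_integral(a: float, s: float) -> float:
    """Area under one Lorentzian line over all offsets: ``a * pi * s / 2``."""
    if s <= 0:
        raise ValueError(f"width must be > 0, got {s}")
    if a < 0:
        raise ValueError(f"amplitude must be >= 0, got {a}")
    return a * np.pi * s / 2.0
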