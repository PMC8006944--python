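"""Continuous glucose input for the forward model.

The secretion model needs glucose concentration G(t) and its time
derivative as continuous, error-free inputs, but oral tests sample
glucose every 15-30 min.  This module (i) estimates the derivative on a
fine virtual grid by regularized deconvolution — fitting the derivative
whose running integral matches the samples, with a second-difference
(curvature) penalty tuned by the discrepancy criterion — and
(ii) wraps samples into a :class:`~ocmm.core.GlucoseSignal` with a
monotone-preserving interpolant and a smooth extension back to basal
beyond the last sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "estimate_derivative",
    "build_glucose_signal",
    "SampledGlucoseSignal",
    "CallableGlucoseSignal",
    "DenseGlucoseSignal",
]

#: step of the virtual grid, min
FINE_DT = 1.0
#: duration of the linear relaxation back to basal after the last sample, min
RELAX_MINUTES = 60.0


def _validate_samples(times: np.ndarray, glucose: np.ndarray, min_samples: int = 5) -> None:
    if times.ndim != 1 or times.shape != glucose.shape:
        raise ValueError("times and glucose must be 1-d arrays of equal length")
    if times.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {times.size}")
    if not np.all(np.diff(times) > 0):
        raise ValueError("sample times must be strictly increasing")
    if not np.all(np.isfinite(glucose)):
        raise ValueError("glucose samples must be finite")


def _tikhonov_solve(
    a: np.ndarray, w: np.ndarray, y: np.ndarray, d2: np.ndarray, gamma: float
) -> np.ndarray:
    h = a.T @ (w[:, None] * a) + gamma * (d2.T @ d2)
    try:
        return np.linalg.solve(h, a.T @ (w * y))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"regularization system singular at gamma={gamma:.3g}: {exc}"
        ) from exc


def estimate_derivative(
    times: Sequence[float],
    glucose: Sequence[float],
    noise_cv: float = 0.02,
    *,
    gamma: float | None = None,
    sigma: Sequence[float] | None = None,
    dt: float = FINE_DT,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate dG/dt on a uniform virtual grid from sparse samples.

    Solves the discrete Tikhonov problem: find the derivative ``u`` on the
    fine grid minimizing the measurement-weighted misfit of its running
    (trapezoid) integral to the above-first-sample glucose excursion,
    plus ``gamma`` times the squared second difference of ``u``.  When
    ``gamma`` is not given it is chosen by the discrepancy criterion
    (weighted residual sum of squares equal to the number of residuals),
    with the measurement SD taken as ``noise_cv`` times the sample value.

    Returns
    -------
    (grid, u) : the virtual time grid (min, step ``dt``) and the
        estimated derivative on it (mmol/L/min).
    """
    times = np.asarray(times, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    _validate_samples(times, glucose)
    t0, t_last = times[0], times[-1]
    n_nodes = int(round((t_last - t0) / dt)) + 1
    grid = t0 + dt * np.arange(n_nodes)
    idx = np.round((times - t0) / dt).astype(int)
    if not np.allclose(t0 + idx * dt, times, atol=dt / 4):
        raise ValueError(f"sample times must lie on the {dt}-min virtual grid")

    # cumulative-trapezoid design matrix: row i integrates u from t0 to t_i
    a = np.zeros((times.size - 1, n_nodes))
    for row, m in enumerate(idx[1:]):
        a[row, : m + 1] = dt
        a[row, 0] = a[row, m] = dt / 2.0
    y = glucose[1:] - glucose[0]

    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != y.shape or np.any(sigma <= 0):
            raise ValueError("sigma must be positive with one entry per post-basal sample")
    else:
        sigma = np.maximum(noise_cv, 0.0) * np.abs(glucose[1:])
        floor = 1e-3 * max(np.max(np.abs(glucose)), 1.0)
        sigma = np.maximum(sigma, floor)
    w = 1.0 / sigma**2

    d2 = np.zeros((n_nodes - 2, n_nodes))
    for i in range(n_nodes - 2):
        d2[i, i : i + 3] = (1.0, -2.0, 1.0)

    if gamma is not None:
        if not gamma >= 0:
            raise ValueError(f"gamma must be >= 0, got {gamma}")
        return grid, _tikhonov_solve(a, w, y, d2, gamma)

    target = float(y.size)

    def wrss(g: float) -> float:
        u = _tikhonov_solve(a, w, y, d2, g)
        r = y - a @ u
        return float(np.sum(w * r**2))

    lo, hi = -10.0, 8.0  # log10 gamma bracket
    if wrss(10.0**hi) <= target:
        chosen = 10.0**hi
    elif wrss(10.0**lo) >= target:
        chosen = 10.0**lo
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if wrss(10.0**mid) < target:
                lo = mid
            else:
                hi = mid
        chosen = 10.0 ** (0.5 * (lo + hi))
    return grid, _tikhonov_solve(a, w, y, d2, chosen)


def _as_float_array(t) -> tuple[np.ndarray, bool]:
    arr = np.asarray(t, dtype=float)
    return np.atleast_1d(arr), arr.ndim == 0


@dataclass
class SampledGlucoseSignal:
    """Glucose input built from oral-test samples.

    Inside the sampled window G(t) is the monotone-preserving piecewise
    cubic through the samples; beyond the last sample it relaxes linearly
    to basal over :data:`RELAX_MINUTES` and then holds.  The derivative
    is the regularized-deconvolution estimate inside the window and 0
    outside (the extension is treated as secretion-silent tail).
    """

    times: np.ndarray
    samples: np.ndarray
    basal: float
    maximum: float
    t_last: float
    horizon: float
    _interp: PchipInterpolator = field(repr=False)
    _dgrid: np.ndarray = field(repr=False)
    _dvals: np.ndarray = field(repr=False)

    def value(self, t):
        tv, scalar = _as_float_array(t)
        out = np.empty_like(tv)
        g_last = float(self._interp(self.t_last))
        t_relax_end = self.t_last + RELAX_MINUTES
        inside = tv <= self.t_last
        out[inside] = self._interp(np.clip(tv[inside], self.times[0], self.t_last))
        relax = (tv > self.t_last) & (tv < t_relax_end)
        out[relax] = g_last + (self.basal - g_last) * (tv[relax] - self.t_last) / RELAX_MINUTES
        out[tv >= t_relax_end] = self.basal
        return float(out[0]) if scalar else out

    def derivative(self, t):
        tv, scalar = _as_float_array(t)
        out = np.where(
            (tv >= self._dgrid[0]) & (tv <= self._dgrid[-1]),
            np.interp(tv, self._dgrid, self._dvals),
            0.0,
        )
        return float(out[0]) if scalar else out

    def derivative_sign_changes(self) -> list[float]:
        u, g = self._dvals, self._dgrid
        crossings: list[float] = []
        for i in range(u.size - 1):
            if u[i] == 0.0 or u[i] * u[i + 1] < 0:
                # linear zero crossing between nodes
                if u[i] == 0.0:
                    crossings.append(float(g[i]))
                else:
                    frac = u[i] / (u[i] - u[i + 1])
                    crossings.append(float(g[i] + frac * (g[i + 1] - g[i])))
        crossings.append(float(self.t_last))
        return crossings


def build_glucose_signal(
    times: Sequence[float],
    glucose: Sequence[float],
    t_total: float = 300.0,
    *,
    noise_cv: float = 0.02,
) -> SampledGlucoseSignal:
    """Build the continuous glucose input required by the forward model.

    ``t_total`` is the horizon out to which the signal must be defined
    (the responsivity integrals run to 300 min even when sampling stops
    at 180-210 min); it must not precede the last sample.
    """
    times = np.asarray(times, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    _validate_samples(times, glucose)
    if np.any(glucose <= 0):
        raise ValueError("glucose concentrations must be positive")
    if times[0] != 0:
        raise ValueError(f"first sample must be at t=0, got t={times[0]}")
    if t_total < times[-1]:
        raise ValueError(f"t_total={t_total} precedes the last sample t={times[-1]}")
    dgrid, dvals = estimate_derivative(times, glucose, noise_cv)
    return SampledGlucoseSignal(
        times=times,
        samples=glucose,
        basal=float(glucose[0]),
        maximum=float(glucose.max()),
        t_last=float(times[-1]),
        horizon=float(t_total),
        _interp=PchipInterpolator(times, glucose),
        _dgrid=dgrid,
        _dvals=dvals,
    )


@dataclass
class CallableGlucoseSignal:
    """Analytic glucose signal for tests and simulation (exact G and dG/dt)."""

    g: Callable
    dg: Callable
    basal: float
    maximum: float
    t_last: float
    sign_changes: tuple[float, ...] = ()

    def value(self, t):
        tv, scalar = _as_float_array(t)
        out = np.asarray(self.g(tv), dtype=float)
        return float(out[0]) if scalar else out

    def derivative(self, t):
        tv, scalar = _as_float_array(t)
        out = np.asarray(self.dg(tv), dtype=float)
        return float(out[0]) if scalar else out

    def derivative_sign_changes(self) -> list[float]:
        return list(self.sign_changes)


class DenseGlucoseSignal:
    """Glucose signal defined by a dense curve on a uniform grid.

    Used for simulated profiles where the curve is known essentially
    continuously; values interpolate linearly and the derivative is the
    central finite difference of the dense curve.
    """

    def __init__(self, grid: Sequence[float], values: Sequence[float]):
        grid = np.asarray(grid, dtype=float)
        values = np.asarray(values, dtype=float)
        if grid.ndim != 1 or grid.shape != values.shape or grid.size < 3:
            raise ValueError("grid and values must be equal-length 1-d arrays (>= 3 points)")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(values <= 0):
            raise ValueError("glucose values must be positive")
        self._grid = grid
        self._values = values
        self._deriv = np.gradient(values, grid)
        self.basal = float(values[0])
        self.maximum = float(values.max())
        self.t_last = float(grid[-1])
        self.horizon = float(grid[-1])

    def value(self, t):
        tv, scalar = _as_float_array(t)
        out = np.interp(tv, self._grid, self._values)
        return float(out[0]) if scalar else out

    def derivative(self, t):
        tv, scalar = _as_float_array(t)
        out = np.where(
            (tv >= self._grid[0]) & (tv <= self._grid[-1]),
            np.interp(tv, self._grid, self._deriv),
            0.0,
        )
        return float(out[0]) if scalar else out

    def derivative_sign_changes(self) -> list[float]:
        u = self._deriv
        g = self._grid
        out: list[float] = []
        for i in range(u.size - 1):
            if u[i] * u[i + 1] < 0:
                frac = u[i] / (u[i] - u[i + 1])
                out.append(float(g[i] + frac * (g[i + 1] - g[i])))
        return out

    def sample(self, times: Sequence[float]) -> np.ndarray:
        return np.asarray(self.value(np.asarray(times, dtype=float)))
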