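"""Forward model: two-compartment C-peptide kinetics driven by glucose-controlled secretion.

The model interprets plasma C-peptide as the output of a linear
two-compartment system (central concentration ``CP1``, peripheral
``CP2``, both above basal) forced by pancreatic secretion ``SR``
normalized by the central volume of distribution::

    dCP1/dt = -(k01 + k21)*CP1 + k12*CP2 + SR(t)      CP1(0) = 0
    dCP2/dt = k21*CP1 - k12*CP2                        CP2(0) = 0

Secretion is the sum of a *static* component — the provision ``Y`` of new
releasable hormone, relaxing with rate ``alpha`` toward ``beta*(G - h)``
— and a *dynamic* component proportional (``k_d``) to the rate of
glucose increase, active only while glucose is rising::

    SR(t)  = Y(t) + k_d * max(dG/dt, 0)
    dY/dt  = -alpha * (Y - beta*(G(t) - h))            Y(0) = 0

Units are fixed project-wide: glucose in mmol/L, C-peptide in pmol/L,
time in min.  The ratio pmol/L over mmol/L carries a factor 10^-9 in
molar terms, so the responsivity indices computed from ``beta`` and
``k_d`` are numerically on the conventional "x 10^-9" display scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "KineticParams",
    "SecretionParams",
    "CPState",
    "ResponsivityIndices",
    "GlucoseSignal",
    "simulate_ocmm",
    "simulate_secretion_driven",
    "FastOCMMSimulator",
    "basal_secretion",
    "responsivity_indices",
]

_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-10


def _require_finite_positive(name: str, value: float, *, allow_zero: bool = False) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")
    if allow_zero:
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")
    elif value <= 0:
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the two-compartment C-peptide model, all in min^-1.

    ``k01`` is the fractional clearance from the central compartment and
    equals the C-peptide metabolic clearance rate (MCR); ``k21`` and
    ``k12`` are the central->peripheral and peripheral->central exchange
    rates.
    """

    k01: float
    k12: float
    k21: float

    def __post_init__(self) -> None:
        for name in ("k01", "k12", "k21"):
            _require_finite_positive(name, getattr(self, name))

    @property
    def mcr(self) -> float:
        """Metabolic clearance rate, an alias for ``k01`` (min^-1)."""
        return self.k01

    def as_array(self) -> np.ndarray:
        return np.array([self.k01, self.k12, self.k21])


@dataclass(frozen=True)
class SecretionParams:
    """Parameters of the glucose-controlled secretion model.

    k_d : dynamic responsivity to the rate of glucose increase
        (pmol/L per mmol/L, i.e. dimensionless on the 10^-9 molar scale).
    alpha : inverse time constant of provision, min^-1.
    beta : static responsivity, (pmol/L/min per mmol/L), i.e. min^-1 on
        the 10^-9 scale.
    h : glucose threshold of the static component, mmol/L; fixed to the
        pre-test basal glucose.
    """

    k_d: float
    alpha: float
    beta: float
    h: float

    def __post_init__(self) -> None:
        _require_finite_positive("k_d", self.k_d, allow_zero=True)
        _require_finite_positive("alpha", self.alpha)
        _require_finite_positive("beta", self.beta, allow_zero=True)
        _require_finite_positive("h", self.h)


@dataclass(frozen=True)
class CPState:
    """Model state: above-basal central/peripheral C-peptide and provision."""

    cp1: float = 0.0
    cp2: float = 0.0
    y: float = 0.0


@dataclass(frozen=True)
class ResponsivityIndices:
    """Beta-cell responsivity indices on the 10^-9 display scale.

    phi_s (10^-9 min^-1) and phi_d (10^-9) equal ``beta`` and ``k_d``;
    phi_b = SR_b / G_b (10^-9 min^-1); phi_tot is the average total
    secretion over the test normalized by average glucose.
    """

    phi_s: float
    phi_d: float
    phi_b: float
    phi_tot: float

    def as_dict(self) -> dict[str, float]:
        return {
            "phi_s": self.phi_s,
            "phi_d": self.phi_d,
            "phi_b": self.phi_b,
            "phi_tot": self.phi_tot,
        }


@runtime_checkable
class GlucoseSignal(Protocol):
    """Continuous glucose input: concentration, derivative, basal and max.

    Concrete signals are built by :mod:`ocmm.glucose`; any object with
    this surface (e.g. an analytic test signal) is accepted by the
    forward model.
    """

    basal: float
    maximum: float
    t_last: float

    def value(self, t):  # G(t), mmol/L
        ...

    def derivative(self, t):  # dG/dt, mmol/L/min
        ...

    def derivative_sign_changes(self) -> Sequence[float]:
        """Times where dG/dt changes sign (integration breakpoints)."""
        ...


def basal_secretion(k01: float, cp1_basal: float) -> float:
    """Basal secretion rate SR_b = k01 * CP1b, in pmol/L/min."""
    _require_finite_positive("k01", k01)
    _require_finite_positive("cp1_basal", cp1_basal)
    return k01 * cp1_basal


def _segment_times(t0: float, t1: float, breakpoints: Sequence[float]) -> list[float]:
    pts = sorted({float(b) for b in breakpoints if t0 < b < t1})
    return [t0, *pts, t1]


def _integrate_piecewise(
    rhs: Callable,
    x0: np.ndarray,
    t_eval: np.ndarray,
    breakpoints: Sequence[float],
) -> np.ndarray:
    """RK45 integration restarted at breakpoints, sampled on t_eval."""
    t_eval = np.asarray(t_eval, dtype=float)
    out = np.empty((t_eval.size, x0.size))
    knots = _segment_times(t_eval[0], t_eval[-1], breakpoints)
    x = np.array(x0, dtype=float)
    # record states at t_eval points exactly on the segment boundaries too
    filled = np.zeros(t_eval.size, dtype=bool)
    on_start = np.isclose(t_eval, knots[0])
    out[on_start] = x
    filled |= on_start
    for ta, tb in zip(knots[:-1], knots[1:]):
        if tb <= ta:
            continue
        inside = (~filled) & (t_eval > ta) & (t_eval <= tb + 1e-12)
        te = np.unique(np.concatenate([t_eval[inside], [tb]]))
        sol = solve_ivp(
            rhs, (ta, tb), x, method="RK45", t_eval=te, rtol=_ODE_RTOL, atol=_ODE_ATOL
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{ta}, {tb}]: {sol.message}")
        x = sol.y[:, -1]
        for j, t in enumerate(te):
            hits = inside & np.isclose(t_eval, t)
            out[hits] = sol.y[:, j]
            filled |= hits
    if not filled.all():
        raise RuntimeError("internal error: some evaluation times were not integrated")
    return out


def simulate_secretion_driven(
    kin: KineticParams,
    sr: Callable[[float], float],
    t_eval: Sequence[float],
    breakpoints: Sequence[float] = (),
) -> np.ndarray:
    """Integrate the two-compartment kinetics under an arbitrary secretion forcing.

    ``sr(t)`` is the above-basal secretion in pmol/L/min.  Returns the
    above-basal central concentration CP1 on ``t_eval``.  ``breakpoints``
    mark discontinuities of ``sr`` where the integrator is restarted.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    _check_grid(t_eval)

    def rhs(t, x):
        cp1, cp2 = x
        return (
            -(kin.k01 + kin.k21) * cp1 + kin.k12 * cp2 + sr(t),
            kin.k21 * cp1 - kin.k12 * cp2,
        )

    states = _integrate_piecewise(rhs, np.zeros(2), t_eval, breakpoints)
    return states[:, 0]


def _check_grid(t_eval: np.ndarray) -> None:
    if t_eval.ndim != 1 or t_eval.size < 2:
        raise ValueError("t_eval must be a 1-d grid with at least two points")
    if t_eval[0] != 0:
        raise ValueError(f"t_eval must start at 0, got {t_eval[0]}")
    if not np.all(np.diff(t_eval) > 0):
        raise ValueError("t_eval must be strictly increasing")


def _system_matrices(kin: KineticParams, sec: SecretionParams) -> tuple[np.ndarray, np.ndarray]:
    """State matrix A for x=(CP1, CP2, Y) and input matrix B for u=(dG+/dt, G-h)."""
    a = np.array(
        [
            [-(kin.k01 + kin.k21), kin.k12, 1.0],
            [kin.k21, -kin.k12, 0.0],
            [0.0, 0.0, -sec.alpha],
        ]
    )
    b = np.array([[sec.k_d, 0.0], [0.0, 0.0], [0.0, sec.alpha * sec.beta]])
    return a, b


def _simulate_lti_foh(
    kin: KineticParams,
    sec: SecretionParams,
    g: GlucoseSignal,
    t_eval: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Exact discretization of the linear system under piecewise-linear inputs.

    The full model (CP1, CP2, Y) is linear and time-invariant with inputs
    u1 = max(dG/dt, 0) and u2 = G - h; sampling the inputs on a uniform
    grid and propagating with the first-order-hold (Van Loan) matrix
    exponential is exact for piecewise-linear inputs and
    O(dt^2)-accurate otherwise.
    """
    return FastOCMMSimulator(g, t_eval, sec.h, dt).cp1(kin, sec)


class FastOCMMSimulator:
    """Reusable matrix-exponential simulator bound to one glucose signal.

    Pre-samples the two model inputs (positive part of dG/dt and G - h)
    on a uniform grid once, so repeated simulation during parameter
    estimation only pays for one 7x7 matrix exponential and a short
    state recursion per parameter vector.
    """

    def __init__(self, g: GlucoseSignal, t_eval: Sequence[float], h: float, dt: float = 1.0):
        t_eval = np.asarray(t_eval, dtype=float)
        _check_grid(t_eval)
        self.t_eval = t_eval
        self.h = float(h)
        self.dt = float(dt)
        t_end = float(t_eval[-1])
        n = int(round(t_end / dt)) + 1
        self.grid = np.linspace(0.0, t_end, n)
        self._u = np.column_stack(
            [
                np.maximum(np.asarray(g.derivative(self.grid), dtype=float), 0.0),
                np.asarray(g.value(self.grid), dtype=float) - self.h,
            ]
        )
        # t_eval points that sit exactly on the fine grid are read off directly
        idx = np.round(t_eval / dt).astype(int)
        self._exact = bool(np.allclose(idx * dt, t_eval, atol=1e-9))
        self._idx = idx

    def cp1(self, kin: KineticParams, sec: SecretionParams) -> np.ndarray:
        """Above-basal CP1 at the bound evaluation times."""
        if sec.h != self.h:
            raise ValueError(f"simulator bound to h={self.h}, got sec.h={sec.h}")
        a, b = _system_matrices(kin, sec)
        m = np.zeros((7, 7))
        m[:3, :3] = a
        m[:3, 3:5] = b
        m[3:5, 5:7] = np.eye(2)
        e = expm(m * self.dt)
        ad = e[:3, :3]
        g1 = e[:3, 3:5]
        g2 = e[:3, 5:7] / self.dt
        force = self._u[:-1] @ (g1 - g2).T + self._u[1:] @ g2.T
        x = np.zeros(3)
        cp1 = np.empty(self.grid.size)
        cp1[0] = 0.0
        for k in range(self.grid.size - 1):
            x = ad @ x + force[k]
            cp1[k + 1] = x[0]
        if self._exact:
            return cp1[self._idx]
        return np.interp(self.t_eval, self.grid, cp1)


def simulate_ocmm(
    kin: KineticParams,
    sec: SecretionParams,
    g: GlucoseSignal,
    t_eval: Sequence[float],
    cp_basal: float = 0.0,
    *,
    method: str = "rk45",
    fine_dt: float = 1.0,
) -> np.ndarray:
    """Simulate the total plasma C-peptide concentration on ``t_eval``.

    Returns ``cp_basal + CP1(t)`` in pmol/L, where CP1 solves the
    above-basal kinetic model driven by the static + dynamic secretion.

    Parameters
    ----------
    method : {"rk45", "lti"}
        ``"rk45"``: adaptive Runge-Kutta 4(5) with the integration
        restarted at sign changes of dG/dt (the dynamic-secretion switch
        makes the right-hand side non-smooth there).  ``"lti"``: exact
        matrix-exponential propagation of the linear system on a uniform
        ``fine_dt`` grid — much faster, used in the inner loop of
        parameter estimation.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    _check_grid(t_eval)
    if not (math.isfinite(cp_basal) and cp_basal >= 0):
        raise ValueError(f"cp_basal must be finite and >= 0, got {cp_basal}")

    if method == "lti":
        cp1 = _simulate_lti_foh(kin, sec, g, t_eval, fine_dt)
        return cp_basal + cp1

    if method != "rk45":
        raise ValueError(f"unknown method {method!r}; expected 'rk45' or 'lti'")

    def rhs(t, x):
        cp1, cp2, y = x
        dg = g.derivative(t)
        srd = sec.k_d * dg if dg > 0 else 0.0
        return (
            -(kin.k01 + kin.k21) * cp1 + kin.k12 * cp2 + y + srd,
            kin.k21 * cp1 - kin.k12 * cp2,
            -sec.alpha * (y - sec.beta * (g.value(t) - sec.h)),
        )

    try:
        breaks = list(g.derivative_sign_changes())
    except (AttributeError, NotImplementedError):
        breaks = []
    states = _integrate_piecewise(rhs, np.zeros(3), t_eval, breaks)
    return cp_basal + states[:, 0]


def responsivity_indices(
    kin: KineticParams,
    sec: SecretionParams,
    g: GlucoseSignal,
    cp1_basal: float,
    t_total: float = 300.0,
    *,
    quad_dt: float = 0.25,
) -> ResponsivityIndices:
    """Compute the four beta-cell responsivity indices over [0, t_total].

    phi_tot averages total secretion (above-basal plus basal) over the
    test and normalizes by average glucose::

        phi_tot = [phi_d*(Gmax - Gb) + phi_s*int(G - h) + T*phi_b*Gb] / int(G)

    Integrals use composite Simpson quadrature on a fixed ``quad_dt``
    grid.  All indices are on the 10^-9 display scale (see module notes
    on units).
    """
    from scipy.integrate import simpson

    if not t_total > 0:
        raise ValueError(f"t_total must be positive, got {t_total}")
    if not (math.isfinite(cp1_basal) and cp1_basal >= 0):
        raise ValueError(f"cp1_basal must be finite and >= 0, got {cp1_basal}")
    n = int(round(t_total / quad_dt))
    if n % 2:  # Simpson wants an even interval count
        n += 1
    grid = np.linspace(0.0, t_total, n + 1)
    gv = np.asarray(g.value(grid), dtype=float)
    if np.any(gv <= 0) or not np.all(np.isfinite(gv)):
        raise ValueError("glucose signal must be positive and finite on [0, T]")
    int_g = simpson(gv, x=grid)
    int_g_minus_h = simpson(gv - sec.h, x=grid)

    phi_s = sec.beta
    phi_d = sec.k_d
    sr_b = kin.k01 * cp1_basal
    phi_b = sr_b / g.basal
    phi_tot = (
        phi_d * (g.maximum - g.basal) + phi_s * int_g_minus_h + t_total * phi_b * g.basal
    ) / int_g
    return ResponsivityIndices(phi_s=phi_s, phi_d=phi_d, phi_b=phi_b, phi_tot=phi_tot)
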