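"""Bayesian maximum-a-posteriori identification of the forward model.

One subject's C-peptide samples are fitted by maximizing the posterior
density of the parameter vector ``p = [k_d, alpha, beta, k01, k12, k21]``
— equivalently, minimizing

    0.5 * sum_i (y_i - yhat_i(p))^2 / sigma_i^2  +  (-log prior(p))

with independent Gaussian measurement error whose SD is proportional to
the measured concentration (constant CV).  Three prior regimes are
supported:

VC
    kinetics fixed to the Van Cauter population prediction; only the
    secretion parameters are estimated (weakly-informative log-normal
    prior on ``alpha``, flat elsewhere).
DB
    all six parameters estimated from the data; independent log-normal
    priors on the kinetic parameters centred at the Van Cauter
    prediction.
PHH
    as DB, but the kinetic prior is a joint log-normal taken from an
    empirical cohort distribution (e.g. data-based estimates in the
    population of interest).

Optimization runs in log-parameter space (positivity for free) with a
jittered multi-start; precision is reported as the per-parameter CV (%)
from the inverse curvature of the negative log posterior at the optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .core import (
    FastOCMMSimulator,
    KineticParams,
    ResponsivityIndices,
    SecretionParams,
    responsivity_indices,
)
from .glucose import build_glucose_signal
from .io import SubjectRecord
from .van_cauter import vc_kinetics

__all__ = [
    "PARAM_NAMES",
    "ErrorModel",
    "FlatPrior",
    "LogNormalPrior",
    "JointLogNormalPrior",
    "PriorSpec",
    "FitConfig",
    "FitResult",
    "neg_log_posterior",
    "fit_subject",
    "parameter_precision",
    "build_prior",
]

#: canonical parameter order of the full vector p
PARAM_NAMES = ("k_d", "alpha", "beta", "k01", "k12", "k21")
_KINETIC_NAMES = ("k01", "k12", "k21")
_PENALTY = 1e12
APPROACHES = ("VC", "DB", "PHH")


@dataclass(frozen=True)
class ErrorModel:
    """Constant-CV Gaussian measurement error: SD(y) = cv * y."""

    cv: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.cv < 1):
            raise ValueError(f"cv must be in (0, 1), got {self.cv}")

    def sd(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValueError("measurements must be positive for a CV error model")
        return self.cv * y


class FlatPrior:
    """Noninformative prior: contributes nothing to the objective."""

    def neg_log(self, value: float) -> float:
        return 0.0

    def __repr__(self) -> str:  # pragma: no cover
        return "FlatPrior()"


def _gcv_to_sdlog(gcv: float) -> float:
    return math.sqrt(math.log1p(gcv * gcv))


@dataclass(frozen=True)
class LogNormalPrior:
    """Log-normal prior specified by its median and geometric CV.

    The contribution is the centred quadratic in log space,
    ``(ln x - ln median)^2 / (2 sdlog^2)``: zero at the median, so a
    perfectly prior-consistent estimate leaves the objective untouched.
    """

    median: float
    gcv: float

    def __post_init__(self) -> None:
        if not self.median > 0:
            raise ValueError(f"median must be positive, got {self.median}")
        if not self.gcv > 0:
            raise ValueError(f"gcv must be positive, got {self.gcv}")

    @property
    def sdlog(self) -> float:
        return _gcv_to_sdlog(self.gcv)

    def neg_log(self, value: float) -> float:
        z = (math.log(value) - math.log(self.median)) / self.sdlog
        return 0.5 * z * z


@dataclass(frozen=True)
class JointLogNormalPrior:
    """Joint log-normal prior over a named parameter subset (full covariance)."""

    names: tuple[str, ...]
    mu: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mu.shape != (len(self.names),) or cov.shape != (mu.size, mu.size):
            raise ValueError("mu/cov shapes inconsistent with names")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "cov", cov)
        object.__setattr__(self, "_prec", np.linalg.pinv(cov))

    def neg_log_vector(self, values: Sequence[float]) -> float:
        d = np.log(np.asarray(values, dtype=float)) - self.mu
        return 0.5 * float(d @ self._prec @ d)


@dataclass(frozen=True)
class PriorSpec:
    """Prior layout for one fit: fixed values, marginal priors, optional joint."""

    fixed: dict[str, float] = field(default_factory=dict)
    marginals: dict[str, FlatPrior | LogNormalPrior] = field(default_factory=dict)
    joint: JointLogNormalPrior | None = None

    def __post_init__(self) -> None:
        covered = set(self.fixed) | set(self.marginals)
        if self.joint is not None:
            overlap = covered & set(self.joint.names)
            if overlap:
                raise ValueError(f"parameters {sorted(overlap)} have multiple prior entries")
            covered |= set(self.joint.names)
        if covered != set(PARAM_NAMES):
            raise ValueError(
                f"every parameter needs exactly one prior entry; got {sorted(covered)}"
            )

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n not in self.fixed)

    def neg_log(self, p: dict[str, float]) -> float:
        total = 0.0
        for name, prior in self.marginals.items():
            total += prior.neg_log(p[name])
        if self.joint is not None:
            total += self.joint.neg_log_vector([p[n] for n in self.joint.names])
        return total


@dataclass(frozen=True)
class FitConfig:
    """Tunable settings of the identification pipeline."""

    error_cv: float = 0.05  # C-peptide measurement CV
    glucose_noise_cv: float = 0.02  # assumed glucose noise for the derivative estimator
    alpha_prior_median: float = 0.05  # min^-1
    alpha_prior_gcv: float = 0.5
    kinetic_prior_gcv: float = 0.3  # spread of the DB kinetic priors around Van Cauter
    n_starts: int = 5
    start_jitter: float = 0.3  # multiplicative jitter range of the multi-start
    seed: int = 0
    fine_dt: float = 1.0  # min, simulation grid of the fast LTI propagator
    t_index: float = 300.0  # min, horizon of the responsivity integrals
    maxiter: int = 400


@dataclass
class FitResult:
    """Outcome of one subject-level MAP fit."""

    approach: str
    estimates: dict[str, float]
    free: tuple[str, ...]
    cv_percent: dict[str, float]
    objective: float
    objective_initial: float
    predictions: np.ndarray
    times: np.ndarray
    indices: ResponsivityIndices
    converged: bool
    message: str = ""
    start_objectives: tuple[float, ...] = ()
    start_estimates: np.ndarray | None = None

    @property
    def kinetics(self) -> KineticParams:
        return KineticParams(
            k01=self.estimates["k01"], k12=self.estimates["k12"], k21=self.estimates["k21"]
        )

    @property
    def secretion(self) -> SecretionParams:
        return SecretionParams(
            k_d=self.estimates["k_d"],
            alpha=self.estimates["alpha"],
            beta=self.estimates["beta"],
            h=self.estimates["h"],
        )

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "estimates": self.estimates,
            "free_parameters": list(self.free),
            "cv_percent": self.cv_percent,
            "objective": self.objective,
            "indices": self.indices.as_dict(),
            "converged": self.converged,
            "message": self.message,
            "predictions": self.predictions.tolist(),
            "times": self.times.tolist(),
        }


def _vector_to_params(p: Sequence[float], h: float) -> tuple[KineticParams, SecretionParams]:
    k_d, alpha, beta, k01, k12, k21 = (float(v) for v in p)
    return (
        KineticParams(k01=k01, k12=k12, k21=k21),
        SecretionParams(k_d=k_d, alpha=alpha, beta=beta, h=h),
    )


def _posterior_factory(
    subject: SubjectRecord,
    prior: PriorSpec,
    err: ErrorModel,
    simulator: FastOCMMSimulator,
):
    """Return neg-log-posterior over the full 6-vector, with precomputed weights."""
    y = subject.cpeptide
    inv_var = 1.0 / err.sd(y) ** 2
    cp_basal = subject.cp_basal
    h = subject.glucose_basal

    def nlp(p: np.ndarray) -> float:
        try:
            kin, sec = _vector_to_params(p, h)
            yhat = cp_basal + simulator.cp1(kin, sec)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"simulation failed at p={np.asarray(p)}: {exc}", RuntimeWarning)
            return _PENALTY
        if not np.all(np.isfinite(yhat)):
            warnings.warn(f"non-finite prediction at p={np.asarray(p)}", RuntimeWarning)
            return _PENALTY
        r = y - yhat
        loglik = 0.5 * float(np.sum(r * r * inv_var))
        return loglik + prior.neg_log(dict(zip(PARAM_NAMES, p)))

    return nlp


def neg_log_posterior(
    p: Sequence[float],
    subject: SubjectRecord,
    g,
    prior: PriorSpec,
    err: ErrorModel,
    *,
    fine_dt: float = 1.0,
) -> float:
    """Negative log posterior (constants dropped) at the full parameter vector.

    ``p`` follows :data:`PARAM_NAMES`; the secretion threshold ``h`` is
    the subject's basal glucose.  ODE/parameter failures return a large
    penalty with a warning rather than raising.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (6,):
        raise ValueError(f"p must have 6 entries {PARAM_NAMES}, got shape {p.shape}")
    if not np.all(p > 0):
        raise ValueError("all parameters must be strictly positive")
    sim = FastOCMMSimulator(g, subject.times, subject.glucose_basal, fine_dt)
    return _posterior_factory(subject, prior, err, sim)(p)


def build_prior(
    subject: SubjectRecord,
    approach: str,
    config: FitConfig,
    phh_population=None,
) -> PriorSpec:
    """Assemble the prior layout for one subject under a given approach."""
    if approach not in APPROACHES:
        raise ValueError(f"approach must be one of {APPROACHES}, got {approach!r}")
    vc = vc_kinetics(subject.demographics)
    alpha_prior = LogNormalPrior(config.alpha_prior_median, config.alpha_prior_gcv)
    p1: dict[str, FlatPrior | LogNormalPrior] = {
        "k_d": FlatPrior(),
        "alpha": alpha_prior,
        "beta": FlatPrior(),
    }
    if approach == "VC":
        return PriorSpec(
            fixed={"k01": vc.k01, "k12": vc.k12, "k21": vc.k21}, marginals=p1
        )
    if approach == "DB":
        marginals = dict(p1)
        for name in _KINETIC_NAMES:
            marginals[name] = LogNormalPrior(getattr(vc, name), config.kinetic_prior_gcv)
        return PriorSpec(marginals=marginals)
    if phh_population is None:
        raise ValueError("PHH approach requires an empirical kinetic population prior")
    joint = JointLogNormalPrior(
        names=_KINETIC_NAMES,
        mu=np.asarray(phh_population.mu, dtype=float),
        cov=np.asarray(phh_population.sigma, dtype=float),
    )
    return PriorSpec(marginals=p1, joint=joint)


def _start_vector(
    subject: SubjectRecord, prior: PriorSpec, config: FitConfig
) -> dict[str, float]:
    """Heuristic central starting point (before multi-start jitter)."""
    vc = vc_kinetics(subject.demographics)
    if prior.joint is not None:
        kin0 = dict(zip(prior.joint.names, np.exp(prior.joint.mu)))
    else:
        kin0 = {"k01": vc.k01, "k12": vc.k12, "k21": vc.k21}
    g_ab = np.maximum(subject.glucose - subject.glucose_basal, 0.0)
    cp_ab = np.maximum(subject.cpeptide - subject.cp_basal, 0.0)
    mean_g = float(np.mean(g_ab))
    beta0 = kin0["k01"] * float(np.mean(cp_ab)) / mean_g if mean_g > 1e-6 else 10.0
    beta0 = float(np.clip(beta0, 1.0, 200.0))
    rise = float(np.max(cp_ab))
    span = max(float(np.max(g_ab)), 0.5)
    kd0 = float(np.clip(rise / span * 0.5, 10.0, 2000.0))
    return {
        "k_d": kd0,
        "alpha": config.alpha_prior_median,
        "beta": beta0,
        **{k: kin0[k] for k in _KINETIC_NAMES},
    }


def _hessian(f, z0: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of a scalar function at z0."""
    n = z0.size
    h = np.empty((n, n))
    f0 = f(z0)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        fpp = f(z0 + ei)
        fmm = f(z0 - ei)
        h[i, i] = (fpp - 2 * f0 + fmm) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            fpq = f(z0 + ei + ej)
            fpm = f(z0 + ei - ej)
            fmp = f(z0 - ei + ej)
            fmq = f(z0 - ei - ej)
            h[i, j] = h[j, i] = (fpq - fpm - fmp + fmq) / (4 * step**2)
    return h


def _cv_from_curvature(nlp_free, z_hat: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    """Per-parameter CV (%) from the inverse log-space curvature at the optimum.

    In log space the posterior SD of ln(p_i) is, to first order, the
    relative SD of p_i, so CV = 100 * sqrt(diag(H^-1)).
    """
    hess = _hessian(nlp_free, z_hat)
    cv: dict[str, float] = {}
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive posterior variance")
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        diag = np.diag(cov)
    for name, v in zip(names, diag):
        cv[name] = 100.0 * math.sqrt(v) if v > 0 else float("nan")
    return cv


def fit_subject(
    subject: SubjectRecord,
    approach: str,
    err: ErrorModel | None = None,
    config: FitConfig | None = None,
    *,
    signal=None,
    phh_population=None,
    compute_cv: bool = True,
) -> FitResult:
    """MAP-fit the forward model to one subject under a prior regime.

    Parameters
    ----------
    signal : GlucoseSignal, optional
        Continuous glucose input.  By default it is built from the
        subject's glucose samples (interpolation + regularized
        derivative); simulation studies pass the known source curve.
    phh_population : object with ``mu`` and ``sigma``, required for PHH
        The empirical joint log-normal kinetic distribution.
    """
    config = config or FitConfig()
    err = err or ErrorModel(config.error_cv)
    if signal is None:
        signal = build_glucose_signal(
            subject.times,
            subject.glucose,
            max(config.t_index, float(subject.times[-1])),
            noise_cv=config.glucose_noise_cv,
        )
    prior = build_prior(subject, approach, config, phh_population)
    free = prior.free_names
    sim = FastOCMMSimulator(signal, subject.times, subject.glucose_basal, config.fine_dt)
    nlp_full = _posterior_factory(subject, prior, err, sim)

    start = _start_vector(subject, prior, config)
    fixed = dict(prior.fixed)
    idx_free = [PARAM_NAMES.index(n) for n in free]

    def assemble(z: np.ndarray) -> np.ndarray:
        p = np.array([fixed.get(n, start[n]) for n in PARAM_NAMES])
        p[idx_free] = np.exp(z)
        return p

    def nlp_free(z: np.ndarray) -> float:
        if np.any(np.abs(z) > 50):  # guard against runaway exponentials
            return _PENALTY
        return nlp_full(assemble(z))

    z0 = np.log([start[n] for n in free])
    rng = np.random.default_rng(config.seed)
    jit = math.log1p(config.start_jitter)
    starts = [z0] + [
        z0 + rng.uniform(-jit, jit, size=z0.size) for _ in range(config.n_starts - 1)
    ]

    objective_initial = nlp_free(z0)
    best = None
    start_objs: list[float] = []
    start_ests: list[np.ndarray] = []
    any_success = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for z_start in starts:
            res = minimize(
                nlp_free,
                z_start,
                method="L-BFGS-B",
                options={"maxiter": config.maxiter, "ftol": 1e-12, "gtol": 1e-9},
            )
            res2 = minimize(
                nlp_free,
                res.x,
                method="Nelder-Mead",
                options={"maxiter": 200 * z0.size, "xatol": 1e-7, "fatol": 1e-10},
            )
            cand = res2 if res2.fun <= res.fun else res
            any_success = any_success or res.success or res2.success
            start_objs.append(float(cand.fun))
            start_ests.append(np.exp(cand.x))
            if best is None or cand.fun < best.fun:
                best = cand

    converged = bool(any_success and best.fun < _PENALTY)
    p_hat = assemble(best.x)
    estimates = dict(zip(PARAM_NAMES, (float(v) for v in p_hat)))
    estimates["h"] = subject.glucose_basal
    kin, sec = _vector_to_params(p_hat, subject.glucose_basal)
    predictions = subject.cp_basal + sim.cp1(kin, sec)
    indices = responsivity_indices(
        kin, sec, signal, cp1_basal=subject.cp_basal, t_total=config.t_index
    )
    cv = {}
    if compute_cv and converged:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cv = _cv_from_curvature(nlp_free, best.x, free)
    return FitResult(
        approach=approach,
        estimates=estimates,
        free=free,
        cv_percent=cv,
        objective=float(best.fun),
        objective_initial=float(objective_initial),
        predictions=predictions,
        times=subject.times.copy(),
        indices=indices,
        converged=converged,
        message="" if converged else "no optimizer start converged",
        start_objectives=tuple(start_objs),
        start_estimates=np.array(start_ests),
    )


def parameter_precision(
    fit: FitResult,
    subject: SubjectRecord,
    err: ErrorModel | None = None,
    config: FitConfig | None = None,
    *,
    signal=None,
    phh_population=None,
) -> dict[str, float]:
    """Recompute per-parameter CV (%) at a fit's optimum.

    The curvature of the negative log posterior (likelihood plus prior)
    is evaluated in log-parameter space at the stored estimates; fixed
    parameters get no entry.
    """
    if not fit.converged:
        raise ValueError("precision is only defined for a converged fit")
    config = config or FitConfig()
    err = err or ErrorModel(config.error_cv)
    if signal is None:
        signal = build_glucose_signal(
            subject.times,
            subject.glucose,
            max(config.t_index, float(subject.times[-1])),
            noise_cv=config.glucose_noise_cv,
        )
    prior = build_prior(subject, fit.approach, config, phh_population)
    sim = FastOCMMSimulator(signal, subject.times, subject.glucose_basal, config.fine_dt)
    nlp_full = _posterior_factory(subject, prior, err, sim)
    free = prior.free_names
    idx_free = [PARAM_NAMES.index(n) for n in free]
    fixed = dict(prior.fixed)

    def nlp_free(z: np.ndarray) -> float:
        p = np.array([fixed.get(n, fit.estimates[n]) for n in PARAM_NAMES])
        p[idx_free] = np.exp(z)
        return nlp_full(p)

    z_hat = np.log([fit.estimates[n] for n in free])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return _cv_from_curvature(nlp_free, z_hat, free)
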