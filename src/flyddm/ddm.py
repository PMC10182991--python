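"""Drift-diffusion model of two-choice decisions.

The decision variable is a Wiener process with unit diffusion coefficient,
drift ``v = k*x`` proportional to task difficulty x, absorbing bounds at
``+A`` (correct) and ``-A`` (incorrect), and starting point 0.  Closed forms
follow for the psychometric function::

    P(correct) = 1 / (1 + exp(-2*A*k*x)),

the chronometric function::

    T(x) = (A/(k*x)) * tanh(A*k*x) + T0,      T(0) = A**2 + T0,

and the first-passage-time density at either bound, evaluated here with the
dual small-time / large-time series representation of the Wiener
first-passage density (Navarro-Fuss style truncation at an absolute series
error of 1e-29 by default).  Measured reaction times add a Gaussian
non-decision time with mean ``T0`` and SD ``sigma0``, truncated at zero;
the reaction-time density is the corresponding convolution, computed by
Gauss-Hermite quadrature over the non-decision kernel.

All times are walking-speed-normalized (dimensionless) units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import least_squares

from .errors import UnderdeterminedError, ValidationError
from .trials import ConditionSummary

__all__ = [
    "DDMParams",
    "choice_probability",
    "accuracy",
    "mean_rt",
    "normalized_choice_probability",
    "fpt_density",
    "rt_density",
    "loglik_ddm",
    "fit_display_curves",
    "DisplayFit",
]

#: default absolute truncation error of the first-passage series
SERIES_TOL = 1e-29

#: density floor applied before logarithms
LOG_FLOOR = 1e-300

#: normalized time below which (in bound-scaled units t/(2A)^2) the
#: small-time series needs fewer terms than the large-time series
_TAU_SPLIT = 0.1


@dataclass(frozen=True)
class DDMParams:
    """Drift-diffusion parameters.

    A : bound height (evidence units); k : difficulty-to-drift scaling;
    t0, sigma0 : mean and SD of the Gaussian non-decision time; pmax :
    optional lapse ceiling used only by the display fits (Eq.-3-style
    normalized psychometric function).
    """

    A: float
    k: float
    t0: float
    sigma0: float
    pmax: float | None = None

    def __post_init__(self):
        for name in ("A", "k", "t0", "sigma0"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.pmax is not None and not (0.5 < self.pmax <= 1.0):
            raise ValidationError(f"pmax must be in (0.5, 1], got {self.pmax!r}")


# ---------------------------------------------------------------------------
# closed-form psychometric / chronometric functions
# ---------------------------------------------------------------------------

def choice_probability(A: float, k: float, x) -> np.ndarray | float:
    """Probability of choosing the left arm: ``1/(1 + exp(-2*A*k*(-x)))``.

    With the sign convention of the behavioral assay, positive x places the
    lower odor concentration on the right, so P(left) falls with x.
    """
    _check_pos(A=A, k=k)
    return _logistic(-2.0 * A * k * np.asarray(x, dtype=float))


def accuracy(A: float, k: float, x) -> np.ndarray | float:
    """Probability of a correct choice, ``1/(1 + exp(-2*A*k*|x|))``."""
    _check_pos(A=A, k=k)
    return _logistic(2.0 * A * k * np.abs(np.asarray(x, dtype=float)))


def mean_rt(A: float, k: float, x, t0: float = 0.0) -> np.ndarray | float:
    """Mean reaction time ``(A/(k*x)) * tanh(A*k*x) + t0``.

    The removable singularity at x = 0 is evaluated by its limit A**2 + t0.
    """
    _check_pos(A=A, k=k)
    x = np.asarray(x, dtype=float)
    akx = A * k * x
    small = np.abs(akx) < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(small, A * A * (1.0 - akx * akx / 3.0), (A / (k * np.where(x == 0, 1.0, x))) * np.tanh(akx))
    out = t + t0
    return float(out) if out.ndim == 0 else out


def normalized_choice_probability(A: float, k: float, x, pmax: float) -> np.ndarray | float:
    """Left-choice probability rescaled into the lapse band [1-pmax, pmax]."""
    if not (0.5 < pmax <= 1.0):
        raise ValidationError(f"pmax must be in (0.5, 1], got {pmax!r}")
    return (1.0 - pmax) + (2.0 * pmax - 1.0) * choice_probability(A, k, x)


def _normalized_accuracy(A, k, absx, pmax):
    return (1.0 - pmax) + (2.0 * pmax - 1.0) * _logistic(2.0 * A * k * absx)


def _logistic(z):
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return float(out) if out.ndim == 0 else out


def _check_pos(**kv):
    for name, val in kv.items():
        if not val > 0:
            raise ValidationError(f"{name} must be > 0, got {val!r}")


# ---------------------------------------------------------------------------
# first-passage-time density
# ---------------------------------------------------------------------------

def _series_terms(tol: float) -> tuple[int, int]:
    """Term counts meeting an absolute truncation error ``tol`` on both
    branches of the dual series, at the worst case tau = _TAU_SPLIT."""
    tau = _TAU_SPLIT
    # small-time branch (worst at the split, count grows with tau)
    arg = 2.0 * tol * math.sqrt(2.0 * math.pi * tau)
    ks = 2.0 + (math.sqrt(-2.0 * tau * math.log(arg)) if arg < 1 else 0.0)
    ks = max(ks, math.sqrt(tau) + 1.0)
    # large-time branch (worst at the split, count shrinks with tau)
    arg = math.pi * tau * tol
    jl = math.sqrt(-2.0 * math.log(arg) / (math.pi**2 * tau)) if arg < 1 else 0.0
    jl = max(jl, 1.0 / (math.pi * math.sqrt(tau)))
    return int(math.ceil(ks)), int(math.ceil(jl))


def _f0_half(tau: np.ndarray, tol: float) -> np.ndarray:
    """Standardized (zero-drift, unit bound separation, midpoint start)
    first-passage density at the lower bound, as a function of tau = t/a^2."""
    K, J = _series_terms(tol)
    out = np.zeros_like(tau)
    small = tau < _TAU_SPLIT
    ts = tau[small]
    if ts.size:
        ks = np.arange(-((K - 1) // 2), (K - 1) - (K - 1) // 2 + 1, dtype=float)
        b = 0.5 + 2.0 * ks  # start offsets of the image charges
        s = np.zeros_like(ts)
        for bk in b:
            s += bk * np.exp(-bk * bk / (2.0 * ts))
        out[small] = s / np.sqrt(2.0 * math.pi * ts**3)
    tl = tau[~small]
    if tl.size:
        js = np.arange(1, J + 1, 2, dtype=float)  # even j vanish (sin(j*pi/2)=0)
        signs = np.where(((js - 1) // 2) % 2 == 0, 1.0, -1.0)
        s = np.zeros_like(tl)
        with np.errstate(under="ignore"):
            for j, sg in zip(js, signs):
                s += sg * j * np.exp(-j * j * math.pi**2 * tl / 2.0)
        out[~small] = math.pi * s
    np.clip(out, 0.0, None, out=out)
    return out


def _wfpt_lower(t: np.ndarray, drift, a: float, tol: float = SERIES_TOL) -> np.ndarray:
    """Density of first passage through the *lower* of two bounds separated
    by ``a``, starting midway, unit diffusion, drift ``drift`` (scalar or
    array broadcastable against t).  t <= 0 yields 0."""
    t = np.asarray(t, dtype=float)
    drift = np.broadcast_to(np.asarray(drift, dtype=float), t.shape)
    out = np.zeros_like(t)
    ok = t > 0
    if np.any(ok):
        tt, v = t[ok], drift[ok]
        with np.errstate(under="ignore"):
            pref = np.exp(-0.5 * v * a - 0.5 * v * v * tt) / (a * a)
            out[ok] = pref * _f0_half(tt / (a * a), tol)
    return out


def fpt_density(t, sign: int, A: float, k: float, x: float,
                series_tol: float = SERIES_TOL) -> np.ndarray | float:
    """First-passage (decision-time) density at the correct (+1) or
    incorrect (-1) bound, for bounds at +/-A, start 0, drift k*x.

    Raises on t <= 0 (the decision-time density has positive support).
    """
    _check_pos(A=A, k=k)
    if sign not in (-1, 1):
        raise ValidationError(f"sign must be +1 or -1, got {sign!r}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr <= 0):
        raise ValidationError("fpt_density requires t > 0")
    # the correct bound (+A) is the lower bound of a flipped process with
    # drift -k*x; the incorrect bound keeps the drift sign
    drift = -sign * k * x
    out = _wfpt_lower(t_arr, drift, 2.0 * A, series_tol)
    return float(out[0]) if np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# reaction-time density (non-decision convolution)
# ---------------------------------------------------------------------------

_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GH_CACHE:
        z, w = hermgauss(n)
        _GH_CACHE[n] = (z, w / math.sqrt(math.pi))
    return _GH_CACHE[n]


def rt_density(t, sign: int, params: DDMParams, x: float,
               gh_nodes: int = 16, series_tol: float = SERIES_TOL) -> np.ndarray | float:
    """Reaction-time density: first-passage density convolved with the
    zero-truncated Gaussian non-decision time N(t0, sigma0^2).

    The convolution integral over the non-decision time is evaluated by
    ``gh_nodes``-point Gauss-Hermite quadrature; the kernel's (tiny) mass at
    negative non-decision times is cut off and the kernel renormalized.
    """
    if sign not in (-1, 1):
        raise ValidationError(f"sign must be +1 or -1, got {sign!r}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    z, w = _gh(gh_nodes)
    nd = params.t0 + math.sqrt(2.0) * params.sigma0 * z  # non-decision times
    keep = nd > 0
    # renormalize over the retained nodes so the discrete kernel is exactly
    # a probability kernel (the truncated-Gaussian mass as the quadrature
    # itself sees it); guarantees unit total mass of the rt density
    norm = float(np.sum(w[keep]))
    if norm == 0.0:
        return 0.0 if np.ndim(t) == 0 else np.zeros_like(t_arr)
    drift = -sign * params.k * x
    s = t_arr[None, :] - nd[keep, None]
    dens = _wfpt_lower(s, drift, 2.0 * params.A, series_tol)
    out = (w[keep] @ dens) / norm
    return float(out[0]) if np.ndim(t) == 0 else out


def loglik_ddm(rt: np.ndarray, choice: np.ndarray, absx: np.ndarray,
               A: float, k: float, t0: float, sigma0: float,
               gh_nodes: int = 16, series_tol: float = SERIES_TOL) -> float:
    """Joint log-likelihood of (rt, choice) trials under the DDM.

    ``absx`` is the unsigned difficulty |x|; ``choice`` is the correctness
    sign (+1/-1).  Densities are floored at 1e-300 before the log so that
    out-of-support observations never produce -inf from log(0).
    """
    z, w = _gh(gh_nodes)
    nd = t0 + math.sqrt(2.0) * sigma0 * z
    keep = nd > 0
    norm = float(np.sum(w[keep]))  # discrete truncated-kernel mass
    if norm == 0.0:
        return float(rt.size * math.log(LOG_FLOOR))
    drift = np.where(choice > 0, -1.0, 1.0) * k * absx  # drift of the flipped/lower-bound form
    s = rt[None, :] - nd[keep, None]
    dens = _wfpt_lower(s, drift[None, :], 2.0 * A, series_tol)
    per_trial = (w[keep] @ dens) / norm
    return float(np.sum(np.log(np.maximum(per_trial, LOG_FLOOR))))


# ---------------------------------------------------------------------------
# display-curve least-squares fits (chronometric + psychometric)
# ---------------------------------------------------------------------------

@dataclass
class DisplayFit:
    """Simultaneous least-squares fit of the chronometric and psychometric
    functions, one (A, k, pmax) triple per light condition with t0 shared
    (estimated from the unstimulated condition and then held fixed)."""

    t0: float
    per_light: Mapping[float, DDMParams]
    residuals: Mapping[float, np.ndarray]

    def cost(self, light: float) -> float:
        r = np.asarray(self.residuals[light])
        return float(0.5 * np.sum(r * r))


def _display_residuals(theta, absx, mrt, acc, t0):
    if t0 is None:
        A, k, t0_, pmax = theta
    else:
        (A, k, pmax), t0_ = theta, t0
    return np.concatenate([
        mean_rt(A, k, absx, t0_) - mrt,
        _normalized_accuracy(A, k, absx, pmax) - acc,
    ])


def fit_display_curves(summary: ConditionSummary) -> DisplayFit:
    """Fit mean reaction times and accuracies per light condition.

    The unstimulated (light = 0) condition is fit with four free parameters
    (A, k, t0, pmax); t0 is then fixed at that estimate while A, k and pmax
    vary with light intensity.  Raises
    :class:`~flyddm.errors.UnderdeterminedError` when a condition has fewer
    data cells than parameters.
    """
    table = summary.table
    lights = sorted(table.index.get_level_values("light").unique())
    if 0.0 not in lights:
        raise ValidationError("display fits require an unstimulated (light=0) condition")

    def cells(light):
        sub = table.xs(light, level="light")
        absx = np.abs(sub.index.to_numpy(dtype=float))
        return absx, sub["mean_rt"].to_numpy(), sub["accuracy"].to_numpy()

    per_light: dict[float, DDMParams] = {}
    residuals: dict[float, np.ndarray] = {}

    absx, mrt, acc = cells(0.0)
    if 2 * len(absx) < 4 or len(np.unique(absx)) < 2:
        raise UnderdeterminedError(
            f"unstimulated condition has {len(absx)} cells; need >= 2 distinct difficulties for 4 parameters"
        )
    x0 = [1.0, 1.0, max(0.5 * float(np.min(mrt)), 1e-3), min(max(float(np.max(acc)), 0.6), 1.0)]
    sol = least_squares(
        _display_residuals, x0, args=(absx, mrt, acc, None),
        bounds=([1e-6, 1e-6, 1e-6, 0.5 + 1e-9], [np.inf, np.inf, 3.0, 1.0]),
        method="trf",
    )
    A, k, t0, pmax = sol.x
    per_light[0.0] = DDMParams(A=A, k=k, t0=t0, sigma0=1e-6, pmax=pmax)
    residuals[0.0] = sol.fun

    for light in lights:
        if light == 0.0:
            continue
        absx, mrt, acc = cells(light)
        if 2 * len(absx) < 3 or len(np.unique(absx)) < 2:
            raise UnderdeterminedError(
                f"light={light} condition has {len(absx)} cells; need >= 2 distinct difficulties"
            )
        x0 = [A, k, min(max(float(np.max(acc)), 0.6), 1.0)]
        sol_l = least_squares(
            _display_residuals, x0, args=(absx, mrt, acc, t0),
            bounds=([1e-6, 1e-6, 0.5 + 1e-9], [np.inf, np.inf, 1.0]),
            method="trf",
        )
        Al, kl, pml = sol_l.x
        per_light[light] = DDMParams(A=Al, k=kl, t0=t0, sigma0=1e-6, pmax=pml)
        residuals[light] = sol_l.fun

    return DisplayFit(t0=float(t0), per_light=per_light, residuals=residuals)
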