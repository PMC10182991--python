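"""Extrema-detection model of two-choice decisions.

Instead of integrating evidence, the decider draws an independent Gaussian
evidence sample ``N(k*x*dt, dt)`` every sampling interval ``dt`` and commits
as soon as a single sample exceeds +A (correct) or falls below -A
(incorrect).  The per-interval crossing probabilities are

    p_plus  = 0.5 * erfc((A - k*x*dt) / sqrt(2*dt)),
    p_minus = 0.5 * erfc((A + k*x*dt) / sqrt(2*dt)),

the decision time is geometric in units of dt with mean

    tau_R = dt / (p_plus + p_minus),

well approximated by an exponential for small dt, and the measured reaction
time adds a Gaussian non-decision time N(t0, sigma0^2): an ex-Gaussian
density, weighted per choice by p_sign / (p_plus + p_minus).

Crossing probabilities are handled in log space throughout because erfc
underflows for bound heights beyond ~27*sqrt(dt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, logsumexp

from .errors import DegenerateModelError, ValidationError

__all__ = [
    "EDParams",
    "crossing_probs",
    "log_crossing_probs",
    "mean_decision_time",
    "exgaussian_logpdf",
    "rt_density_ed",
    "loglik_ed",
    "choice_probability_ed",
]

#: default sampling interval (normalized-time units; the behavioral
#: experiments used 0.5 ms with one unit ~ 1 s)
DEFAULT_DT = 5e-4

LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class EDParams:
    """Extrema-detection parameters: bound height A, evidence-rate scaling k,
    non-decision mean/SD (t0, sigma0), sampling interval dt."""

    A: float
    k: float
    t0: float
    sigma0: float
    dt: float = DEFAULT_DT

    def __post_init__(self):
        for name in ("A", "t0", "sigma0", "dt"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)!r}")


def log_crossing_probs(A: float, k: float, x, dt: float = DEFAULT_DT):
    """Log of the per-interval crossing probabilities (log p_plus, log p_minus).

    ``0.5*erfc(u/sqrt(2)) = Phi(-u)``, evaluated with ``log_ndtr`` so that
    probabilities far below the float underflow limit remain usable.
    """
    if not A >= 0:
        raise ValidationError(f"A must be >= 0, got {A!r}")
    if not dt > 0:
        raise ValidationError(f"dt must be > 0, got {dt!r}")
    x = np.asarray(x, dtype=float)
    root = math.sqrt(dt)
    lp_plus = log_ndtr(-(A - k * x * dt) / root)
    lp_minus = log_ndtr(-(A + k * x * dt) / root)
    return lp_plus, lp_minus


def crossing_probs(A: float, k: float, x, dt: float = DEFAULT_DT):
    """Per-interval bound-crossing probabilities (p_plus, p_minus)."""
    lp, lm = log_crossing_probs(A, k, x, dt)
    return np.exp(lp), np.exp(lm)


def mean_decision_time(p_plus, p_minus, dt: float = DEFAULT_DT):
    """Mean decision time ``tau_R = dt / (p_plus + p_minus)``."""
    total = np.asarray(p_plus, dtype=float) + np.asarray(p_minus, dtype=float)
    if np.any(total <= 0):
        raise DegenerateModelError(
            "p_plus + p_minus underflows to zero; increase dt or decrease A"
        )
    out = dt / total
    return float(out) if out.ndim == 0 else out


def _log_tau_r(A, k, absx, dt):
    lp, lm = log_crossing_probs(A, k, absx, dt)
    log_total = logsumexp(np.stack([lp, lm]), axis=0)
    return math.log(dt) - log_total, lp, lm, log_total


def exgaussian_logpdf(t, tau: float, t0: float, sigma0: float):
    """Log of the exponential (mean ``tau``) + Gaussian (t0, sigma0)
    convolution density, computed stably in log space.

    log f = -log(2 tau) - (t - t0)/tau + sigma0^2/(2 tau^2)
            + log erfc(-(t - t0)/(sigma0 sqrt 2) + sigma0/(tau sqrt 2)).
    """
    t = np.asarray(t, dtype=float)
    u = -(t - t0) / (sigma0 * math.sqrt(2.0)) + sigma0 / (tau * math.sqrt(2.0))
    # log erfc(u) = log 2 + log Phi(-u*sqrt(2))
    log_erfc = math.log(2.0) + log_ndtr(-u * math.sqrt(2.0))
    out = -math.log(2.0 * tau) - (t - t0) / tau + sigma0**2 / (2.0 * tau**2) + log_erfc
    return float(out) if out.ndim == 0 else out


def rt_density_ed(t, sign: int, params: EDParams, x: float):
    """Reaction-time density of the extrema-detection model for one choice
    sign: the ex-Gaussian density times the choice weight
    ``p_sign / (p_plus + p_minus)``."""
    if sign not in (-1, 1):
        raise ValidationError(f"sign must be +1 or -1, got {sign!r}")
    log_tau, lp, lm, log_total = _log_tau_r(params.A, params.k, float(x), params.dt)
    tau = math.exp(log_tau)
    log_w = (lp if sign == 1 else lm) - log_total
    out = np.exp(exgaussian_logpdf(t, tau, params.t0, params.sigma0) + log_w)
    return float(out) if np.ndim(t) == 0 else out


def choice_probability_ed(params: EDParams, x) -> np.ndarray | float:
    """Probability of a correct choice, ``p_plus / (p_plus + p_minus)``."""
    lp, lm = log_crossing_probs(params.A, params.k, np.abs(x), params.dt)
    both = np.stack([np.atleast_1d(lp), np.atleast_1d(lm)])
    log_total = logsumexp(both, axis=0)
    if np.any(log_total < math.log(LOG_FLOOR)):
        raise DegenerateModelError(
            "p_plus + p_minus underflows to zero; increase dt or decrease A"
        )
    out = np.exp(np.atleast_1d(lp) - log_total)
    return float(out[0]) if np.ndim(x) == 0 else out


def loglik_ed(rt: np.ndarray, choice: np.ndarray, absx: np.ndarray,
              A: float, k: float, t0: float, sigma0: float,
              dt: float = DEFAULT_DT) -> float:
    """Joint log-likelihood of (rt, choice) trials under extrema detection.

    ``absx`` is the unsigned difficulty; ``choice`` the correctness sign.
    """
    lp, lm = log_crossing_probs(A, k, absx, dt)
    log_total = logsumexp(np.stack([lp, lm]), axis=0)
    if np.any(~np.isfinite(log_total)) or np.any(log_total < math.log(LOG_FLOOR)):
        return -np.inf
    with np.errstate(over="ignore", under="ignore"):
        tau = dt * np.exp(-log_total)
        log_w = np.where(choice > 0, lp, lm) - log_total
        # exgaussian with per-trial tau
        u = -(rt - t0) / (sigma0 * math.sqrt(2.0)) + sigma0 / (tau * math.sqrt(2.0))
        log_erfc = math.log(2.0) + log_ndtr(-u * math.sqrt(2.0))
        log_f = -np.log(2.0 * tau) - (rt - t0) / tau + sigma0**2 / (2.0 * tau**2) + log_erfc
    log_f = np.maximum(log_f + log_w, math.log(LOG_FLOOR))
    return float(np.sum(log_f))
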