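"""Bayesian estimation of decision models.

The central objects follow the Model/Results pattern:
:class:`DecisionModel` holds trial data (one :class:`~flyddm.trials.TrialSet`
per photostimulation condition) together with a :class:`ModelSpec` saying
which family (drift-diffusion or extrema detection) and which parameters are
shared across conditions versus free per condition; ``fit()`` runs
coordinate-wise slice sampling over the flat-prior posterior (parameters
positive, non-decision parameters in (0, 3]) and returns a
:class:`DecisionFitResult` carrying the posterior draws, the best estimate
(mode of a kernel-smoothed joint density over the draws), the maximized
log-likelihood, and the BIC.

The sampling budget defaults to 500 retained draws per fitted parameter
after 300 burn-in iterations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from scipy.special import erfcinv

from . import ddm as _ddm
from . import extrema as _ed
from .errors import ValidationError
from .selection import bic as _bic
from .trials import TrialSet

__all__ = [
    "ModelSpec",
    "PosteriorSamples",
    "DecisionModel",
    "DecisionFitResult",
    "log_likelihood",
    "global_log_likelihood",
    "slice_sample",
    "posterior_mode",
    "fit",
]

#: upper prior bound for the non-decision parameters t0 and sigma0
T0_SIGMA0_MAX = 3.0


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which family is fit and how parameters are shared across conditions.

    ``a_policy`` / ``k_policy`` are 'shared' or 'per_condition'.  ``t0`` and
    ``sigma0`` are either None (fitted, always shared) or a fixed value that
    does not count toward the number of fitted parameters q.
    """

    family: Literal["ddm", "ed"] = "ddm"
    a_policy: Literal["shared", "per_condition"] = "shared"
    k_policy: Literal["shared", "per_condition"] = "shared"
    t0: float | None = None
    sigma0: float | None = None
    dt: float = _ed.DEFAULT_DT
    gh_nodes: int = 16

    def __post_init__(self):
        if self.family not in ("ddm", "ed"):
            raise ValidationError(f"unknown family {self.family!r}")
        for pol in (self.a_policy, self.k_policy):
            if pol not in ("shared", "per_condition"):
                raise ValidationError(f"unknown sharing policy {pol!r}")
        for name in ("t0", "sigma0"):
            val = getattr(self, name)
            if val is not None and not (0 < val <= T0_SIGMA0_MAX):
                raise ValidationError(f"fixed {name} must lie in (0, {T0_SIGMA0_MAX}], got {val!r}")

    def param_names(self, conditions: Sequence[float]) -> list[str]:
        names: list[str] = []
        for base, pol in (("A", self.a_policy), ("k", self.k_policy)):
            if pol == "shared" or len(conditions) == 1:
                names.append(base)
            else:
                names.extend(f"{base}[{c:g}]" for c in conditions)
        if self.t0 is None:
            names.append("t0")
        if self.sigma0 is None:
            names.append("sigma0")
        if not names:
            raise ValidationError("model has no free parameters")
        return names

    def q(self, conditions: Sequence[float]) -> int:
        return len(self.param_names(conditions))

    def bounds(self, conditions: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        names = self.param_names(conditions)
        lower = np.zeros(len(names))
        upper = np.array([
            T0_SIGMA0_MAX if n in ("t0", "sigma0") else np.inf for n in names
        ])
        return lower, upper

    def condition_params(self, theta: np.ndarray, conditions: Sequence[float],
                         condition: float) -> tuple[float, float, float, float]:
        """Unpack (A, k, t0, sigma0) for one condition from the flat vector."""
        theta = np.asarray(theta, dtype=float)
        pos = 0
        ci = list(conditions).index(condition)
        nc = len(conditions)
        if self.a_policy == "shared" or nc == 1:
            A = theta[pos]
            pos += 1
        else:
            A = theta[pos + ci]
            pos += nc
        if self.k_policy == "shared" or nc == 1:
            k = theta[pos]
            pos += 1
        else:
            k = theta[pos + ci]
            pos += nc
        t0 = theta[pos] if self.t0 is None else self.t0
        pos += self.t0 is None
        sigma0 = theta[pos] if self.sigma0 is None else self.sigma0
        return float(A), float(k), float(t0), float(sigma0)


# ---------------------------------------------------------------------------
# likelihoods (free-function surface)
# ---------------------------------------------------------------------------

def _loglik_arrays(spec: ModelSpec, A, k, t0, sigma0, rt, choice, absx) -> float:
    if spec.family == "ddm":
        return _ddm.loglik_ddm(rt, choice, absx, A, k, t0, sigma0, gh_nodes=spec.gh_nodes)
    return _ed.loglik_ed(rt, choice, absx, A, k, t0, sigma0, dt=spec.dt)


def _in_support(spec: ModelSpec, A, k, t0, sigma0) -> bool:
    return (A > 0 and k > 0 and 0 < t0 <= T0_SIGMA0_MAX and 0 < sigma0 <= T0_SIGMA0_MAX)


def log_likelihood(spec: ModelSpec, params: Mapping[str, float], ts: TrialSet) -> float:
    """Log-likelihood of a single trial set; -inf (not an exception) outside
    the prior support so that samplers can reject."""
    A, k = params["A"], params["k"]
    t0 = params.get("t0", spec.t0)
    sigma0 = params.get("sigma0", spec.sigma0)
    if t0 is None or sigma0 is None:
        raise ValidationError("t0/sigma0 must be given either in params or fixed in the spec")
    if not _in_support(spec, A, k, t0, sigma0):
        return -np.inf
    rt, choice, x = ts.arrays()
    return _loglik_arrays(spec, A, k, t0, sigma0, rt, choice, np.abs(x))


def global_log_likelihood(spec: ModelSpec,
                          params_by_condition: Mapping[float, Mapping[str, float]],
                          datasets: Mapping[float, TrialSet]) -> float:
    """Sum of per-condition log-likelihoods (log of the product density of a
    global model); condition keys of parameters and datasets must match."""
    if set(params_by_condition) != set(datasets):
        raise ValidationError(
            f"condition mismatch: params {sorted(params_by_condition)} vs data {sorted(datasets)}"
        )
    return float(sum(
        log_likelihood(spec, params_by_condition[c], datasets[c]) for c in datasets
    ))


# ---------------------------------------------------------------------------
# slice sampling
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Retained MCMC draws (rows = samples, columns = parameters)."""

    draws: np.ndarray
    logdensities: np.ndarray
    burn_in: int
    n_per_param: int
    seed: object
    param_names: list[str] = field(default_factory=list)
    n_evals: int = 0

    @property
    def dim(self) -> int:
        return self.draws.shape[1]

    def to_csv(self, path) -> None:
        import pandas as pd

        names = self.param_names or [f"p{i}" for i in range(self.dim)]
        df = pd.DataFrame(self.draws, columns=names)
        df["logdensity"] = self.logdensities
        df.to_csv(path, index=False)


def slice_sample(logdensity: Callable[[np.ndarray], float],
                 init: Sequence[float],
                 n_per_param: int = 500,
                 burn_in: int = 300,
                 seed=0,
                 widths: Sequence[float] | None = None,
                 lower: Sequence[float] | None = None,
                 upper: Sequence[float] | None = None,
                 adapt: bool = True,
                 param_names: Sequence[str] | None = None) -> PosteriorSamples:
    """Coordinate-wise univariate slice sampling (step-out + shrinkage).

    Retains ``n_per_param * dim`` draws after ``burn_in`` full sweeps.
    Initial step widths default to 10% of the prior range for bounded
    coordinates and 1.0 otherwise; with ``adapt=True`` they are re-tuned to
    3x the draw SD every 50 burn-in sweeps (frozen before retention, so the
    retained chain is a valid slice sampler).  Bit-reproducible given seed.
    """
    x = np.asarray(init, dtype=float).copy()
    d = x.size
    lower = np.full(d, -np.inf) if lower is None else np.asarray(lower, dtype=float)
    upper = np.full(d, np.inf) if upper is None else np.asarray(upper, dtype=float)
    if widths is None:
        rng_width = upper - lower
        widths = np.where(np.isfinite(rng_width), 0.1 * rng_width, 1.0)
    w = np.asarray(widths, dtype=float).copy()

    rng = np.random.default_rng(seed)
    lf = float(logdensity(x))
    if not np.isfinite(lf):
        raise ValidationError("logdensity is not finite at the initial point")
    evals = 0

    def logf(xi, i):
        nonlocal evals
        if xi <= lower[i] or xi > upper[i]:
            return -np.inf
        trial = x.copy()
        trial[i] = xi
        evals += 1
        return float(logdensity(trial))

    n_retained = n_per_param * d
    draws = np.empty((n_retained, d))
    logds = np.empty(n_retained)
    recent = np.empty((min(50, max(burn_in, 1)), d))

    total = burn_in + n_retained
    for it in range(total):
        for i in range(d):
            y = lf + math.log(1.0 - rng.random())
            L = x[i] - w[i] * rng.random()
            R = L + w[i]
            L = max(L, lower[i])
            R = min(R, upper[i])
            while L > lower[i] and logf(L, i) > y:
                L = max(L - w[i], lower[i])
            while R < upper[i] and logf(R, i) > y:
                R = min(R + w[i], upper[i])
            while True:
                xi = L + rng.random() * (R - L)
                lf_new = logf(xi, i)
                if lf_new >= y:
                    x[i] = xi
                    lf = lf_new
                    break
                if xi < x[i]:
                    L = xi
                else:
                    R = xi
        if it < burn_in:
            recent[it % recent.shape[0]] = x
            if adapt and (it + 1) % 50 == 0:
                sd = np.std(recent[: min(it + 1, recent.shape[0])], axis=0)
                w = np.where(sd > 0, 3.0 * sd, w)
        else:
            draws[it - burn_in] = x
            logds[it - burn_in] = lf

    return PosteriorSamples(draws=draws, logdensities=logds, burn_in=burn_in,
                            n_per_param=n_per_param, seed=seed,
                            param_names=list(param_names or []), n_evals=evals)


def posterior_mode(samples: PosteriorSamples) -> np.ndarray:
    """Best estimate: the draw maximizing a kernel-smoothed *joint* density
    over the draws (Gaussian product kernel, Silverman bandwidth per
    dimension); for dimension > 4 the highest-logdensity draw is used."""
    draws = samples.draws
    n, d = draws.shape
    if n < 100:
        raise ValidationError(f"posterior_mode needs >= 100 draws, got {n}")
    if d > 4:
        return draws[int(np.argmax(samples.logdensities))].copy()
    sd = np.std(draws, axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    h = sd * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))
    z = draws / h
    sq = np.sum(z * z, axis=1)
    # pairwise squared distances via the expansion |a-b|^2 = |a|^2+|b|^2-2ab
    cross = z @ z.T
    d2 = sq[:, None] + sq[None, :] - 2.0 * cross
    np.clip(d2, 0.0, None, out=d2)
    dens = np.sum(np.exp(-0.5 * d2), axis=1)
    return draws[int(np.argmax(dens))].copy()


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DecisionModel:
    """A decision model bound to trial data.

    Parameters
    ----------
    data : TrialSet or mapping of light power -> TrialSet
        A bare TrialSet is split into conditions by its light column.
    spec : ModelSpec, optional
        Family and sharing plan; keyword arguments build one if omitted.
    """

    def __init__(self, data: TrialSet | Mapping[float, TrialSet],
                 spec: ModelSpec | None = None, **spec_kwargs):
        if spec is None:
            spec = ModelSpec(**spec_kwargs)
        elif spec_kwargs:
            raise ValidationError("pass either a spec or keyword arguments, not both")
        if isinstance(data, TrialSet):
            datasets: dict[float, TrialSet] = {}
            for t in data:
                datasets.setdefault(float(t.light), []).append(t)  # type: ignore[arg-type]
            data = {c: TrialSet(v) for c, v in datasets.items()}  # type: ignore[arg-type]
        if not data:
            raise ValidationError("no data")
        for c, ts in data.items():
            if len(ts) == 0:
                raise ValidationError(f"condition {c} has no trials")
        self.spec = spec
        self.conditions: list[float] = sorted(data)
        self.datasets: dict[float, TrialSet] = {c: data[c] for c in self.conditions}
        self._arrays = {}
        for c in self.conditions:
            rt, choice, x = self.datasets[c].arrays()
            self._arrays[c] = (rt, choice, np.abs(x))
        self.param_names = spec.param_names(self.conditions)
        self.nobs = sum(len(ts) for ts in self.datasets.values())

    @classmethod
    def from_csv(cls, path, spec: ModelSpec | None = None, **spec_kwargs) -> "DecisionModel":
        from .trials import read_trials

        return cls(read_trials(path), spec=spec, **spec_kwargs)

    # -- likelihood --------------------------------------------------------
    def loglike(self, theta: Sequence[float]) -> float:
        """Global log-likelihood at the flat parameter vector; -inf outside
        the prior support."""
        theta = np.asarray(theta, dtype=float)
        if theta.size != len(self.param_names):
            raise ValidationError(
                f"expected {len(self.param_names)} parameters {self.param_names}, got {theta.size}"
            )
        total = 0.0
        for c in self.conditions:
            A, k, t0, sigma0 = self.spec.condition_params(theta, self.conditions, c)
            if not _in_support(self.spec, A, k, t0, sigma0):
                return -np.inf
            rt, choice, absx = self._arrays[c]
            total += _loglik_arrays(self.spec, A, k, t0, sigma0, rt, choice, absx)
        return float(total)

    # -- moment-based initial values --------------------------------------
    def initial_guess(self) -> np.ndarray:
        """Method-of-moments start values from the psychometric and
        chronometric closed forms at the easiest and hardest difficulties."""
        per_cond = {c: self._moments_init(c) for c in self.conditions}
        theta: list[float] = []
        for base, pol in (("A", 0), ("k", 1)):
            vals = [per_cond[c][pol] for c in self.conditions]
            if (self.spec.a_policy if base == "A" else self.spec.k_policy) == "shared" \
                    or len(self.conditions) == 1:
                theta.append(float(np.mean(vals)))
            else:
                theta.extend(vals)
        if self.spec.t0 is None:
            theta.append(float(np.mean([per_cond[c][2] for c in self.conditions])))
        if self.spec.sigma0 is None:
            theta.append(float(np.mean([per_cond[c][3] for c in self.conditions])))
        return np.asarray(theta)

    def _moments_init(self, c: float) -> tuple[float, float, float, float]:
        rt, choice, absx = self._arrays[c]
        levels = np.unique(absx)
        easiest = levels[-1]
        sel = absx == easiest
        acc = float(np.clip(np.mean(choice[sel] == 1), 0.55, 0.999))
        mean_easy = float(np.mean(rt[sel]))
        mean_hard = float(np.mean(rt[absx == levels[0]]))
        t0 = self.spec.t0 if self.spec.t0 is not None else \
            float(np.clip(0.5 * np.min(rt), 1e-3, T0_SIGMA0_MAX))
        sigma0 = self.spec.sigma0 if self.spec.sigma0 is not None else \
            float(np.clip(0.25 * np.std(rt[sel]), 1e-3, T0_SIGMA0_MAX))
        if self.spec.family == "ddm":
            ak = math.log(acc / (1.0 - acc)) / (2.0 * easiest) if easiest > 0 else 1.0
            A = math.sqrt(max(mean_hard - t0, 0.25 * mean_hard, 1e-4))
            k = max(ak / A, 1e-3)
            return A, k, t0, sigma0
        # extrema detection: invert the erfc crossing probabilities
        dt = self.spec.dt
        tau = max(mean_easy - t0, 10.0 * dt)
        p = min(dt / tau, 0.5)
        u_plus = erfcinv(2.0 * np.clip(acc * p, 1e-12, 0.999))
        u_minus = erfcinv(2.0 * np.clip((1.0 - acc) * p, 1e-12, 0.999))
        root = math.sqrt(2.0 * dt)
        A = max(root * (u_plus + u_minus) / 2.0, 1e-4)
        k = max(root * (u_minus - u_plus) / (2.0 * easiest * dt), 1e-3) if easiest > 0 else 1.0
        return float(A), float(k), t0, sigma0

    # -- fitting -----------------------------------------------------------
    def fit(self, seed=0, n_per_param: int = 500, burn_in: int = 300,
            init: Sequence[float] | None = None,
            widths: Sequence[float] | None = None,
            polish: bool = True) -> "DecisionFitResult":
        """Slice-sample the posterior and summarize it.

        Returns a :class:`DecisionFitResult` whose best estimate is the
        smoothed joint-posterior mode, with BIC = q log n - 2 Lhat.  Lhat is
        the *maximized* log-likelihood: with ``polish=True`` (default) a
        deterministic Nelder-Mead ascent from the best posterior draw
        replaces the plug-in value, which a finite chain systematically
        under-estimates.
        """
        lower, upper = self.spec.bounds(self.conditions)
        theta0 = np.asarray(init, dtype=float) if init is not None else self.initial_guess()
        theta0 = np.clip(theta0, lower + 1e-6, np.where(np.isfinite(upper), upper, np.inf))
        if not np.isfinite(self.loglike(theta0)):
            raise ValidationError(f"initial point {theta0} has zero likelihood")
        samples = slice_sample(self.loglike, theta0, n_per_param=n_per_param,
                               burn_in=burn_in, seed=seed, widths=widths,
                               lower=lower, upper=upper,
                               param_names=self.param_names)
        best = posterior_mode(samples)
        lhat = self.loglike(best)
        best_draw = samples.draws[int(np.argmax(samples.logdensities))]
        lhat = max(lhat, float(np.max(samples.logdensities)))
        if polish:
            from scipy.optimize import minimize

            res = minimize(lambda th: -self.loglike(th), best_draw,
                           method="Nelder-Mead",
                           options={"xatol": 1e-5, "fatol": 1e-6, "maxiter": 400 * len(best_draw)})
            if np.isfinite(res.fun) and -res.fun > lhat:
                lhat = float(-res.fun)
        q = len(self.param_names)
        bic_val = _bic(q, self.nobs, lhat)
        return DecisionFitResult(model=self, spec=self.spec, theta=best,
                                 params=dict(zip(self.param_names, best.tolist())),
                                 loglike=lhat, q=q, n=self.nobs, bic=bic_val,
                                 samples=samples, seed=seed)


@dataclass
class DecisionFitResult:
    """Posterior summary of a fitted decision model."""

    spec: ModelSpec
    theta: np.ndarray
    params: dict[str, float]
    loglike: float
    q: int
    n: int
    bic: float
    samples: PosteriorSamples | None = None
    seed: object = None
    model: DecisionModel | None = None

    def params_for(self, condition: float):
        """Family parameter object for one condition, fixed values filled in."""
        if self.model is None:
            raise ValidationError("detached result has no model")
        A, k, t0, sigma0 = self.spec.condition_params(self.theta, self.model.conditions, condition)
        if self.spec.family == "ddm":
            return _ddm.DDMParams(A=A, k=k, t0=t0, sigma0=sigma0)
        return _ed.EDParams(A=A, k=k, t0=t0, sigma0=sigma0, dt=self.spec.dt)

    def summary(self) -> str:
        lines = [
            f"{'Decision model fit':^60}",
            "=" * 60,
            f"family: {self.spec.family:<12} conditions: "
            + (", ".join(f"{c:g}" for c in self.model.conditions) if self.model else "?"),
            f"n = {self.n}   q = {self.q}   logL = {self.loglike:.3f}   BIC = {self.bic:.3f}",
            "-" * 60,
            f"{'parameter':<14}{'estimate':>12}{'post. sd':>12}{'2.5%':>10}{'97.5%':>10}",
        ]
        draws = self.samples.draws if self.samples is not None else None
        for i, name in enumerate(self.params):
            est = self.params[name]
            if draws is not None:
                sd = np.std(draws[:, i], ddof=1)
                lo, hi = np.quantile(draws[:, i], [0.025, 0.975])
                lines.append(f"{name:<14}{est:>12.4f}{sd:>12.4f}{lo:>10.4f}{hi:>10.4f}")
            else:
                lines.append(f"{name:<14}{est:>12.4f}{'':>12}{'':>10}{'':>10}")
        lines.append("=" * 60)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "params": self.params,
            "loglike": self.loglike,
            "q": self.q,
            "n": self.n,
            "bic": self.bic,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DecisionFitResult":
        with open(path) as fh:
            d = json.load(fh)
        spec = ModelSpec(family=d["family"])
        theta = np.asarray(list(d["params"].values()), dtype=float)
        return cls(spec=spec, theta=theta, params=d["params"], loglike=d["loglike"],
                   q=d["q"], n=d["n"], bic=d["bic"], seed=d.get("seed"))


def fit(spec: ModelSpec, datasets: Mapping[float, TrialSet], seed=0,
        n_per_param: int = 500, burn_in: int = 300) -> DecisionFitResult:
    """Convenience wrapper: build a :class:`DecisionModel` and fit it."""
    return DecisionModel(dict(datasets), spec=spec).fit(
        seed=seed, n_per_param=n_per_param, burn_in=burn_in
    )
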