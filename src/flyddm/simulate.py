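"""Synthetic data generators: ground-truth trial sets and toy trajectories.

These emulate the statistical structure of the behavioral assay: per trial,
a fly at difficulty x (log10 odor concentration ratio) makes a choice with
a reaction time drawn either from a drift-diffusion process (Euler-Maruyama
paths to symmetric bounds) or from the exact discrete extrema-detection
process, plus a zero-truncated Gaussian non-decision time.  Trajectory
synthesis produces piecewise-constant-velocity chamber walks that exercise
the kinematics rules.

Every generator takes an explicit seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .ddm import DDMParams
from .errors import DegenerateModelError, ValidationError
from .extrema import EDParams, crossing_probs
from .kinematics import ChamberGeometry, Trajectory
from .trials import Trial, TrialSet

__all__ = [
    "ExperimentDesign",
    "SimulatedTrialSet",
    "simulate_ddm_trials",
    "simulate_ed_trials",
    "simulate_experiment",
    "CrossingSpec",
    "simulate_trajectory",
    "DEFAULT_DIFFICULTIES",
]

#: the ten difficulty levels of the standard design: 1, 4, 5, 7 or 9 ppm
#: against 10 ppm, on either side of the chamber
DEFAULT_DIFFICULTIES: tuple[float, ...] = tuple(
    s * math.log10(10.0 / c) for s in (1.0, -1.0) for c in (1, 4, 5, 7, 9)
)


class SimulatedTrialSet(TrialSet):
    """A TrialSet carrying its generating parameters and model family."""

    def __init__(self, trials, truth, family: str):
        super().__init__(trials)
        self.truth = truth
        self.family = family


def _nondecision(rng: np.random.Generator, t0: float, sigma0: float, n: int) -> np.ndarray:
    """Draw N(t0, sigma0) truncated to > 0 by rejection."""
    out = rng.normal(t0, sigma0, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(t0, sigma0, size=int(bad.sum()))
        bad = out <= 0
    return out


def simulate_ddm_trials(params: DDMParams, x: float, n: int, seed,
                        step: float = 1e-4, light: float = 0.0,
                        n_flies: int = 10, bridge: bool = True) -> SimulatedTrialSet:
    """Simulate n drift-diffusion trials at difficulty x.

    Euler-Maruyama paths with drift ``k*|x|`` toward the correct bound +A,
    unit diffusion, start 0, absorbing bounds +/-A, with a per-step
    boundary-crossing check; the reaction time adds a zero-truncated
    Gaussian non-decision time.  With ``bridge=True`` (default) each step
    additionally triggers a crossing with the Brownian-bridge probability
    ``exp(-2(A - a)(A - b)/step)`` given the step endpoints a, b, removing
    the O(sqrt(step)) missed-crossing bias of the bare endpoint check.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if step >= params.A**2:
        import warnings

        warnings.warn("integration step is not small against the typical decision time")
    rng = np.random.default_rng(seed)
    v = params.k * abs(x)
    sqdt = math.sqrt(step)
    dec_time = np.empty(n)
    correct = np.empty(n, dtype=bool)

    block = 256
    chunk = 20000
    for start in range(0, n, chunk):
        m = min(chunk, n - start)
        ev = np.zeros(m)
        t_off = 0.0
        idx = np.arange(m)
        while idx.size:
            g = rng.standard_normal((idx.size, block)) * sqdt + v * step
            path = ev[:, None] + np.cumsum(g, axis=1)
            up = path >= params.A
            dn = path <= -params.A
            if bridge:
                # a bridge trigger needs an endpoint within delta of a bound
                # (probability exp(-25) ~ 1e-11 beyond); find those few
                # entries first, then evaluate the exact probabilities there
                delta = math.sqrt(12.5 * step)
                nearp = np.abs(path) > params.A - delta
                near = nearp.copy()
                near[:, 1:] |= nearp[:, :-1]
                near[:, 0] |= np.abs(ev) > params.A - delta
                rows, cols = np.nonzero(near)
                if rows.size:
                    nxt = path[rows, cols]
                    prv = np.where(cols > 0, path[rows, np.maximum(cols - 1, 0)], ev[rows])
                    with np.errstate(under="ignore", over="ignore"):
                        pu = np.exp(-2.0 * (params.A - prv) * (params.A - nxt) / step)
                        pl = np.exp(-2.0 * (params.A + prv) * (params.A + nxt) / step)
                    pu[(prv >= params.A) | (nxt >= params.A)] = 0.0  # direct hits already counted
                    pl[(prv <= -params.A) | (nxt <= -params.A)] = 0.0
                    u = rng.random(rows.size)
                    up[rows[u < pu], cols[u < pu]] = True
                    trig_dn = (u > 1.0 - pl) & ~(u < pu)
                    dn[rows[trig_dn], cols[trig_dn]] = True
            hit = up | dn
            first = np.argmax(hit, axis=1)
            done = hit[np.arange(idx.size), first]
            if np.any(done):
                rows = np.where(done)[0]
                tloc = first[rows]
                dec_time[start + idx[rows]] = t_off + (tloc + 1) * step
                correct[start + idx[rows]] = up[rows, tloc]
            ev = path[~done, -1]
            idx = idx[~done]
            t_off += block * step

    rt = dec_time + _nondecision(rng, params.t0, params.sigma0, n)
    trials = [
        Trial(rt=float(rt[i]), choice=1 if correct[i] else -1, difficulty=float(x),
              light=light, fly_id=f"sim{i % n_flies:02d}")
        for i in range(n)
    ]
    return SimulatedTrialSet(trials, truth=params, family="ddm")


def simulate_ed_trials(params: EDParams, x: float, n: int, seed,
                       light: float = 0.0, n_flies: int = 10) -> SimulatedTrialSet:
    """Simulate n extrema-detection trials at difficulty x.

    Evidence samples are N(k*|x|*dt, dt) each interval; the trial stops at
    the first sample beyond +A or -A.  Because samples are independent, the
    interval count is exactly geometric with success p_+ + p_- and the
    choice is Bernoulli(p_+/(p_+ + p_-)); trials are drawn from that joint
    law directly, which is distribution-identical to the literal loop.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    p_plus, p_minus = crossing_probs(params.A, params.k, abs(x), params.dt)
    total = float(p_plus + p_minus)
    if total <= 0 or not np.isfinite(1.0 / total):
        raise DegenerateModelError(
            "p_plus + p_minus underflows to zero; increase dt or decrease A"
        )
    rng = np.random.default_rng(seed)
    intervals = rng.geometric(total, size=n)
    correct = rng.random(n) < (p_plus / total)
    rt = intervals * params.dt + _nondecision(rng, params.t0, params.sigma0, n)
    trials = [
        Trial(rt=float(rt[i]), choice=1 if correct[i] else -1, difficulty=float(x),
              light=light, fly_id=f"sim{i % n_flies:02d}")
        for i in range(n)
    ]
    return SimulatedTrialSet(trials, truth=params, family="ed")


@dataclass
class ExperimentDesign:
    """A full condition grid: difficulties x light conditions x trials.

    ``conditions`` maps optical power (mW/mm^2) to the true parameters of
    that condition.  The defaults mirror the standard assay: ten difficulty
    levels, unstimulated / low / high photostimulation with the bound
    height lowered by light, 100 trials per cell.
    """

    difficulties: Sequence[float] = DEFAULT_DIFFICULTIES
    conditions: Mapping[float, DDMParams | EDParams] = field(
        default_factory=lambda: {
            0.0: DDMParams(A=1.0, k=2.0, t0=0.5, sigma0=0.1),
            0.01: DDMParams(A=0.9, k=2.0, t0=0.5, sigma0=0.1),
            0.20: DDMParams(A=0.75, k=2.0, t0=0.5, sigma0=0.1),
        }
    )
    trials_per_cell: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_cell < 1:
            raise ValidationError("trials_per_cell must be >= 1")
        if not self.conditions:
            raise ValidationError("at least one condition is required")


def simulate_experiment(design: ExperimentDesign,
                        family: Literal["ddm", "ed"] = "ddm",
                        step: float = 1e-4) -> dict[float, SimulatedTrialSet]:
    """Simulate one trial set per light condition over the difficulty grid."""
    ss = np.random.SeedSequence(design.seed)
    children = iter(ss.spawn(len(design.conditions) * len(design.difficulties)))
    out: dict[float, SimulatedTrialSet] = {}
    for light, params in design.conditions.items():
        trials: list[Trial] = []
        for x in design.difficulties:
            child = next(children)
            if family == "ddm":
                sub = simulate_ddm_trials(params, x, design.trials_per_cell, child,
                                          step=step, light=light)
            elif family == "ed":
                sub = simulate_ed_trials(params, x, design.trials_per_cell, child,
                                         light=light)
            else:
                raise ValidationError(f"unknown family {family!r}")
            trials.extend(sub)
        out[light] = SimulatedTrialSet(trials, truth=params, family=family)
    return out


# ---------------------------------------------------------------------------
# toy trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossingSpec:
    """One planned traverse of the decision zone.

    ``slowdown`` is the fractional speed reduction achieved inside the zone
    (0.95 means the fly slows to 5% of its approach speed).
    """

    enter_from: Literal["left", "right"]
    dwell_s: float
    slowdown: float
    exit_to: Literal["left", "right"]


def simulate_trajectory(specs: Sequence[CrossingSpec],
                        geometry: ChamberGeometry = ChamberGeometry(),
                        base_speed: float = 10.0,
                        jitter_sd: float = 0.0,
                        seed=None,
                        low_conc_side: str = "right",
                        fly_id: str = "sim00") -> Trajectory:
    """Build a piecewise-constant-velocity chamber walk realizing ``specs``.

    Each spec starts from an end region (an end-to-center run), enters the
    decision zone, dwells for ``dwell_s`` with its minimum in-zone speed at
    ``(1 - slowdown) * base_speed``, and exits toward ``exit_to``.  Gaussian
    position jitter of SD ``jitter_sd`` mm is added on top.
    """
    lo, hi = geometry.zone_lo, geometry.zone_hi
    ends = {"left": geometry.end_width / 2.0, "right": geometry.length - geometry.end_width / 2.0}
    edge = {"left": lo, "right": hi}
    width = hi - lo

    tpts = [0.0]
    ppts = [ends[specs[0].enter_from if specs else "left"]]

    def walk_to(pos: float, speed: float):
        d = abs(pos - ppts[-1])
        if d == 0:
            return
        tpts.append(tpts[-1] + d / speed)
        ppts.append(pos)

    for spec in specs:
        slow_speed = max((1.0 - spec.slowdown) * base_speed, 1e-9)
        walk_to(ends[spec.enter_from], base_speed)
        walk_to(edge[spec.enter_from], base_speed)
        inward = 1.0 if spec.enter_from == "left" else -1.0
        start = edge[spec.enter_from]

        def crawl_between(p1: float, p2: float, slow_time: float):
            """Oscillate between p1 and p2 at the crawl speed for slow_time."""
            remaining = slow_time
            anchor, other = p1, p2
            leg_t = abs(p2 - p1) / slow_speed
            while remaining > leg_t:
                walk_to(other, slow_speed)
                anchor, other = other, anchor
                remaining -= leg_t
            if remaining > 0:
                direction = 1.0 if other > anchor else -1.0
                walk_to(ppts[-1] + direction * slow_speed * remaining, slow_speed)

        if spec.exit_to != spec.enter_from:
            slow_time = (spec.dwell_s - width / base_speed) / (1.0 - slow_speed / base_speed)
            if slow_time <= 0:
                raise ValidationError(
                    f"dwell {spec.dwell_s}s infeasible: zone traverse alone takes {width / base_speed:.2f}s"
                )
            slow_dist = slow_speed * slow_time
            if slow_dist < width - 0.5:
                # exact plan: straight crawl centered in the zone
                fast_half = (width - slow_dist) / 2.0
                walk_to(start + inward * fast_half, base_speed)
                walk_to(start + inward * (fast_half + slow_dist), slow_speed)
            else:
                # long dwell: oscillating crawl between 1 and 2 mm inside
                # (dwell accurate to ~0.1 s, fine for long intervals)
                slow_time = spec.dwell_s - (1.0 + (width - 1.0)) / base_speed
                walk_to(start + inward * 1.0, base_speed)
                crawl_between(start + inward * 1.0, start + inward * 2.0, slow_time)
            walk_to(edge[spec.exit_to], base_speed)
        else:
            probe = 2.0  # fast inward excursion before the crawl (mm)
            slow_time = (spec.dwell_s - 2.0 * probe / base_speed) / (1.0 + slow_speed / base_speed)
            if slow_time <= 0:
                raise ValidationError(
                    f"dwell {spec.dwell_s}s infeasible for a same-side exit"
                )
            slow_dist = slow_speed * slow_time
            walk_to(start + inward * probe, base_speed)
            if probe + slow_dist < width - 0.5:
                walk_to(start + inward * (probe + slow_dist), slow_speed)
            else:
                slow_time = spec.dwell_s - (probe + probe + 1.0) / base_speed
                crawl_between(start + inward * probe, start + inward * (probe + 1.0), slow_time)
            walk_to(edge[spec.exit_to], base_speed)
        walk_to(ends[spec.exit_to], base_speed)

    n_frames = int(math.floor(tpts[-1] * geometry.frame_rate)) + 1
    frame_t = np.arange(n_frames) / geometry.frame_rate
    pos = np.interp(frame_t, tpts, ppts)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.normal(0.0, jitter_sd, size=pos.shape)
    pos = np.clip(pos, 0.0, geometry.length - 1e-9)
    return Trajectory(positions=pos, fly_id=fly_id, low_conc_side=low_conc_side)
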