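# flyddm

Decision models for two-choice reaction-time behavior in walking flies.

Flies discriminating two odor concentrations in a linear chamber produce,
per trial, a choice (exit into the arm with the lower concentration =
correct) and a walking-speed-normalized reaction time — the dwell in a
7 mm central decision zone divided by the transit time across matched
off-center zones. `flyddm` asks two questions of such trial tables:

1. **Which decision strategy generated the data?** Temporal integration —
   a drift-diffusion process with drift `v = k·x` (difficulty
   `x = log10` concentration ratio), unit diffusion, and absorbing bounds
   `±A` — versus extrema detection, where an independent evidence sample
   `N(k·x·Δt, Δt)` is drawn each interval until one exceeds `±A`.
2. **Which parameter does an experimental manipulation move?** For
   closed-loop optogenetic photostimulation delivered on decision-zone
   entry: does light lower the bound height `A`, change the drift scaling
   `k`, both, or neither?

Both families share a Gaussian non-decision time `N(T0, σ0²)` truncated at
zero. The drift-diffusion likelihood uses the first-passage-time density
of the bounded Wiener process (dual small/large-time series, truncation
error 1e-29) convolved with the non-decision kernel; its closed-form
marginals are the psychometric function `P(correct) = 1/(1+exp(−2Akx))`
and the chronometric function `T = (A/kx)·tanh(Akx) + T0`. The
extrema-detection likelihood is the ex-Gaussian with rate
`1/τ_R = (p₊+p₋)/Δt`, `p± = ½·erfc((A ∓ kxΔt)/√(2Δt))`, weighted per
choice by `p±/(p₊+p₋)`.

Parameters are estimated by coordinate-wise slice-sampling MCMC under
flat priors (positivity; `T0, σ0 ∈ (0, 3]`), 500 retained draws per fitted
parameter after 300 burn-in sweeps; the best estimate is the mode of the
kernel-smoothed joint posterior. Models are compared through
`BIC = q·ln(n) − 2·L̂` and Bayes factors `exp(−ΔBIC/2)` on Jeffreys'
scale (decisive beyond 100). A synthetic-data module generates
ground-truth trial sets from either family (Euler–Maruyama paths with a
Brownian-bridge crossing check; exact geometric sampling for extrema
detection) and toy chamber trajectories for the reaction-time extraction
rules.

## Worked example

Simulate the standard photostimulation experiment (ten difficulty levels,
three light intensities, bound height lowered by light: A = 1.0 / 0.9 /
0.75 at 0 / 0.01 / 0.20 mW mm⁻²), then test which mechanism the data
support:

```python
import flyddm as f
from flyddm.inference import DecisionModel, ModelSpec
from flyddm.selection import compare

design = f.ExperimentDesign(trials_per_cell=100, seed=7)
datasets = f.simulate_experiment(design, family="ddm")

# non-decision parameters from the unstimulated condition, then fixed
unstim = DecisionModel({0.0: datasets[0.0]}, spec=ModelSpec(family="ddm")).fit(
    seed=1, n_per_param=200, burn_in=150)
t0, s0 = unstim.params["t0"], unstim.params["sigma0"]

var_a = DecisionModel(datasets, spec=ModelSpec(
    family="ddm", a_policy="per_condition", t0=t0, sigma0=s0)).fit(
    seed=1, n_per_param=200, burn_in=150)
fixed = DecisionModel(datasets, spec=ModelSpec(
    family="ddm", t0=t0, sigma0=s0)).fit(seed=1, n_per_param=200, burn_in=150)

print(var_a.summary())
c = compare(var_a, fixed, "variable-A", "light-insensitive")
print(f"dBIC = {c.delta_bic:.2f}, Bayes factor = {c.bayes_factor:.3g}")
print(c.jeffreys_label)
```

Output:

```
                     Decision model fit
============================================================
family: ddm          conditions: 0, 0.01, 0.2
n = 3000   q = 4   logL = -3113.531   BIC = 6259.088
------------------------------------------------------------
parameter         estimate    post. sd      2.5%     97.5%
A[0]                1.0339      0.0144    1.0002    1.0570
A[0.01]             0.8775      0.0123    0.8582    0.9056
A[0.2]              0.7532      0.0102    0.7322    0.7745
k                   1.9849      0.0562    1.8679    2.0836
============================================================
dBIC = -246.70, Bayes factor = 3.73e+53
decisive in favor of variable-A
```

The per-condition bound heights recover the generating values (1.0, 0.9,
0.75) and decrease with optical power, and the variable-bound model beats
the light-insensitive one decisively: on these data, photostimulation
lowers the decision bound.

A command-line interface mirrors the library:

```bash
flyddm simulate --family ddm --trials-per-cell 100 --seed 7 --out data/
flyddm preprocess --traj fly1.csv --out trials.csv --qc-report qc.json
flyddm fit --data trials.csv --vary A --t0 0.49 --sigma0 0.11 --out fit_varA.json
flyddm compare --fit-a fit_varA.json --fit-b fit_fixed.json --out comparison.csv
```

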