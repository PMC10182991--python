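import math

import numpy as np
import pytest

from flyddm import (
    DDMParams,
    DecisionModel,
    ModelSpec,
    Trial,
    TrialSet,
    global_log_likelihood,
    log_likelihood,
    posterior_mode,
    rt_density,
    simulate_ddm_trials,
    slice_sample,
)
from flyddm.errors import ValidationError
from flyddm.inference import PosteriorSamples


def _ts(trials):
    return TrialSet(trials)


class TestLogLikelihood:
    SPEC = ModelSpec(family="ddm")
    PARAMS = {"A": 1.0, "k": 2.0, "t0": 0.5, "sigma0": 0.1}

    def test_single_trial_is_log_density(self):
        ts = _ts([Trial(rt=1.2, choice=1, difficulty=0.3)])
        d = rt_density(1.2, 1, DDMParams(**{"A": 1.0, "k": 2.0, "t0": 0.5, "sigma0": 0.1}), 0.3)
        assert log_likelihood(self.SPEC, self.PARAMS, ts) == pytest.approx(math.log(d), rel=1e-10)

    def test_concatenation_sums(self):
        a = _ts([Trial(rt=1.2, choice=1, difficulty=0.3)])
        b = _ts([Trial(rt=0.9, choice=-1, difficulty=1.0), Trial(rt=1.7, choice=1, difficulty=0.05)])
        both = _ts(list(a) + list(b))
        assert log_likelihood(self.SPEC, self.PARAMS, both) == pytest.approx(
            log_likelihood(self.SPEC, self.PARAMS, a) + log_likelihood(self.SPEC, self.PARAMS, b),
            rel=1e-10,
        )

    def test_brute_force_oracle_ten_trials(self, rng):
        trials = [Trial(rt=float(rng.uniform(0.6, 2.5)), choice=int(rng.choice([-1, 1])),
                        difficulty=float(rng.choice([-1.0, -0.3, 0.05, 0.3])))
                  for _ in range(10)]
        expected = sum(
            math.log(rt_density(t.rt, t.choice, DDMParams(A=1.0, k=2.0, t0=0.5, sigma0=0.1),
                                abs(t.difficulty)))
            for t in trials
        )
        assert log_likelihood(self.SPEC, self.PARAMS, _ts(trials)) == pytest.approx(expected, rel=1e-10)

    def test_trial_order_invariance(self, rng):
        trials = [Trial(rt=float(rng.uniform(0.6, 2.5)), choice=int(rng.choice([-1, 1])),
                        difficulty=0.3) for _ in range(20)]
        shuffled = list(trials)
        rng.shuffle(shuffled)
        assert log_likelihood(self.SPEC, self.PARAMS, _ts(trials)) == pytest.approx(
            log_likelihood(self.SPEC, self.PARAMS, _ts(shuffled)), rel=1e-12
        )

    @pytest.mark.parametrize("bad", [{"A": -1.0}, {"k": 0.0}, {"t0": 3.5}, {"sigma0": 0.0}])
    def test_out_of_support_is_minus_inf_not_exception(self, bad):
        ts = _ts([Trial(rt=1.2, choice=1, difficulty=0.3)])
        assert log_likelihood(self.SPEC, {**self.PARAMS, **bad}, ts) == -np.inf


class TestGlobalLogLikelihood:
    SPEC = ModelSpec(family="ddm")
    P = {"A": 1.0, "k": 2.0, "t0": 0.5, "sigma0": 0.1}

    def test_single_condition_degenerates(self):
        ts = _ts([Trial(rt=1.2, choice=1, difficulty=0.3)])
        assert global_log_likelihood(self.SPEC, {0.0: self.P}, {0.0: ts}) == pytest.approx(
            log_likelihood(self.SPEC, self.P, ts)
        )

    def test_two_identical_conditions_double(self):
        ts = _ts([Trial(rt=1.2, choice=1, difficulty=0.3)])
        val = global_log_likelihood(self.SPEC, {0.0: self.P, 0.2: self.P}, {0.0: ts, 0.2: ts})
        assert val == pytest.approx(2 * log_likelihood(self.SPEC, self.P, ts))

    def test_per_condition_separability(self):
        ts1 = _ts([Trial(rt=1.2, choice=1, difficulty=0.3)])
        ts2 = _ts([Trial(rt=0.9, choice=-1, difficulty=0.3)])
        base = {0.0: self.P, 0.2: dict(self.P)}
        v0 = global_log_likelihood(self.SPEC, base, {0.0: ts1, 0.2: ts2})
        perturbed = {0.0: self.P, 0.2: {**self.P, "A": 1.3}}
        v1 = global_log_likelihood(self.SPEC, perturbed, {0.0: ts1, 0.2: ts2})
        # condition-1 term unchanged: the difference equals the condition-2 change
        d2 = log_likelihood(self.SPEC, perturbed[0.2], ts2) - log_likelihood(self.SPEC, base[0.2], ts2)
        assert v1 - v0 == pytest.approx(d2, rel=1e-10)

    def test_condition_mismatch_raises(self):
        ts = _ts([Trial(rt=1.2, choice=1, difficulty=0.3)])
        with pytest.raises(ValidationError):
            global_log_likelihood(self.SPEC, {0.0: self.P}, {0.1: ts})


class TestSliceSampler:
    def test_standard_normal_moments(self):
        logf = lambda x: -0.5 * float(x[0] ** 2)
        s = slice_sample(logf, [0.0], n_per_param=10000, burn_in=300, seed=7)
        assert abs(np.mean(s.draws)) < 0.05
        assert 0.9 < np.var(s.draws) < 1.1

    def test_bounded_support_respected(self):
        logf = lambda x: 0.0 if 0 < x[0] <= 3 else -np.inf
        s = slice_sample(logf, [1.0], n_per_param=2000, burn_in=100, seed=3,
                         lower=[0.0], upper=[3.0])
        assert np.all(s.draws > 0) and np.all(s.draws <= 3.0)
        # flat density on (0,3]: draws should look uniform
        assert np.mean(s.draws) == pytest.approx(1.5, abs=0.1)

    def test_same_seed_bit_identical(self):
        logf = lambda x: -0.5 * float(x[0] ** 2 + x[1] ** 2)
        a = slice_sample(logf, [0.1, -0.2], n_per_param=200, burn_in=50, seed=11)
        b = slice_sample(logf, [0.1, -0.2], n_per_param=200, burn_in=50, seed=11)
        assert np.array_equal(a.draws, b.draws)

    def test_retained_draw_count(self):
        logf = lambda x: -0.5 * float(np.sum(np.asarray(x) ** 2))
        s = slice_sample(logf, [0.0, 0.0, 0.0], n_per_param=100, burn_in=10, seed=5)
        assert s.draws.shape == (300, 3)

    def test_infinite_start_rejected(self):
        logf = lambda x: -np.inf
        with pytest.raises(ValidationError):
            slice_sample(logf, [0.0], n_per_param=10, burn_in=1, seed=0)


def _samples(draws, logds=None):
    draws = np.asarray(draws, dtype=float)
    if logds is None:
        logds = np.zeros(len(draws))
    return PosteriorSamples(draws=draws, logdensities=np.asarray(logds),
                            burn_in=0, n_per_param=len(draws) // draws.shape[1], seed=0)


class TestPosteriorMode:
    def test_gaussian_mode_near_center(self, rng):
        mu = np.array([1.0, -2.0])
        draws = rng.normal(mu, 0.5, size=(4000, 2))
        mode = posterior_mode(_samples(draws))
        assert np.all(np.abs(mode - mu) < 0.1 * 0.5 * np.array([1, 1]) * 2)  # within 0.1 SD x safety

    def test_repeated_draw_returns_it(self):
        draws = np.tile([[2.5]], (200, 1))
        assert posterior_mode(_samples(draws))[0] == 2.5

    def test_bimodal_prefers_heavier_lobe(self, rng):
        light = rng.normal(-3.0, 0.3, size=(300, 1))
        heavy = rng.normal(3.0, 0.3, size=(1200, 1))
        mode = posterior_mode(_samples(np.vstack([light, heavy])))
        assert mode[0] > 2.0

    def test_high_dimension_uses_best_logdensity(self, rng):
        draws = rng.normal(0, 1, size=(500, 5))
        logds = rng.normal(size=500)
        mode = posterior_mode(_samples(draws, logds))
        assert np.array_equal(mode, draws[np.argmax(logds)])

    def test_too_few_draws(self):
        with pytest.raises(ValidationError):
            posterior_mode(_samples(np.zeros((50, 1))))


@pytest.fixture(scope="module")
def tiny_data():
    truth = DDMParams(A=1.0, k=2.0, t0=0.5, sigma0=0.1)
    trials = []
    for i, x in enumerate([0.05, 0.3, 1.0]):
        trials.extend(simulate_ddm_trials(truth, x, 80, seed=50 + i))
    return TrialSet(trials)


class TestDecisionModelFit:
    def test_seed_determinism(self, tiny_data):
        spec = ModelSpec(family="ddm", t0=0.5, sigma0=0.1)
        r1 = DecisionModel({0.0: tiny_data}, spec=spec).fit(seed=9, n_per_param=60, burn_in=40)
        r2 = DecisionModel({0.0: tiny_data}, spec=spec).fit(seed=9, n_per_param=60, burn_in=40)
        assert np.array_equal(r1.theta, r2.theta)
        assert r1.bic == r2.bic

    def test_bic_recomputable_from_fields(self, tiny_data):
        spec = ModelSpec(family="ddm", t0=0.5, sigma0=0.1)
        r = DecisionModel({0.0: tiny_data}, spec=spec).fit(seed=9, n_per_param=60, burn_in=40)
        assert r.bic == pytest.approx(r.q * math.log(r.n) - 2 * r.loglike, rel=1e-12)
        assert r.n == len(tiny_data)
        assert r.q == 2

    def test_light_split_from_bare_trialset(self):
        trials = [Trial(rt=1.0, choice=1, difficulty=0.3, light=0.0),
                  Trial(rt=1.1, choice=1, difficulty=0.3, light=0.2)]
        m = DecisionModel(TrialSet(trials), family="ddm", t0=0.5, sigma0=0.1)
        assert m.conditions == [0.0, 0.2]

    def test_param_naming_per_condition(self):
        spec = ModelSpec(family="ddm", a_policy="per_condition", t0=0.5, sigma0=0.1)
        trials = [Trial(rt=1.0, choice=1, difficulty=0.3, light=0.0),
                  Trial(rt=1.1, choice=1, difficulty=0.3, light=0.2)]
        m = DecisionModel(TrialSet(trials), spec=spec)
        assert m.param_names == ["A[0]", "A[0.2]", "k"]
        assert spec.q(m.conditions) == 3

    def test_summary_contains_key_fields(self, tiny_data):
        spec = ModelSpec(family="ddm", t0=0.5, sigma0=0.1)
        r = DecisionModel({0.0: tiny_data}, spec=spec).fit(seed=9, n_per_param=60, burn_in=40)
        text = r.summary()
        assert "BIC" in text and "A" in text and "ddm" in text
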