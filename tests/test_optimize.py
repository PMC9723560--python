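"""Optimization moves, schedules and replicate management."""

import math

import numpy as np
import pytest

from fluxnet.config import ModelSpec, Param
from fluxnet.optimize import (
    ParamRef,
    collect_optimizable,
    lhs_scan,
    nelder_mead_subset,
    refine_sensitive,
    replicate_manager,
    single_param_sweep,
    elite_stats,
)


class ToyProblem:
    """Analytic objective over @env parameters (no ODE in the loop)."""

    def __init__(self, fn):
        self.fn = fn
        self.n_evals = 0
        self.exhausted = False

    def evaluate(self, spec):
        self.n_evals += 1
        x = {k: p.value for k, p in spec.environment.items()}
        return float(self.fn(x))


def toy_spec(**params):
    spec = ModelSpec()
    for name, (val, lo, hi) in params.items():
        spec.environment[name] = Param(val, lo, hi, optimize=True)
    return spec


class TestSweep:
    def test_recovers_quadratic_minimum(self):
        spec = toy_spec(x=(0.1, -2.0, 2.0))
        prob = ToyProblem(lambda p: (p["x"] - 0.7) ** 2)
        refs = collect_optimizable(spec)
        best, sens = single_param_sweep(spec, prob, refs, prob.evaluate(spec), 7)
        assert refs[0].value(spec) == pytest.approx(0.7, abs=1e-4)
        assert sens[refs[0]] > 0

    def test_zero_influence_parameter_untouched(self):
        spec = toy_spec(x=(0.3, -1.0, 1.0), dead=(0.5, 0.0, 1.0))
        prob = ToyProblem(lambda p: (p["x"] - 0.2) ** 2)
        refs = collect_optimizable(spec)
        best, sens = single_param_sweep(spec, prob, refs, prob.evaluate(spec), 5)
        dead = [r for r in refs if r.name == "dead"][0]
        assert dead.value(spec) == 0.5
        assert sens[dead] == 0.0

    def test_separable_bowl_matches_coordinate_descent(self):
        target = {"a": 0.1, "b": -0.4, "c": 0.9, "d": -1.2, "e": 0.0}

        def bowl(p):
            return sum((p[k] - target[k]) ** 2 for k in target)

        spec = toy_spec(**{k: (0.0, -2.0, 2.0) for k in target})
        prob = ToyProblem(bowl)
        refs = collect_optimizable(spec)
        best = prob.evaluate(spec)
        best, _ = single_param_sweep(spec, prob, refs, best, 9)
        # oracle: exact coordinate descent solves a separable bowl exactly
        for r in refs:
            assert r.value(spec) == pytest.approx(target[r.name], abs=1e-3)
        assert best < 1e-5

    def test_infinite_bounds_rejected(self):
        spec = ModelSpec()
        spec.environment["x"] = Param(1.0, 0.0, math.inf, optimize=True)
        prob = ToyProblem(lambda p: p["x"] ** 2)
        with pytest.raises(ValueError, match="finite"):
            single_param_sweep(spec, prob, collect_optimizable(spec), 1.0)


class TestRefine:
    def test_full_fraction_equals_second_sweep(self):
        def fn(p):
            return (p["x"] - 0.33) ** 2 + abs(p["y"])

        spec1 = toy_spec(x=(0.0, -1, 1), y=(0.5, -1, 1))
        prob1 = ToyProblem(fn)
        refs1 = collect_optimizable(spec1)
        b1, s1 = single_param_sweep(spec1, prob1, refs1, prob1.evaluate(spec1), 5)
        b1 = refine_sensitive(spec1, prob1, s1, b1, top_fraction=1.0, sweep_points=5)

        spec2 = toy_spec(x=(0.0, -1, 1), y=(0.5, -1, 1))
        prob2 = ToyProblem(fn)
        refs2 = collect_optimizable(spec2)
        b2, s2 = single_param_sweep(spec2, prob2, refs2, prob2.evaluate(spec2), 5)
        b2, _ = single_param_sweep(spec2, prob2, refs2, b2, 5)
        assert b1 == pytest.approx(b2, rel=1e-12)

    def test_zero_fraction_is_noop(self):
        spec = toy_spec(x=(0.4, -1, 1))
        prob = ToyProblem(lambda p: p["x"] ** 2)
        best = refine_sensitive(spec, prob, {}, 0.16, top_fraction=0.0)
        assert best == 0.16 and prob.n_evals == 0


class TestNelderMead:
    def test_rosenbrock_in_box(self):
        spec = toy_spec(x=(-1.0, -2.0, 2.0), y=(2.0, -1.0, 3.0))

        def rosen(p):
            return (1 - p["x"]) ** 2 + 100 * (p["y"] - p["x"] ** 2) ** 2

        prob = ToyProblem(rosen)
        refs = collect_optimizable(spec)
        best = prob.evaluate(spec)
        for _ in range(4):
            best = nelder_mead_subset(spec, prob, refs, best, maxiter=400,
                                      rng=np.random.default_rng(0))
        assert refs[0].value(spec) == pytest.approx(1.0, abs=1e-3)
        assert refs[1].value(spec) == pytest.approx(1.0, abs=1e-3)

    def test_fixed_parameter_in_subset_rejected(self):
        spec = toy_spec(x=(0.0, -1, 1), y=(0.0, -1, 1))
        spec.environment["y"].optimize = False
        prob = ToyProblem(lambda p: p["x"] ** 2)
        refs = [ParamRef("@env", "x"), ParamRef("@env", "y")]
        with pytest.raises(ValueError, match="not an optimizable"):
            nelder_mead_subset(spec, prob, refs, 1.0)

    def test_accepted_only_on_improvement(self):
        spec = toy_spec(x=(0.05, -1, 1), y=(0.05, -1, 1))
        prob = ToyProblem(lambda p: p["x"] ** 2 + p["y"] ** 2)
        refs = collect_optimizable(spec)
        start = prob.evaluate(spec)
        best = nelder_mead_subset(spec, prob, refs, start, maxiter=50,
                                  rng=np.random.default_rng(0))
        assert best <= start


class TestLHS:
    def test_per_dimension_stratification(self):
        """Each of n bins in each dimension is visited exactly once."""
        from scipy.stats import qmc
        n, d = 16, 3
        X = qmc.LatinHypercube(d=d, seed=np.random.default_rng(0)).random(n)
        for j in range(d):
            bins = np.floor(X[:, j] * n).astype(int)
            assert sorted(bins) == list(range(n))

    def test_seeded_reproducibility(self):
        spec1 = toy_spec(x=(0.0, -1, 1), y=(0.0, -1, 1))
        prob1 = ToyProblem(lambda p: (p["x"] - 0.5) ** 2 + (p["y"] + 0.5) ** 2)
        best1 = lhs_scan(spec1, prob1, collect_optimizable(spec1), math.inf, 20,
                         np.random.default_rng(42))
        spec2 = toy_spec(x=(0.0, -1, 1), y=(0.0, -1, 1))
        prob2 = ToyProblem(lambda p: (p["x"] - 0.5) ** 2 + (p["y"] + 0.5) ** 2)
        best2 = lhs_scan(spec2, prob2, collect_optimizable(spec2), math.inf, 20,
                         np.random.default_rng(42))
        assert best1 == best2
        assert collect_optimizable(spec1)[0].value(spec1) == \
            collect_optimizable(spec2)[0].value(spec2)

    def test_single_sample_accept_if_better(self):
        spec = toy_spec(x=(0.9, -1, 1))
        prob = ToyProblem(lambda p: p["x"] ** 2)
        best = lhs_scan(spec, prob, collect_optimizable(spec), 0.81, 1,
                        np.random.default_rng(0))
        assert best <= 0.81

    def test_beats_plain_monte_carlo_on_multimodal(self):
        """LHS stratification locates the global basin of a multimodal toy
        at least as often as unstratified sampling at equal n."""
        from scipy.stats import qmc

        def fn(x):   # narrow global well at 0.93, broad local well at 0.2
            return ((x - 0.2) ** 2 * 0.3 + 0.02) * (abs(x - 0.93) > 0.05) \
                + (abs(x - 0.93) <= 0.05) * (x - 0.93) ** 2

        n = 10
        hits_lhs = hits_mc = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            xs_lhs = qmc.LatinHypercube(1, seed=rng).random(n)[:, 0]
            xs_mc = np.random.default_rng(seed + 1000).random(n)
            if np.any(np.abs(xs_lhs - 0.93) <= 0.05):
                hits_lhs += 1
            if np.any(np.abs(xs_mc - 0.93) <= 0.05):
                hits_mc += 1
        assert hits_lhs >= hits_mc


class TestReplicates:
    def test_single_replicate_elite(self):
        elite, results = replicate_manager(lambda s: (None, None, 1.0 + s), [3])
        assert len(elite) == 1 and elite[0].seed == 3
        mean, sd = elite_stats([elite[0].error])
        assert mean == 4.0 and math.isnan(sd)

    def test_elite_fraction_selects_best(self):
        elite, results = replicate_manager(
            lambda s: (None, None, float(s)), list(range(20)), elite_frac=0.05)
        assert [r.seed for r in elite] == [0]

    def test_all_failed_raises(self):
        with pytest.raises(RuntimeError, match="all replicates failed"):
            replicate_manager(lambda s: (None, None, math.inf), [0, 1])
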