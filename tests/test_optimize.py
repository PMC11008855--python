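"""Metaheuristic kernels: schedule/map identities, update-rule arithmetic,
and convergence of the hybrid driver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridpath import (
    OptConfig,
    csco_update,
    hybrid_optimize,
    logistic_next,
    replace_worst,
    rg_schedule,
    roa_update,
)
from hybridpath.optimize import Agent, sphere, validate_chaos_seed


class _StubRng:
    """Deterministic stand-in feeding prescribed uniform draws."""

    def __init__(self, scalars, vectors=None, normals=None):
        self.scalars = list(scalars)
        self.vectors = list(vectors or [])
        self.normals = list(normals or [])

    def random(self, size=None):
        if size is None:
            return self.scalars.pop(0)
        return np.asarray(self.vectors.pop(0), dtype=np.float64)

    def uniform(self, lo, hi):
        return self.scalars.pop(0) * (hi - lo) + lo

    def standard_normal(self, size):
        return np.asarray(self.normals.pop(0), dtype=np.float64)


class TestSchedulesAndMap:
    @pytest.mark.parametrize("t,expected", [(0, 2.0), (50, 1.0), (100, 0.0)])
    def test_sensitivity_decays_linearly(self, t, expected):
        assert rg_schedule(t, 100, 2.0) == pytest.approx(expected)

    def test_zero_horizon_rejected(self):
        with pytest.raises(ValueError):
            rg_schedule(0, 0)

    def test_logistic_map_orbit(self):
        assert logistic_next(0.7) == pytest.approx(0.84)
        assert logistic_next(0.84) == pytest.approx(0.5376)
        assert logistic_next(0.5) == pytest.approx(1.0)  # why 0.5 is forbidden

    @pytest.mark.parametrize("bad", [0.0, 0.25, 0.5, 0.75, 1.0, -0.1, 1.3])
    def test_forbidden_seeds_rejected(self, bad):
        with pytest.raises(ValueError):
            validate_chaos_seed(bad)

    def test_chaotic_stream_stays_in_unit_interval(self):
        mu = 0.7
        for _ in range(10_000):
            mu = logistic_next(mu)
            assert 0.0 < mu < 1.0


class TestCscoUpdate:
    def test_zero_sensitivity_returns_best(self):
        # rand = 0.5, rG = 2 ⇒ R = 0 ⇒ exploitation; rG·μ = 0 kills the term
        rng = _StubRng(scalars=[0.5, 0.3], vectors=[[0.2, 0.9]])
        best = np.array([1.0, -2.0])
        new = csco_update(np.array([3.0, 4.0]), best, rg=2.0, chaos_mu=0.0,
                          rng=rng, bounds=(-5, 5))
        np.testing.assert_allclose(new, best)

    def test_transition_at_half_rand_selects_exploitation(self):
        # R = 2·rG·0.5 − rG = 0 for any rG, so |R| ≤ 1 always holds here;
        # with θ = 90° the cosine kills the attack term and pos = best
        rng = _StubRng(scalars=[0.5, 0.25], vectors=[[0.5, 0.5]])
        best = np.array([2.0, 2.0])
        new = csco_update(np.array([0.0, 0.0]), best, rg=2.0, chaos_mu=0.9,
                          rng=rng, bounds=(-5, 5))
        np.testing.assert_allclose(new, best, atol=1e-12)

    def test_matches_independent_recomputation(self, rng):
        """Line-by-line re-computation of the update with a recorded stream."""
        d = 5
        pos = rng.uniform(-3, 3, d)
        best = rng.uniform(-3, 3, d)
        rg_val, chaos = 1.3, 0.42
        seed_state = rng.integers(2 ** 31)
        stream = np.random.default_rng(seed_state)
        got = csco_update(pos, best, rg_val, chaos, stream, (-5, 5))
        replay = np.random.default_rng(seed_state)
        r_trans = 2 * rg_val * replay.random() - rg_val
        if abs(r_trans) <= 1:
            pos_rnd = np.abs(replay.random(d) * best - pos)
            theta = np.deg2rad(replay.uniform(0, 360))
            expected = best - pos_rnd * np.cos(theta) * (rg_val * chaos)
        else:
            expected = (rg_val * chaos) * (best - replay.random(d) * pos)
        np.testing.assert_allclose(got, np.clip(expected, -5, 5), rtol=1e-12)


class TestReplaceWorst:
    def test_toward_best_branch(self):
        pop = [Agent(np.array([0.0, 0.0]), 1.0), Agent(np.array([9.0, 9.0]), 50.0)]
        rng = _StubRng(scalars=[0.4], vectors=[[0.5, 0.5]])
        replace_worst(pop, np.array([2.0, 2.0]), (-5, 5), rng, sphere)
        np.testing.assert_allclose(pop[1].position, [1.0, 1.0])
        assert pop[1].fitness == pytest.approx(2.0)

    def test_resample_branch_at_lower_bound(self):
        pop = [Agent(np.array([0.0] * 3), 1.0), Agent(np.array([4.0] * 3), 48.0)]
        rng = _StubRng(scalars=[0.6], vectors=[[0.0, 0.0, 0.0]])
        replace_worst(pop, np.array([2.0] * 3), (-5, 5), rng, sphere)
        np.testing.assert_allclose(pop[1].position, [-5.0] * 3)

    def test_population_size_unchanged(self, rng):
        pop = [Agent(rng.uniform(-5, 5, 4), float(i)) for i in range(6)]
        out = replace_worst(pop, pop[0].position, (-5, 5),
                            np.random.default_rng(0), sphere)
        assert len(out) == 6


class TestRoaUpdate:
    def test_sfo_with_zero_rand_lands_at_best_plus_rand(self):
        # rand = 0 ⇒ candidate = R_best + R_rand; make the trial strictly
        # better so the candidate-vs-trial greedy step is exercised
        best = np.array([1.0, 1.0])
        r_rand = np.array([0.5, -0.5])
        r_pre = np.array([0.0, 0.0])
        rng = _StubRng(scalars=[], vectors=[[0.0, 0.0]], normals=[[1.0, 1.0]])
        got = roa_update(np.array([2.0, 2.0]), best, r_rand, r_pre, t=1,
                         t_max=10, fitness_fn=sphere, rng=rng, bounds=(-5, 5))
        # candidate (1.5, 0.5); trial = cand − (cand − pre)·1 = 0 — better
        np.testing.assert_allclose(got, [0.0, 0.0])

    def test_host_feeding_is_noop_at_final_iteration(self):
        pos = np.array([2.0, -1.0])
        # trial must be rejected: normals push the trial away from 0
        rng = _StubRng(scalars=[0.9], vectors=[[1.0, 1.0], [0.5, 0.5]],
                       normals=[[5.0, 5.0]])
        got = roa_update(pos, np.array([0.1, 0.1]), np.array([3.0, 3.0]),
                         np.array([0.0, 0.0]), t=10, t_max=10,
                         fitness_fn=sphere, rng=rng, bounds=(-5, 5))
        np.testing.assert_allclose(got, pos)

    def test_woa_spiral_is_noop_when_at_best(self):
        pos = np.array([0.0, 0.0])
        best = pos.copy()
        rng = _StubRng(scalars=[0.2, 0.7], vectors=[[1.0, 1.0]],
                       normals=[[50.0, 50.0]])
        got = roa_update(pos, best, np.array([4.0, 4.0]), np.array([1.0, 1.0]),
                         t=1, t_max=10, fitness_fn=sphere, rng=rng,
                         bounds=(-5, 5))
        np.testing.assert_allclose(got, pos)


class TestDriver:
    def test_constant_objective_trace_is_flat(self):
        cfg = OptConfig(pop_size=5, dim=3, t_max=10, seed=0)
        res = hybrid_optimize(lambda x: 7.25, cfg)
        assert np.all(res.trace == 7.25)

    def test_trace_non_increasing(self):
        cfg = OptConfig(pop_size=10, dim=5, t_max=50, seed=1)
        res = hybrid_optimize(sphere, cfg)
        assert np.all(np.diff(res.trace) <= 0)

    def test_positions_respect_bounds(self):
        hits = []

        def probe(x):
            hits.append(x.copy())
            return sphere(x)

        cfg = OptConfig(pop_size=8, dim=4, bounds=(-2.0, 2.0), t_max=30, seed=3)
        hybrid_optimize(probe, cfg)
        stacked = np.stack(hits)
        assert stacked.min() >= -2.0 and stacked.max() <= 2.0

    def test_seeded_determinism(self):
        cfg = OptConfig(pop_size=8, dim=4, t_max=30, seed=9)
        a = hybrid_optimize(sphere, cfg)
        b = hybrid_optimize(sphere, cfg)
        assert a.best_fitness == b.best_fitness
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_nonfinite_fitness_names_the_agent(self):
        cfg = OptConfig(pop_size=4, dim=2, t_max=5, seed=0)
        with pytest.raises(FloatingPointError, match="agent"):
            hybrid_optimize(lambda x: float("nan"), cfg)

    def test_sco_mode_matches_uniform_rand_oracle(self):
        """Non-chaotic mode still minimizes the sphere (regression guard)."""
        cfg = OptConfig(pop_size=15, dim=5, t_max=100, seed=2, mode="sco")
        res = hybrid_optimize(sphere, cfg)
        assert res.best_fitness < 1e-3


@settings(max_examples=50, deadline=None, derandomize=True)
@given(mu=st.floats(0.001, 0.999).filter(
    lambda m: m not in (0.25, 0.5, 0.75)))
def test_logistic_map_preserves_unit_interval(mu):
    assert 0.0 <= logistic_next(mu) <= 1.0
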