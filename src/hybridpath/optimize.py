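"""Continuous metaheuristic core: chaotic sand-cat optimization (CSCO),
remora optimization (ROA), and the hybrid driver that interleaves them.

All algorithms minimize a fitness function over a box.  The sand-cat family
balances exploration and exploitation through a sensitivity schedule rG that
decays linearly from 2 to 0 over the run; the chaotic variant replaces the
uniform draw in the sensitivity product with a logistic-map stream
(μ ← 4μ(1−μ)), which avoids premature convergence.  The remora family moves
agents by a sailfish-style lunge toward the best solution, a small
"experience attack" probe accepted greedily, and two exploitation moves — a
whale-style logarithmic spiral around the best and tiny host-feeding steps
whose amplitude decays to zero by the final iteration.

Hybridization: each agent, each iteration, is routed to the CSCO rule when
the current chaotic value is < 0.5 and to the ROA rule otherwise, so both
operator sets act every iteration on a mixed population.  One worst-agent
replacement per iteration and elitist best-so-far tracking apply in every
mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

SM_HEARING = 2.0          # sand-cat hearing constant
REMORA_FACTOR = 0.01      # remora volume ≈ 1% of the host's
FORBIDDEN_CHAOS_SEEDS = (0.0, 0.25, 0.5, 0.75, 1.0)

MODES = ("sco", "csco", "roa", "hybrid")


@dataclass
class Agent:
    position: np.ndarray
    fitness: float


@dataclass
class OptConfig:
    pop_size: int = 30
    dim: int = 10
    bounds: tuple[float, float] = (-5.0, 5.0)
    t_max: int = 500
    seed: int = 0
    mode: str = "hybrid"
    chaos_seed: float = 0.7

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.pop_size < 2 or self.dim < 1 or self.t_max < 1:
            raise ValueError("pop_size >= 2, dim >= 1 and t_max >= 1 required")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds must satisfy lo < hi")
        validate_chaos_seed(self.chaos_seed)


@dataclass
class OptResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray          # best-so-far per iteration, non-increasing
    n_evaluations: int = 0


def rg_schedule(t: int, t_max: int, s_m: float = SM_HEARING) -> float:
    """General sensitivity rG: linear decay s_m → 0 over the run."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not 0 <= t <= t_max:
        raise ValueError(f"t must be in [0, {t_max}], got {t}")
    return s_m - s_m * t / t_max


def validate_chaos_seed(mu: float) -> None:
    if not 0.0 < mu < 1.0 or mu in FORBIDDEN_CHAOS_SEEDS:
        raise ValueError(
            f"chaos seed must be in (0,1) excluding {FORBIDDEN_CHAOS_SEEDS}, got {mu}"
        )


def logistic_next(mu: float) -> float:
    """One step of the logistic map with the standard chaotic gain a = 4."""
    return 4.0 * mu * (1.0 - mu)


def _clip(x: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    return np.clip(x, bounds[0], bounds[1])


def csco_update(position: np.ndarray, best: np.ndarray, rg: float,
                chaos_mu: float, rng: np.random.Generator,
                bounds: tuple[float, float]) -> np.ndarray:
    """One chaotic sand-cat position update.

    Transition R = 2·rG·rand − rG selects exploitation (|R| ≤ 1): an attack
    toward the best position modulated by cos θ and the chaotic sensitivity
    rG·μ, or exploration (|R| > 1): a scaled move around the best.
    """
    r_transition = 2.0 * rg * rng.random() - rg
    sens = rg * chaos_mu
    if abs(r_transition) <= 1.0:
        pos_rnd = np.abs(rng.random(position.size) * best - position)
        theta = np.deg2rad(rng.uniform(0.0, 360.0))
        new = best - pos_rnd * np.cos(theta) * sens
    else:
        new = sens * (best - rng.random(position.size) * position)
    return _clip(new, bounds)


def replace_worst(population: list[Agent], best: np.ndarray,
                  bounds: tuple[float, float], rng: np.random.Generator,
                  fitness_fn: Callable[[np.ndarray], float]) -> list[Agent]:
    """Replace the worst-fitness agent: toward the best (p = 0.5) or uniformly
    resampled in the box; its fitness is re-evaluated.  Population size is
    unchanged (mutation in place)."""
    if not population:
        raise ValueError("population is empty")
    worst = max(range(len(population)), key=lambda i: population[i].fitness)
    d = population[worst].position.size
    rand3 = rng.random()
    if rand3 <= 0.5:
        new_pos = rng.random(d) * best
    else:
        lo, hi = bounds
        new_pos = lo + rng.random(d) * (hi - lo)
    new_pos = _clip(new_pos, bounds)
    population[worst] = Agent(position=new_pos, fitness=float(fitness_fn(new_pos)))
    return population


def roa_update(position: np.ndarray, best: np.ndarray, r_rand: np.ndarray,
               r_pre: np.ndarray, t: int, t_max: int,
               fitness_fn: Callable[[np.ndarray], float],
               rng: np.random.Generator, bounds: tuple[float, float],
               a_remora: float = REMORA_FACTOR) -> np.ndarray:
    """One remora position update (exploration probe, then exploitation).

    A sailfish lunge proposes R = R_best − (rand·(R_best − R_rand)/2 − R_rand);
    an experience-attack trial R_att = R − (R − R_pre)·randn is accepted when
    strictly better.  Otherwise the agent exploits from its current position:
    a whale-spiral move around the best, or host-feeding increments whose
    amplitude S = 2(1 − t/T) vanishes at the final iteration.
    """
    cand = best - (rng.random(position.size) * (best - r_rand) / 2.0 - r_rand)
    cand = _clip(cand, bounds)
    att = _clip(cand - (cand - r_pre) * rng.standard_normal(position.size), bounds)
    if fitness_fn(att) < fitness_fn(cand):
        return att
    if rng.random() < 0.5:
        # whale-style logarithmic spiral around the best
        n = -(1.0 + t / t_max)
        a = rng.random() * (n - 1.0) + 1.0
        dist = np.abs(best - position)
        new = dist * np.exp(a) * np.cos(2.0 * np.pi * a) + position
    else:
        # host feeding: small steps shrinking to zero by t = T
        s_decay = 2.0 * (1.0 - t / t_max)
        h = 2.0 * s_decay * rng.random(position.size) - s_decay
        new = position + h * (position - a_remora * best)
    return _clip(new, bounds)


def hybrid_optimize(fitness_fn: Callable[[np.ndarray], float],
                    config: OptConfig) -> OptResult:
    """Run the configured optimizer; returns the elitist best and its trace.

    ``mode='sco'`` replaces the chaotic value by a uniform draw in the
    sand-cat sensitivity (the non-chaotic original); ``'csco'`` and ``'roa'``
    run a single family; ``'hybrid'`` routes each agent per iteration by the
    chaotic coin described in the module docstring.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    d = config.dim
    n_eval = 0

    def evaluate(x: np.ndarray, who: str) -> float:
        nonlocal n_eval
        n_eval += 1
        f = float(fitness_fn(x))
        if not np.isfinite(f):
            raise FloatingPointError(f"non-finite fitness {f} for {who}")
        return f

    pop = []
    for i in range(config.pop_size):
        x = rng.uniform(lo, hi, d)
        pop.append(Agent(position=x, fitness=evaluate(x, f"agent {i} (init)")))

    best_i = min(range(len(pop)), key=lambda i: pop[i].fitness)
    best_pos = pop[best_i].position.copy()
    best_fit = pop[best_i].fitness
    prev_pos = [a.position.copy() for a in pop]
    chaos = config.chaos_seed
    trace = np.empty(config.t_max)

    for t in range(1, config.t_max + 1):
        rg = rg_schedule(t, config.t_max)
        for i, agent in enumerate(pop):
            chaos = logistic_next(chaos)
            if config.mode == "hybrid":
                use_csco = chaos < 0.5
            else:
                use_csco = config.mode in ("sco", "csco")
            old = agent.position.copy()
            if use_csco:
                mu = rng.random() if config.mode == "sco" else chaos
                new_pos = csco_update(agent.position, best_pos, rg, mu, rng,
                                      config.bounds)
            else:
                j = rng.integers(config.pop_size)
                new_pos = roa_update(agent.position, best_pos,
                                     pop[j].position, prev_pos[i], t,
                                     config.t_max,
                                     lambda x: evaluate(x, f"agent {i} (probe)"),
                                     rng, config.bounds)
            agent.position = new_pos
            agent.fitness = evaluate(new_pos, f"agent {i} (iter {t})")
            prev_pos[i] = old
            if agent.fitness < best_fit:
                best_fit = agent.fitness
                best_pos = agent.position.copy()
        replace_worst(pop, best_pos, config.bounds, rng,
                      lambda x: evaluate(x, "replacement agent"))
        for a in pop:
            if a.fitness < best_fit:
                best_fit = a.fitness
                best_pos = a.position.copy()
        trace[t - 1] = best_fit

    return OptResult(best_position=best_pos, best_fitness=best_fit,
                     trace=trace, n_evaluations=n_eval)


# Benchmark objectives used by the CLI and the examples
def sphere(x: np.ndarray) -> float:
    return float(np.sum(np.asarray(x) ** 2))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x)
    return float(10.0 * x.size + np.sum(x ** 2 - 10.0 * np.cos(2 * np.pi * x)))


OBJECTIVES = {"sphere": sphere, "rastrigin": rastrigin}
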