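"""Tri-phase hybrid optimizer for constrained DNA sequence design (TC-HUR).

Candidates are continuous vectors in ``[0, 3]^L`` that are clipped and
rounded (half-up) to quaternary digits before every fitness evaluation; the
continuous vector is optimizer-internal state only.  A run has three phases:

1. **Global exploration** (first ``SR`` fraction of iterations): a
   hunger-driven population search.  Individuals that match the global best
   reset their hunger to zero; the rest accumulate hunger, and the
   normalized hunger sensitivity decides between a self-perturbation move
   and attraction moves toward the best or toward random peers.  A
   heavy-tailed Cauchy jump around the incumbent best — with linearly
   decaying intensity ``beta(t) = beta_start * (1 - t / T_HGS)`` — supplies
   occasional long-range escapes and is accepted greedily.
2. **Elite refinement** (after the switch): the top ``elite_frac`` of the
   population receives Runge-Kutta-style local steps around the best,
   ``x_best + r * f_refine(t) * (x_best - x_rand)``, with exponentially
   shrinking step size ``f_refine(t) = f0 * exp(-decay * t / Tmax)``;
   accepted only on improvement.
3. **Adaptive intensive mutation** (alongside phase 2): a random
   ``mutation_frac`` of the population gets nucleotide-level repair of
   homopolymer runs longer than 3 and of positions matching the reverse
   complement, at a rate ramping linearly from 2% to 5%.

The best-so-far fitness trace is non-increasing by elitist bookkeeping, and
all randomness flows from one seeded generator per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codec import DEFAULT_MAP, EncodingMap, NucleotideSequence
from .fitness import (
    ConstraintConfig,
    FitnessBreakdown,
    FitnessEvaluator,
    FitnessWeights,
    ThermoTable,
    _run_lengths,
)

__all__ = [
    "Individual",
    "TCHURConfig",
    "OptimizerTrace",
    "update_hunger",
    "hunger_sensitivity",
    "convergence_factor",
    "diversity_weight",
    "hgs_step",
    "cauchy_beta",
    "cauchy_jump",
    "refine_coefficient",
    "rk_refine",
    "mutation_rate",
    "targeted_mutation",
    "correct_bounds",
    "optimize",
]

_LOW, _HIGH = 0.0, 3.0


@dataclass(eq=False)
class Individual:
    position: np.ndarray  # continuous, entries in [0, 3]
    hunger: float = 0.0
    fitness: float = np.inf
    digits: np.ndarray | None = None


@dataclass(frozen=True)
class TCHURConfig:
    """All schedule and population parameters of the tri-phase optimizer."""

    N: int = 50
    Tmax: int = 100
    SR: float = 0.5            # switching ratio: phase 1 lasts round(SR * Tmax)
    beta_start: float = 0.015  # initial Cauchy jump intensity
    refine_coeff: float = 0.008
    refine_decay: float = 3.0
    mut_lo: float = 0.02
    mut_hi: float = 0.05
    elite_frac: float = 0.30
    mutation_frac: float = 0.20
    alpha_scale: float = 1.0   # hunger increment = U(0,1] * alpha_scale
    LH: float = 10_000.0       # hunger cap
    PUP: float = 0.08
    w1: float = 1.0
    w2: float = 1.0
    a_range: float = 1.0       # peak amplitude of the R-vector, shrinks linearly
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.SR < 1:
            raise ValueError("SR must lie in (0, 1)")
        if not (0 < self.elite_frac <= 1 and 0 < self.mutation_frac <= 1):
            raise ValueError("elite_frac and mutation_frac must lie in (0, 1]")
        if self.mut_lo >= self.mut_hi:
            raise ValueError("mut_lo must be below mut_hi")
        for name in ("beta_start", "refine_coeff", "refine_decay", "alpha_scale", "LH", "a_range"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.N < 3:
            raise ValueError("population must have at least 3 individuals")
        if self.Tmax < 1:
            raise ValueError("Tmax must be >= 1")

    @property
    def T_hgs(self) -> int:
        return int(round(self.SR * self.Tmax))


@dataclass
class OptimizerTrace:
    best_fitness: np.ndarray
    phases: list[str]
    snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.best_fitness)),
                "best_fitness": self.best_fitness,
                "phase": self.phases,
            }
        )


# ------------------------------------------------------------- schedules


def cauchy_beta(t: int, cfg: TCHURConfig) -> float:
    """Linearly decaying Cauchy intensity: beta_start at t=0, 0 at T_HGS."""
    if not 0 <= t <= cfg.T_hgs:
        raise ValueError("t outside the exploration phase")
    return cfg.beta_start * (1.0 - t / cfg.T_hgs)


def refine_coefficient(t: int, cfg: TCHURConfig) -> float:
    """Exponentially shrinking refinement step size."""
    if not 0 <= t <= cfg.Tmax:
        raise ValueError("t outside the run")
    return cfg.refine_coeff * float(np.exp(-cfg.refine_decay * t / cfg.Tmax))


def mutation_rate(t: float, cfg: TCHURConfig) -> float:
    """Linear ramp mut_lo -> mut_hi over the second half of the run."""
    half = cfg.SR * cfg.Tmax
    if t < half:
        raise ValueError("mutation phase starts at t = SR * Tmax")
    return cfg.mut_lo + (cfg.mut_hi - cfg.mut_lo) * (t - half) / (cfg.Tmax - half)


def diversity_weight(i: int, cfg: TCHURConfig) -> float:
    """Index-dependent exploration weight ``w1 * exp(-(N - i)/N) + w2``."""
    return cfg.w1 * float(np.exp(-(cfg.N - i) / cfg.N)) + cfg.w2


def convergence_factor(fit_i: float, fit_best: float) -> float:
    """sech of the fitness gap: 1 at the best, decaying with distance."""
    d = abs(fit_i - fit_best)
    # sech(d) = 2 e^-d / (1 + e^-2d), stable for large gaps
    e = np.exp(-d)
    return float(2.0 * e / (1.0 + e * e))


# ------------------------------------------------------------- operators


def update_hunger(ind: Individual, best_fitness: float, cfg: TCHURConfig, rng) -> float:
    """Reset hunger at the global best; otherwise accumulate, capped at LH."""
    if ind.fitness == best_fitness:
        ind.hunger = 0.0
    else:
        alpha = (1.0 - rng.random()) * cfg.alpha_scale  # U(0, 1] increment
        ind.hunger = min(ind.hunger + alpha, cfg.LH)
    return ind.hunger


def hunger_sensitivity(hungers: np.ndarray) -> np.ndarray:
    """Normalized hunger shares; uniform when every hunger is zero."""
    hungers = np.asarray(hungers, dtype=float)
    total = hungers.sum()
    if total == 0:
        return np.full(len(hungers), 1.0 / len(hungers))
    return hungers / total


def _r_vector(dim: int, t: int, cfg: TCHURConfig, rng) -> np.ndarray:
    a = cfg.a_range * max(0.0, 1.0 - t / cfg.T_hgs)
    return rng.uniform(-a, a, size=dim)


def hgs_step(
    ind: Individual,
    best: Individual,
    population: list[Individual],
    t: int,
    cfg: TCHURConfig,
    rng,
    sensitivity: float | None = None,
) -> np.ndarray:
    """One hunger-driven position update; returns the new clipped position."""
    if len(population) < 3:
        raise ValueError("hgs_step needs a population of at least 3")
    if sensitivity is None:
        sensitivity = float(
            hunger_sensitivity(np.array([p.hunger for p in population]))[population.index(ind)]
        )
    x = ind.position
    dim = len(x)
    r1, r2 = rng.random(), rng.random()
    if r1 < sensitivity:
        new = x * (1.0 + rng.standard_normal(dim))
    else:
        i = population.index(ind)
        W = diversity_weight(i, cfg)
        R = _r_vector(dim, t, cfg, rng)
        if r2 < convergence_factor(ind.fitness, best.fitness):
            new = best.position + R * W * np.abs(best.position - x)
        else:
            others = [j for j in range(len(population)) if j != i]
            j1, j2 = rng.choice(others, size=2, replace=False)
            new = population[j1].position + R * W * np.abs(
                population[j1].position - population[j2].position
            )
    return np.clip(new, _LOW, _HIGH)


def cauchy_jump(best: Individual, t: int, cfg: TCHURConfig, rng) -> np.ndarray:
    """Heavy-tailed candidate around the best; caller accepts greedily."""
    delta = rng.standard_cauchy(len(best.position))
    cand = best.position + delta * cauchy_beta(t, cfg)
    return np.clip(cand, _LOW, _HIGH)


def rk_refine(
    best: Individual, population: list[Individual], t: int, cfg: TCHURConfig, rng
) -> np.ndarray:
    """One refinement proposal ``x_best + r * f_refine * (x_best - x_rand)``."""
    x_rand = population[rng.integers(len(population))].position
    r = rng.random(len(best.position))
    cand = best.position + r * refine_coefficient(t, cfg) * (best.position - x_rand)
    return np.clip(cand, _LOW, _HIGH)


def _violation_sites(digits: np.ndarray, comp: np.ndarray, hp_limit: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices inside homopolymer runs > hp_limit and RC-matching indices."""
    lengths = _run_lengths(digits)
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    hp_idx = np.concatenate(
        [np.arange(s, s + h) for s, h in zip(starts, lengths) if h > hp_limit]
    ) if np.any(lengths > hp_limit) else np.empty(0, dtype=np.int64)
    rc = comp[digits][::-1]
    rc_idx = np.flatnonzero(digits == rc)
    return hp_idx, rc_idx


def targeted_mutation(
    ind: Individual,
    rate: float,
    constraints: ConstraintConfig,
    rng,
    mapping: EncodingMap = DEFAULT_MAP,
) -> Individual:
    """Nucleotide-level repair of homopolymer and reverse-complement sites.

    Each violating position is rewritten with probability ``rate`` to a base
    that breaks its violation; all other positions are untouched.  The
    continuous position is snapped to the mutated digits.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    digits = ind.digits.copy() if ind.digits is not None else correct_bounds(ind.position)[1]
    b2d = mapping.base_to_digit
    comp = np.array(
        [b2d[{"A": "T", "T": "A", "C": "G", "G": "C"}[mapping.digit_to_base[d]]] for d in range(4)],
        dtype=np.int8,
    )
    hp_idx, rc_idx = _violation_sites(digits, comp, constraints.hp_limit)
    L = len(digits)
    for i in hp_idx:  # left-to-right; avoid run base and both current neighbors
        if rng.random() < rate:
            i = int(i)
            forbidden = {int(digits[i])}
            if i > 0:
                forbidden.add(int(digits[i - 1]))
            if i < L - 1:
                forbidden.add(int(digits[i + 1]))
            allowed = [b for b in range(4) if b not in forbidden]
            digits[i] = allowed[rng.integers(len(allowed))]
    for i in rc_idx:
        if rng.random() < rate:
            i = int(i)
            forbidden = int(comp[digits[L - 1 - i]])
            choice = int(rng.integers(3))
            digits[i] = choice if choice < forbidden else choice + 1
    out = Individual(position=digits.astype(float), digits=digits, hunger=ind.hunger)
    return out


def correct_bounds(position: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clip to [0, 3] and digitize by round-half-up."""
    position = np.asarray(position, dtype=float)
    if np.isnan(position).any():
        raise ValueError("NaN in position vector")
    clipped = np.clip(position, _LOW, _HIGH)
    digits = np.floor(clipped + 0.5).astype(np.int8)
    np.clip(digits, 0, 3, out=digits)
    return clipped, digits


# ------------------------------------------------------------- main loop


def _evaluate(ind: Individual, evaluator: FitnessEvaluator) -> None:
    ind.position, ind.digits = correct_bounds(ind.position)
    ind.fitness = evaluator.evaluate(ind.digits)


def optimize(
    problem: int | NucleotideSequence,
    weights: FitnessWeights = FitnessWeights(),
    constraints: ConstraintConfig = ConstraintConfig(),
    cfg: TCHURConfig = TCHURConfig(),
    thermo: ThermoTable | None = None,
    mapping: EncodingMap = DEFAULT_MAP,
) -> tuple[NucleotideSequence, FitnessBreakdown, OptimizerTrace]:
    """Run the full tri-phase search and return the digitized best solution.

    ``problem`` is either a design length or a payload-bearing sequence; a
    sequence seeds one member of the initial population (the rest are
    uniform random) and fixes the length.
    """
    if isinstance(problem, NucleotideSequence):
        L = len(problem)
        seed_digits = problem.digits
        mapping = problem.mapping
    else:
        L = int(problem)
        seed_digits = None
    if L < 1:
        raise ValueError("design length must be >= 1")
    evaluator = FitnessEvaluator(L, weights, constraints, thermo, mapping)
    rng = np.random.default_rng(cfg.seed)

    pop = [Individual(position=rng.uniform(_LOW, _HIGH, L)) for _ in range(cfg.N)]
    if seed_digits is not None:
        pop[0].position = seed_digits.astype(float)
    for ind in pop:
        _evaluate(ind, evaluator)

    best = min(pop, key=lambda p: p.fitness)
    best = Individual(position=best.position.copy(), digits=best.digits.copy(), fitness=best.fitness)

    trace_f = np.empty(cfg.Tmax)
    phases: list[str] = []
    snapshots: list[tuple[int, np.ndarray]] = []
    T_hgs = cfg.T_hgs
    n_elite = max(1, int(round(cfg.elite_frac * cfg.N)))
    n_mut = max(1, int(round(cfg.mutation_frac * cfg.N)))

    def consider(position: np.ndarray, digits: np.ndarray, fitness: float, t: int) -> None:
        nonlocal best
        if fitness < best.fitness:
            best = Individual(position=position.copy(), digits=digits.copy(), fitness=fitness)
            snapshots.append((t, best.digits.copy()))

    for t in range(cfg.Tmax):
        if t < T_hgs:
            phases.append("hgs")
            for ind in pop:
                update_hunger(ind, best.fitness, cfg, rng)
            sens = hunger_sensitivity(np.array([p.hunger for p in pop]))
            for i, ind in enumerate(pop):
                ind.position = hgs_step(ind, best, pop, t, cfg, rng, sensitivity=float(sens[i]))
                _evaluate(ind, evaluator)
                consider(ind.position, ind.digits, ind.fitness, t)
            # greedy Cauchy jump around the incumbent best
            cand = cauchy_jump(best, t, cfg, rng)
            _, cand_d = correct_bounds(cand)
            cand_f = evaluator.evaluate(cand_d)
            consider(cand, cand_d, cand_f, t)
        else:
            phases.append("refine")
            order = np.argsort([p.fitness for p in pop])
            for j in order[:n_elite]:
                cand = rk_refine(best, pop, t, cfg, rng)
                _, cand_d = correct_bounds(cand)
                cand_f = evaluator.evaluate(cand_d)
                if cand_f < pop[j].fitness:  # greedy acceptance into the elite slot
                    pop[j].position, pop[j].digits, pop[j].fitness = cand, cand_d, cand_f
                consider(cand, cand_d, cand_f, t)
            rate = mutation_rate(t, cfg)
            # surgical repair of the incumbent best, accepted greedily —
            # the phase-3 analogue of the phase-1 Cauchy elite update
            repaired = targeted_mutation(best, rate, constraints, rng, mapping)
            _evaluate(repaired, evaluator)
            consider(repaired.position, repaired.digits, repaired.fitness, t)
            for j in rng.choice(cfg.N, size=n_mut, replace=False):
                mutated = targeted_mutation(pop[j], rate, constraints, rng, mapping)
                _evaluate(mutated, evaluator)
                if mutated.fitness < pop[j].fitness:
                    pop[j] = mutated
                consider(mutated.position, mutated.digits, mutated.fitness, t)
        trace_f[t] = best.fitness

    seq = NucleotideSequence.from_digits(best.digits, mapping)
    breakdown = evaluator.breakdown(best.digits)
    return seq, breakdown, OptimizerTrace(best_fitness=trace_f, phases=phases, snapshots=snapshots)
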