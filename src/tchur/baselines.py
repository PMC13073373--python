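"""Reference population optimizers for head-to-head comparison.

Four canonical algorithms — particle swarm optimization (PSO), grey wolf
optimizer (GWO), hunger games search (HGS) and the Runge-Kutta method (RUN)
— share the sequence-design fitness, the [0, 3] continuous representation,
the round-half-up digitization and the elitist trace bookkeeping of the
tri-phase optimizer, so that any fitness difference reflects the search
dynamics alone.

Parameter defaults: PSO uses the global-best velocity form with constant
inertia (c1 = c2 = 2.05, w = 0.4); GWO decreases its control parameter
linearly from 2 to 0; HGS is the original two-weight hunger model with
update probability 0.08 and hunger cap 10,000; RUN uses the fourth-order
Runge-Kutta search mechanism with the enhanced-solution-quality step
(randomness control a = 20, step-size scaling f = 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codec import DEFAULT_MAP, EncodingMap, NucleotideSequence
from .fitness import (
    ConstraintConfig,
    FitnessBreakdown,
    FitnessEvaluator,
    FitnessWeights,
    ThermoTable,
)
from .optimizer import OptimizerTrace, correct_bounds

__all__ = ["BaselineConfig", "run_baseline", "random_search", "gwo_a", "DEFAULT_PARAMS"]

_LOW, _HIGH = 0.0, 3.0

DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "PSO": {"c1": 2.05, "c2": 2.05, "w": 0.4},
    "GWO": {"a_start": 2.0, "a_end": 0.0},
    "HGS": {"PUP": 0.08, "LH": 10_000.0},
    "RUN": {"a": 20.0, "f": 0.1, "b": 12.0},
}


@dataclass(frozen=True)
class BaselineConfig:
    algorithm: str
    N: int = 50
    Tmax: int = 100
    seed: int = 0
    parameters: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        name = self.algorithm.upper()
        if name not in DEFAULT_PARAMS:
            raise ValueError(f"unknown baseline algorithm {self.algorithm!r}")
        unknown = set(self.parameters) - set(DEFAULT_PARAMS[name])
        if unknown:
            raise ValueError(f"parameters {sorted(unknown)} do not belong to {name}")

    def resolved(self) -> dict[str, float]:
        return {**DEFAULT_PARAMS[self.algorithm.upper()], **self.parameters}


class _Run:
    """Shared population state with elitist trace bookkeeping."""

    def __init__(self, L: int, cfg: BaselineConfig, evaluator: FitnessEvaluator,
                 seed_digits: np.ndarray | None):
        self.evaluator = evaluator
        self.rng = np.random.default_rng(cfg.seed)
        self.X = self.rng.uniform(_LOW, _HIGH, size=(cfg.N, L))
        if seed_digits is not None:
            self.X[0] = seed_digits.astype(float)
        self.F = np.empty(cfg.N)
        self.D = np.empty((cfg.N, L), dtype=np.int8)
        for i in range(cfg.N):
            self._eval(i)
        b = int(np.argmin(self.F))
        self.best_x = self.X[b].copy()
        self.best_d = self.D[b].copy()
        self.best_f = float(self.F[b])
        self.trace: list[float] = []
        self.snapshots: list[tuple[int, np.ndarray]] = []

    def _eval(self, i: int) -> None:
        self.X[i], self.D[i] = correct_bounds(self.X[i])
        self.F[i] = self.evaluator.evaluate(self.D[i])

    def sync_best(self, t: int) -> None:
        b = int(np.argmin(self.F))
        if self.F[b] < self.best_f:
            self.best_x = self.X[b].copy()
            self.best_d = self.D[b].copy()
            self.best_f = float(self.F[b])
            self.snapshots.append((t, self.best_d.copy()))
        self.trace.append(self.best_f)


def run_baseline(
    cfg: BaselineConfig,
    problem: int | NucleotideSequence,
    weights: FitnessWeights = FitnessWeights(),
    constraints: ConstraintConfig = ConstraintConfig(),
    thermo: ThermoTable | None = None,
    mapping: EncodingMap = DEFAULT_MAP,
) -> tuple[NucleotideSequence, FitnessBreakdown, OptimizerTrace]:
    """Run one baseline with the same output contract as the tri-phase search."""
    if isinstance(problem, NucleotideSequence):
        L, seed_digits, mapping = len(problem), problem.digits, problem.mapping
    else:
        L, seed_digits = int(problem), None
    evaluator = FitnessEvaluator(L, weights, constraints, thermo, mapping)
    state = _Run(L, cfg, evaluator, seed_digits)
    params = cfg.resolved()
    step = {"PSO": _pso_step, "GWO": _gwo_step, "HGS": _hgs_step, "RUN": _run_step}[
        cfg.algorithm.upper()
    ]
    ctx: dict = {}
    for t in range(cfg.Tmax):
        step(state, t, cfg, params, ctx)
        state.sync_best(t)
    seq = NucleotideSequence.from_digits(state.best_d, mapping)
    trace = OptimizerTrace(
        best_fitness=np.array(state.trace),
        phases=[cfg.algorithm.lower()] * cfg.Tmax,
        snapshots=state.snapshots,
    )
    return seq, evaluator.breakdown(state.best_d), trace


def random_search(
    problem: int | NucleotideSequence,
    n_evals: int,
    seed: int,
    weights: FitnessWeights = FitnessWeights(),
    constraints: ConstraintConfig = ConstraintConfig(),
    thermo: ThermoTable | None = None,
    mapping: EncodingMap = DEFAULT_MAP,
) -> tuple[NucleotideSequence, float]:
    """Uniform random sampling at an equal evaluation budget (sanity floor)."""
    if isinstance(problem, NucleotideSequence):
        L, mapping = len(problem), problem.mapping
    else:
        L = int(problem)
    evaluator = FitnessEvaluator(L, weights, constraints, thermo, mapping)
    rng = np.random.default_rng(seed)
    best_d, best_f = None, np.inf
    for _ in range(n_evals):
        _, d = correct_bounds(rng.uniform(_LOW, _HIGH, L))
        f = evaluator.evaluate(d)
        if f < best_f:
            best_d, best_f = d, f
    return NucleotideSequence.from_digits(best_d, mapping), float(best_f)


# ----------------------------------------------------------- algorithms


def _pso_step(s: _Run, t: int, cfg: BaselineConfig, p: dict, ctx: dict) -> None:
    N, L = s.X.shape
    if "V" not in ctx:
        ctx["V"] = np.zeros((N, L))
        ctx["pbest_x"] = s.X.copy()
        ctx["pbest_f"] = s.F.copy()
    V, px, pf = ctx["V"], ctx["pbest_x"], ctx["pbest_f"]
    r1 = s.rng.random((N, L))
    r2 = s.rng.random((N, L))
    V[:] = p["w"] * V + p["c1"] * r1 * (px - s.X) + p["c2"] * r2 * (s.best_x - s.X)
    s.X += V
    for i in range(N):
        s._eval(i)
        if s.F[i] < pf[i]:
            pf[i], px[i] = s.F[i], s.X[i]


def gwo_a(t: int, Tmax: int, a_start: float = 2.0, a_end: float = 0.0) -> float:
    """Linearly decreasing GWO control parameter: a_start at t=0, a_end at the last iteration."""
    return a_start + (a_end - a_start) * t / max(1, Tmax - 1)


def _gwo_step(s: _Run, t: int, cfg: BaselineConfig, p: dict, ctx: dict) -> None:
    N, L = s.X.shape
    a = gwo_a(t, cfg.Tmax, p["a_start"], p["a_end"])
    order = np.argsort(s.F)
    leaders = s.X[order[: min(3, N)]]
    while len(leaders) < 3:  # degenerate tiny populations reuse the alpha
        leaders = np.vstack([leaders, leaders[0]])
    new = np.empty_like(s.X)
    for i in range(N):
        acc = np.zeros(L)
        for leader in leaders:
            A = 2.0 * a * s.rng.random(L) - a
            C = 2.0 * s.rng.random(L)
            acc += leader - A * np.abs(C * leader - s.X[i])
        new[i] = acc / 3.0
    s.X[:] = new
    for i in range(N):
        s._eval(i)


def _hgs_step(s: _Run, t: int, cfg: BaselineConfig, p: dict, ctx: dict) -> None:
    """Original two-weight hunger model (shrinking-amplitude attraction)."""
    N, L = s.X.shape
    if "H" not in ctx:
        ctx["H"] = np.zeros(N)
    H = ctx["H"]
    worst = float(s.F.max())
    best = s.best_f
    span = max(worst - best, 1e-12)
    for i in range(N):
        if s.F[i] <= best:
            H[i] = 0.0
        else:
            th = (s.F[i] - best) / span * s.rng.random() * 2.0 * (_HIGH - _LOW)
            H[i] = min(H[i] + (p["LH"] * (1 + s.rng.random()) if th < p["LH"] else th), p["LH"] * 10)
    sumH = max(H.sum(), 1e-12)
    shrink = 2.0 * (1.0 - t / cfg.Tmax)
    for i in range(N):
        if s.rng.random() < p["PUP"]:
            s.X[i] = s.X[i] * (1.0 + s.rng.standard_normal(L))
        else:
            W1 = H[i] * N / sumH * s.rng.random() if s.rng.random() < p["PUP"] else 1.0
            W2 = (1.0 - np.exp(-abs(H[i] - sumH))) * s.rng.random() * 2.0
            R = 2.0 * shrink * s.rng.random(L) - shrink
            e = np.exp(-abs(s.F[i] - best))
            E = 2.0 * e / (1.0 + e * e)
            if s.rng.random() > E:
                s.X[i] = W1 * s.best_x + R * W2 * np.abs(s.best_x - s.X[i])
            else:
                s.X[i] = W1 * s.best_x - R * W2 * np.abs(s.best_x - s.X[i])
        s._eval(i)


def _run_step(s: _Run, t: int, cfg: BaselineConfig, p: dict, ctx: dict) -> None:
    """Runge-Kutta search mechanism with the enhanced-solution-quality step."""
    N, L = s.X.shape
    rng = s.rng
    span = _HIGH - _LOW
    for i in range(N):
        pool = [j for j in range(N) if j != i]
        if len(pool) >= 3:
            r1, r2, r3 = rng.choice(pool, size=3, replace=False)
        else:  # degenerate tiny populations sample with replacement
            r1, r2, r3 = rng.integers(0, N, size=3)
        # better/worse of the pair (x_i, x_r1) anchor the RK slope estimates
        if s.F[i] < s.F[r1]:
            xb, xw = s.X[i], s.X[r1]
        else:
            xb, xw = s.X[r1], s.X[i]
        gamma = rng.random(L) * (s.X[i] - rng.random(L) * span) * np.exp(-4.0 * t / cfg.Tmax)
        stp = rng.random(L) * ((xb - rng.random(L) * s.X[[r1, r2, r3]].mean(axis=0)) + gamma)
        dx = 2.0 * rng.random(L) * np.abs(stp) + 1e-12
        u = np.round(1.0 + rng.random()) * (1.0 - rng.random())
        k1 = (rng.random(L) * xw - u * xb) / (2.0 * dx)
        k2 = (rng.random(L) * (xw + rng.random(L) * k1 * dx) - (u * xb + rng.random(L) * k1 * dx)) / (2.0 * dx)
        k3 = (rng.random(L) * (xw + rng.random(L) * k2 * dx / 2) - (u * xb + rng.random(L) * k2 * dx / 2)) / (2.0 * dx)
        k4 = (rng.random(L) * (xw + rng.random(L) * k3 * dx) - (u * xb + rng.random(L) * k3 * dx)) / (2.0 * dx)
        sm = (dx / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        sf = 2.0 * (0.5 - rng.random()) * p["f"] * p["a"] * np.exp(-p["b"] * rng.random() * t / cfg.Tmax)
        phi = rng.random()
        xc = phi * s.X[i] + (1 - phi) * s.X[r1]
        xm = phi * s.best_x + (1 - phi) * s.X[int(np.argmin(s.F))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if rng.random() < 0.5:
            new = xc + sf * sm + rng.standard_normal(L) * 0.1 * (xm - xc)
        else:
            new = xm + sf * sm + rng.standard_normal(L) * 0.1 * (s.X[r1] - s.X[r2])
        cand_x, cand_d = correct_bounds(new)
        cand_f = s.evaluator.evaluate(cand_d)
        if cand_f < s.F[i]:
            s.X[i], s.D[i], s.F[i] = cand_x, cand_d, cand_f
        # enhanced solution quality: blend of three peers and the best
        if rng.random() < 0.5:
            beta = rng.random()
            w = rng.uniform(0, 2) * np.exp(-5.0 * rng.random() * t / cfg.Tmax)
            x_avg = s.X[[r1, r2, r3]].mean(axis=0)
            x_new1 = beta * x_avg + (1 - beta) * s.best_x
            if w < 1:
                cand = x_new1 + sign * w * np.abs(x_new1 - x_avg + rng.standard_normal(L))
            else:
                cand = (x_new1 - x_avg) + sign * w * np.abs(u * x_new1 - x_avg)
            cand_x, cand_d = correct_bounds(cand)
            cand_f = s.evaluator.evaluate(cand_d)
            if cand_f < s.F[i]:
                s.X[i], s.D[i], s.F[i] = cand_x, cand_d, cand_f
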