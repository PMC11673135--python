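"""GA phase, constriction-factor PSO and the hybrid GA-CPSO driver.

The optimisation variable is the rigid-transform triple (tx, ty, theta),
searched inside a :class:`SearchBounds` box against a caller-supplied scalar
cost (for registration: the MSE between the fixed image and the warped
moving image).

The hybrid runs a real-coded genetic algorithm as a coarse global search and
hands its best chromosome to a constriction-factor particle swarm for fine
refinement.  The constriction factor chi = 2 / |2 - phi - sqrt(phi^2 - 4 phi)|
(phi = c1 + c2 > 4) damps the velocity update; the "squared" variant applies
chi^2 instead, contracting the swarm harder and reaching its final best in
fewer iterations.

All randomness flows from the ``rng_seed`` fields of the config dataclasses,
so a (config, seed) pair reproduces a run bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .imaging import RigidTransform

__all__ = [
    "SearchBounds",
    "GAConfig",
    "CPSOConfig",
    "OptimizerTrace",
    "SwarmResult",
    "HybridResult",
    "constriction_factor",
    "ga_phase",
    "cpso_phase",
    "ga_cpso",
]


@dataclass(frozen=True)
class SearchBounds:
    """Per-parameter search intervals for (tx, ty, theta)."""

    tx: tuple[float, float] = (-100.0, 100.0)
    ty: tuple[float, float] = (-100.0, 100.0)
    theta: tuple[float, float] = (-20.0, 20.0)

    def __post_init__(self) -> None:
        for name in ("tx", "ty", "theta"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.tx[0], self.ty[0], self.theta[0]], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.tx[1], self.ty[1], self.theta[1]], dtype=float)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, p: RigidTransform) -> bool:
        x = p.as_array()
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm phase parameters.

    Defaults follow the coarse-search recipe: 50 real-coded chromosomes,
    roulette-wheel selection, one-point crossover with probability 0.8,
    per-gene Gaussian mutation with probability 0.05, 50 generations.
    ``mutation_sigma_frac`` scales the mutation noise as a fraction of each
    parameter's bound width.
    """

    population_size: int = 50
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    mutation_sigma_frac: float = 0.02
    elitism: bool = True
    stall_generations: int = 10
    stall_rel_tol: float = 1e-8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass(frozen=True)
class CPSOConfig:
    """Constriction-factor PSO parameters.

    ``factor_mode`` selects the conventional factor chi ("conventional")
    or its square ("squared", the fast-converging variant).  c1 + c2 must
    exceed 4 for the factor to be defined; the canonical setting
    c1 = c2 = 2.05 gives chi ~= 0.7298.  Inertia decays linearly from
    ``w_max`` to ``w_min`` over the run.  Velocities are capped at
    ``velocity_limit_frac`` of each bound width per step.
    """

    swarm_size: int = 30
    max_iterations: int = 100
    c1: float = 2.05
    c2: float = 2.05
    w_max: float = 0.9
    w_min: float = 0.4
    factor_mode: str = "squared"
    velocity_limit_frac: float = 0.2
    init_jitter_frac: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.c1 + self.c2 <= 4.0:
            raise ValueError("constriction requires c1 + c2 > 4")
        if self.factor_mode not in ("conventional", "squared"):
            raise ValueError(f"unknown factor_mode {self.factor_mode!r}")
        if not self.w_min < self.w_max:
            raise ValueError("need w_min < w_max")
        if self.swarm_size < 2 or self.max_iterations < 1:
            raise ValueError("swarm_size >= 2 and max_iterations >= 1 required")


@dataclass
class OptimizerTrace:
    """Per-iteration best-cost record of one optimisation phase."""

    best_costs: np.ndarray  # non-increasing, one entry per iteration (incl. init)
    label: str = ""

    @property
    def final_cost(self) -> float:
        return float(self.best_costs[-1])

    @property
    def first_attainment(self) -> int:
        """Index of the first iteration whose best equals the final best."""
        return int(np.argmax(self.best_costs <= self.best_costs[-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iteration": np.arange(len(self.best_costs)), "best_cost": self.best_costs}
        )


@dataclass
class SwarmResult:
    """Outcome of a single optimisation phase."""

    position: RigidTransform
    cost: float
    trace: OptimizerTrace


@dataclass
class HybridResult:
    """Outcome of the GA -> CPSO hybrid, with both phase traces."""

    position: RigidTransform
    cost: float
    ga: SwarmResult
    cpso: SwarmResult

    @property
    def trace(self) -> OptimizerTrace:
        return OptimizerTrace(
            np.concatenate([self.ga.trace.best_costs, self.cpso.trace.best_costs]),
            label="ga+cpso",
        )


def constriction_factor(c1: float, c2: float, mode: str = "conventional") -> float:
    """Velocity constriction factor chi (or chi^2 for mode='squared').

    chi = 2 / |2 - phi - sqrt(phi^2 - 4 phi)| with phi = c1 + c2, valid for
    phi > 4.  For the canonical c1 = c2 = 2.05, chi ~= 0.7298 and
    chi^2 ~= 0.5327.
    """
    phi = c1 + c2
    if phi <= 4.0:
        raise ValueError(f"constriction factor undefined for phi = c1 + c2 = {phi} <= 4")
    chi = 2.0 / abs(2.0 - phi - math.sqrt(phi * phi - 4.0 * phi))
    if mode == "conventional":
        return chi
    if mode == "squared":
        return chi * chi
    raise ValueError(f"unknown mode {mode!r}")


def _eval_population(cost, positions: np.ndarray) -> np.ndarray:
    out = np.empty(len(positions))
    for i, row in enumerate(positions):
        c = float(cost(RigidTransform.from_array(row)))
        if not np.isfinite(c):
            raise ValueError(f"non-finite cost {c} at {row}")
        out[i] = c
    return out


def ga_phase(cost, bounds: SearchBounds, cfg: GAConfig) -> SwarmResult:
    """Real-coded GA minimising ``cost`` over the bounds box.

    Roulette-wheel selection acts on the fitness transform
    ``1 / (1 + (cost - min_cost) / median_spread)`` (scale-free inverted
    cost); crossover cuts the 3-gene chromosome at a
    random interior point; mutation adds per-gene Gaussian noise scaled to the
    bound width.  The incumbent best is carried unmodified into each new
    generation (elitism), which makes the best-cost trace non-increasing.
    Stops early when the best cost has stalled for ``stall_generations``
    generations.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    lower, upper, width = bounds.lower, bounds.upper, bounds.width
    pop = rng.uniform(lower, upper, size=(cfg.population_size, 3))
    costs = _eval_population(cost, pop)

    best_idx = int(np.argmin(costs))
    best_x = pop[best_idx].copy()
    best_c = float(costs[best_idx])
    trace = [best_c]
    stall = 0

    sigma = cfg.mutation_sigma_frac * width
    for _gen in range(cfg.generations):
        # roulette selection on inverted-cost fitness; the cost spread is
        # normalised by its population median so selection pressure does not
        # depend on the cost scale (raw 1/(1+cost-min) collapses diversity
        # prematurely when costs span hundreds of units)
        spread = costs - costs.min()
        fitness = 1.0 / (1.0 + spread / (np.median(spread) + 1e-12))
        probs = fitness / fitness.sum()
        parents = pop[rng.choice(cfg.population_size, size=cfg.population_size, p=probs)]

        # one-point crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, cfg.population_size - 1, 2):
            if rng.random() < cfg.crossover_prob:
                cut = int(rng.integers(1, 3))  # cut after gene 1 or 2
                children[i, cut:], children[i + 1, cut:] = (
                    parents[i + 1, cut:].copy(),
                    parents[i, cut:].copy(),
                )

        # Gaussian mutation, per gene
        mut_mask = rng.random(children.shape) < cfg.mutation_prob
        noise = rng.normal(0.0, 1.0, size=children.shape) * sigma
        children = np.where(mut_mask, children + noise, children)
        children = bounds.clip(children)

        if cfg.elitism:
            children[0] = best_x  # incumbent survives unmodified

        pop = children
        costs = _eval_population(cost, pop)
        gen_best = int(np.argmin(costs))
        if costs[gen_best] < best_c:
            improvement = best_c - costs[gen_best]
            stall = 0 if improvement > cfg.stall_rel_tol * max(abs(best_c), 1e-12) else stall + 1
            best_c = float(costs[gen_best])
            best_x = pop[gen_best].copy()
        else:
            stall += 1
        trace.append(best_c)
        if stall >= cfg.stall_generations:
            break

    return SwarmResult(
        RigidTransform.from_array(best_x), best_c, OptimizerTrace(np.array(trace), label="ga")
    )


def cpso_phase(
    cost,
    bounds: SearchBounds,
    cfg: CPSOConfig,
    init_center: RigidTransform | None = None,
) -> SwarmResult:
    """Constriction-factor PSO minimising ``cost``.

    With ``init_center`` given (the GA hand-off), one particle starts exactly
    there and the rest are Gaussian-jittered around it; with ``init_center``
    None the swarm initialises uniformly inside the bounds (the stand-alone
    CPSO baseline).  Velocity update:
    ``v <- chi * [w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)]`` with
    per-dimension uniform r1, r2, linear inertia decay, velocity capping and
    position clipping to the bounds.
    """
    if init_center is not None and not bounds.contains(init_center):
        raise ValueError("init_center lies outside the search bounds")
    rng = np.random.default_rng(cfg.rng_seed)
    lower, upper, width = bounds.lower, bounds.upper, bounds.width
    chi = constriction_factor(cfg.c1, cfg.c2, cfg.factor_mode)
    vmax = cfg.velocity_limit_frac * width

    if init_center is None:
        x = rng.uniform(lower, upper, size=(cfg.swarm_size, 3))
    else:
        center = init_center.as_array()
        x = center + rng.normal(0.0, 1.0, size=(cfg.swarm_size, 3)) * (
            cfg.init_jitter_frac * width
        )
        x[0] = center  # one particle exactly at the hand-off point
        x = bounds.clip(x)
    v = np.zeros_like(x)

    costs = _eval_population(cost, x)
    pbest_x = x.copy()
    pbest_c = costs.copy()
    g = int(np.argmin(pbest_c))
    gbest_x = pbest_x[g].copy()
    gbest_c = float(pbest_c[g])
    trace = [gbest_c]

    T = cfg.max_iterations
    for it in range(T):
        w = cfg.w_max + (cfg.w_min - cfg.w_max) * (it / max(T - 1, 1))
        r1 = rng.random(x.shape)
        r2 = rng.random(x.shape)
        v = chi * (w * v + cfg.c1 * r1 * (pbest_x - x) + cfg.c2 * r2 * (gbest_x - x))
        v = np.clip(v, -vmax, vmax)
        x = bounds.clip(x + v)
        costs = _eval_population(cost, x)
        improved = costs < pbest_c  # strict: ties keep the earlier incumbent
        pbest_x[improved] = x[improved]
        pbest_c[improved] = costs[improved]
        g = int(np.argmin(pbest_c))
        if pbest_c[g] < gbest_c:
            gbest_c = float(pbest_c[g])
            gbest_x = pbest_x[g].copy()
        trace.append(gbest_c)

    return SwarmResult(
        RigidTransform.from_array(gbest_x),
        gbest_c,
        OptimizerTrace(np.array(trace), label=f"cpso-{cfg.factor_mode}"),
    )


def ga_cpso(cost, bounds: SearchBounds, ga_cfg: GAConfig, cpso_cfg: CPSOConfig) -> HybridResult:
    """Hybrid driver: GA coarse search, then CPSO seeded at the GA best.

    Because one particle starts exactly at the GA best, the hybrid's final
    cost never exceeds the GA phase's.
    """
    ga = ga_phase(cost, bounds, ga_cfg)
    cpso = cpso_phase(cost, bounds, cpso_cfg, init_center=ga.position)
    if cpso.cost <= ga.cost:
        best, best_c = cpso.position, cpso.cost
    else:  # cannot happen with the seeded particle, kept as a guard
        best, best_c = ga.position, ga.cost
    return HybridResult(best, best_c, ga=ga, cpso=cpso)


def derive_seeded(cfg, seed: int):
    """Copy a config with a new rng_seed (convenience for seed sweeps)."""
    return replace(cfg, rng_seed=int(seed))
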