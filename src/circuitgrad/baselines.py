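"""Comparison algorithms sharing the circuit model and cost: an
evolutionary algorithm (truncation selection + Gaussian mutation) and a
comprehensive random parameter screen (running minimum over i.i.d. draws).

Both report a best-so-far cost trace indexed by cumulative cost-function
evaluations, the common currency for comparing them against gradient
training (one gradient iteration is counted as a configurable number of
evaluations, default 2: one forward pass plus one backward sweep of
comparable expense).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuits import GeneCircuit
from .objectives import CostSpec
from .optimizers import AdamConfig
from .solver import SolverConfig, _forward, _stack_inputs
from .tasks import TrainingSet
from .training import TrainConfig, train

GRAD_ITER_EVALS = 2


@dataclass
class EvoConfig:
    population: int = 20
    mutation_scale: float = 0.1
    selection_fraction: float = 0.25
    generations: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 < self.selection_fraction < 1:
            raise ValueError("selection_fraction must lie in (0, 1)")
        if self.mutation_scale < 0:
            raise ValueError("mutation_scale must be >= 0")


@dataclass
class ScreenConfig:
    n_samples: int = 1000
    w_scale: float = 1.0  # std of the Normal(0, w_scale) weight draws
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _evaluate(circuit: GeneCircuit, W: np.ndarray, I_full, times, rec,
              solver_cfg, cost) -> float:
    c = circuit.copy()
    c.W = W
    Y = _forward(c, I_full, solver_cfg)
    return float(cost.value(times, Y[rec], c))


def _task_setup(circuit, training_set: TrainingSet, cost_spec: CostSpec,
                solver_cfg: SolverConfig):
    signals = training_set.signals()
    trajectory_mode = training_set.target_mode == "trajectory"
    cost = cost_spec.build(None if trajectory_mode else training_set.targets())
    I_full = _stack_inputs(circuit, signals, solver_cfg)
    rec = solver_cfg.recorded_indices()
    return cost, I_full, rec, rec * solver_cfg.dt


def evolve(
    training_set: TrainingSet,
    template: GeneCircuit,
    config: EvoConfig,
    cost_spec: CostSpec | None = None,
    solver_cfg: SolverConfig | None = None,
) -> tuple[GeneCircuit, np.ndarray]:
    """Evolve the interaction weights of a population of circuits.

    Truncation selection keeps the lowest-cost fraction each generation and
    refills by mutating random survivors with additive Gaussian noise.
    Returns the best circuit and the best-so-far cost per evaluation.
    """
    cost_spec = cost_spec or CostSpec(learn_scale=False)
    solver_cfg = solver_cfg or SolverConfig(duration=training_set.duration)
    cost, I_full, rec, times = _task_setup(template, training_set, cost_spec, solver_cfg)
    rng = np.random.default_rng(config.seed)
    N = template.n_nodes

    pop = [rng.normal(0.0, 0.1, size=(N, N)) for _ in range(config.population)]
    if template.variant == "hill_product":
        pop = [np.abs(W) for W in pop]
    trace: list[float] = []
    best = np.inf
    best_W = pop[0]
    n_keep = max(1, int(round(config.selection_fraction * config.population)))

    for _gen in range(config.generations):
        costs = []
        for W in pop:
            c = _evaluate(template, W, I_full, times, rec, solver_cfg, cost)
            costs.append(c)
            if c < best:
                best, best_W = c, W.copy()
            trace.append(best)
        keep_idx = np.argsort(costs)[:n_keep]
        survivors = [pop[i] for i in keep_idx]
        pop = list(survivors)
        while len(pop) < config.population:
            parent = survivors[rng.integers(len(survivors))]
            child = parent + rng.normal(0.0, config.mutation_scale, size=(N, N))
            if template.variant == "hill_product":
                child = np.abs(child)
            pop.append(child)

    out = template.copy()
    out.W = best_W
    return out, np.asarray(trace)


def random_screen(
    training_set: TrainingSet,
    template: GeneCircuit,
    config: ScreenConfig,
    cost_spec: CostSpec | None = None,
    solver_cfg: SolverConfig | None = None,
) -> tuple[GeneCircuit, np.ndarray]:
    """Comprehensive random screen: i.i.d. weight draws, running minimum."""
    cost_spec = cost_spec or CostSpec(learn_scale=False)
    solver_cfg = solver_cfg or SolverConfig(duration=training_set.duration)
    cost, I_full, rec, times = _task_setup(template, training_set, cost_spec, solver_cfg)
    rng = np.random.default_rng(config.seed)
    N = template.n_nodes

    best = np.inf
    best_W = None
    trace = np.empty(config.n_samples)
    for s in range(config.n_samples):
        W = rng.normal(0.0, config.w_scale, size=(N, N))
        if template.variant == "hill_product":
            W = np.abs(W)
        c = _evaluate(template, W, I_full, times, rec, solver_cfg, cost)
        if c < best:
            best, best_W = c, W
        trace[s] = best

    out = template.copy()
    out.W = best_W
    return out, trace


def compare(
    training_set: TrainingSet,
    template: GeneCircuit,
    methods=("gradient", "evolutionary", "screen"),
    budget: int = 400,
    n_repeats: int = 10,
    seed: int = 0,
    cost_spec: CostSpec | None = None,
    solver_cfg: SolverConfig | None = None,
    grad_iter_evals: int = GRAD_ITER_EVALS,
) -> pd.DataFrame:
    """Mean +/- sd best-so-far cost versus cost evaluations per method.

    All methods optimise the identical cost on the identical model under an
    equal evaluation budget.  Returns a tidy frame with columns
    method, evaluations, mean_cost, sd_cost.
    """
    known = {"gradient", "evolutionary", "screen"}
    bad = set(methods) - known
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")
    cost_spec = cost_spec or CostSpec(learn_scale=False)
    solver_cfg = solver_cfg or SolverConfig(duration=training_set.duration)
    rows = []
    evals_axis = np.arange(1, budget + 1)
    for method in methods:
        traces = np.full((n_repeats, budget), np.nan)
        for r in range(n_repeats):
            method_tag = ("gradient", "evolutionary", "screen").index(method)
            run_seed = int((seed * 1_000_003 + r * 7919 + method_tag * 101) % 2**31)
            if method == "gradient":
                circ = template.copy()
                n_iter = budget // grad_iter_evals
                cfg = TrainConfig(n_iterations=n_iter, seed=run_seed,
                                  cost=cost_spec, solver=solver_cfg)
                _, trace = train(circ, training_set, cfg, AdamConfig())
                best = np.minimum.accumulate(trace.data)
                per_eval = np.repeat(best, grad_iter_evals)[:budget]
            elif method == "evolutionary":
                evo = EvoConfig(seed=run_seed)
                gens = max(1, budget // evo.population)
                evo.generations = gens
                _, trace = evolve(training_set, template, evo, cost_spec, solver_cfg)
                per_eval = trace[:budget]
            else:
                scr = ScreenConfig(n_samples=budget, seed=run_seed)
                _, trace = random_screen(training_set, template, scr,
                                         cost_spec, solver_cfg)
                per_eval = trace[:budget]
            n = len(per_eval)
            traces[r, :n] = per_eval
            if n < budget:  # method exhausted its budget early; carry forward
                traces[r, n:] = per_eval[-1]
        rows.append(pd.DataFrame({
            "method": method,
            "evaluations": evals_axis,
            "mean_cost": traces.mean(axis=0),
            "sd_cost": traces.std(axis=0, ddof=1) if n_repeats > 1 else 0.0,
        }))
    return pd.concat(rows, ignore_index=True)
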