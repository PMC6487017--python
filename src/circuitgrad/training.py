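"""End-to-end circuit design: initialise, batch-train, regularise, prune.

The pipeline mirrors how one designs a circuit in practice: draw a random
fully connected network, fit its weights by stochastic mini-batch gradient
descent (Adam by default) through the differentiable Euler solver, then
simplify — re-train under increasing L1 pressure, zero the sub-threshold
weights, and re-fit the survivors with the penalty removed.  Every stage is
a pure function of its configuration and seed.

The per-iteration trace records the *full-data* cost (not the noisy batch
cost), which is what the iterations-to-cost scalability metric N(C) is
measured on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .circuits import GeneCircuit
from .objectives import CostSpec
from .optimizers import AdamConfig, AdamState, adam_step, gd_step
from .solver import SolverConfig, _backward, _forward, _stack_inputs
from .tasks import TrainingSet

log = logging.getLogger("circuitgrad.training")


@dataclass
class GDConfig:
    """Classic constant-learning-rate gradient descent."""

    lr: float = 0.1

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass
class TrainConfig:
    """Everything one training stage needs besides the task itself."""

    n_iterations: int = 2000
    batch_size: int | None = None  # default: min(16, n_cases)
    seed: int = 0
    learn_k: bool | None = None    # None -> follow the task's metadata
    learn_y0: bool | None = None
    cost: CostSpec = field(default_factory=CostSpec)
    solver: SolverConfig = field(default_factory=SolverConfig)
    prune_eps: float = 0.1
    lambda_sweep: tuple = ()
    stop_cost: float | None = None  # stop once full-data cost falls below
    w_mask: np.ndarray | None = None  # frozen-zero weight mask (pruning)

    def __post_init__(self):
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.prune_eps < 0:
            raise ValueError("prune_eps must be >= 0")


@dataclass
class CostTrace:
    """Per-iteration full-data cost, with and without the L1 penalty."""

    total: np.ndarray
    data: np.ndarray

    def __len__(self) -> int:
        return len(self.total)

    def final(self) -> float:
        return float(self.data[-1]) if len(self.data) else float("nan")


def initialize(
    n_nodes: int,
    seed: int,
    variant: str = "additive",
    k_on_decay_only: bool = False,
    input_nodes: tuple[int, ...] = (0,),
    output_node: int = -1,
) -> GeneCircuit:
    """Random starting circuit: k = 1, y0 = 0.1, W ~ Normal(0, 0.1).

    The Hill variant takes |W| so repressor strengths start non-negative;
    the dimer variant starts with gamma = 0 so the dimer channel is learned
    from scratch.
    """
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, 0.1, size=(n_nodes, n_nodes))
    if variant == "hill_product":
        W = np.abs(W)
    gamma = np.zeros((n_nodes, n_nodes)) if variant == "dimer_decay" else None
    return GeneCircuit(
        n_nodes=n_nodes,
        W=W,
        k=np.ones(n_nodes),
        y0=np.full(n_nodes, 0.1),
        gamma=gamma,
        variant=variant,
        k_on_decay_only=k_on_decay_only,
        input_nodes=input_nodes,
        output_node=output_node,
    )


def _resolve_learnables(circuit: GeneCircuit, training_set: TrainingSet,
                        config: TrainConfig) -> None:
    meta = training_set.metadata
    learn_k = config.learn_k if config.learn_k is not None else bool(meta.get("learn_k"))
    learn_y0 = (config.learn_y0 if config.learn_y0 is not None
                else bool(meta.get("learn_y0")))
    learn_A = config.cost.learn_scale and training_set.target_mode == "endpoint"
    circuit.learnable.update(
        {"W": True, "k": learn_k, "y0": learn_y0, "A": learn_A,
         "gamma": circuit.variant == "dimer_decay"}
    )


def train(
    circuit: GeneCircuit,
    training_set: TrainingSet,
    config: TrainConfig,
    optimizer: AdamConfig | GDConfig | None = None,
) -> tuple[GeneCircuit, CostTrace]:
    """Stochastic mini-batch training of one circuit on one task.

    Each iteration draws a batch of B cases without replacement (reshuffling
    once the pool is exhausted), computes the exact adjoint gradient of the
    batch cost plus the L1 subgradient, applies one optimizer step, and logs
    the full-data cost.  Fully reproducible per (circuit, config, seed).
    """
    if optimizer is None:
        optimizer = AdamConfig()
    circuit = circuit.copy()
    _resolve_learnables(circuit, training_set, config)

    signals = training_set.signals()
    n_cases = len(signals)
    B = config.batch_size if config.batch_size else min(16, n_cases)
    B = min(B, n_cases)
    solver_cfg = config.solver
    spec = config.cost
    trajectory_mode = training_set.target_mode == "trajectory"
    if trajectory_mode and spec.kind != "trajectory_mse":
        spec = replace(spec, kind="trajectory_mse",
                       A_osc=training_set.metadata.get("A_osc", spec.A_osc),
                       omega=training_set.metadata.get("omega", spec.omega))
    targets = training_set.targets()
    full_cost = spec.build(None if trajectory_mode else targets)

    I_full = _stack_inputs(circuit, signals, solver_cfg)
    rec = solver_cfg.recorded_indices()
    times = rec * solver_cfg.dt

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n_cases)
    cursor = 0

    params = circuit.learnable_params()
    adam_state = AdamState.for_params(params) if isinstance(optimizer, AdamConfig) else None

    if config.w_mask is not None:
        circuit.W = circuit.W * config.w_mask

    total_trace: list[float] = []
    data_trace: list[float] = []

    for it in range(config.n_iterations):
        if cursor + B > n_cases:
            order = rng.permutation(n_cases)
            cursor = 0
        idx = order[cursor:cursor + B]
        cursor += B

        I_batch = np.ascontiguousarray(I_full[:, idx, :])
        Y = _forward(circuit, I_batch, solver_cfg)
        batch_cost = full_cost if trajectory_mode else spec.build(targets[idx])
        dYrec, direct = batch_cost.state_grad(times, Y[rec], circuit)
        G = np.zeros_like(Y)
        G[rec] = dYrec
        raw = _backward(circuit, Y, I_batch, solver_cfg, G)

        params = circuit.learnable_params()
        grads = {}
        pen = spec.penalty_grads(circuit)
        for name in params:
            if name == "A":
                grads["A"] = float(direct.get("A", 0.0))
                continue
            g = raw[name].copy()
            if name in pen:
                g += pen[name]
            if name == "W" and config.w_mask is not None:
                g *= config.w_mask
            grads[name] = g

        if log.isEnabledFor(logging.DEBUG):
            norms = {n: float(np.linalg.norm(np.atleast_1d(g)))
                     for n, g in grads.items()}
            log.debug("iter %d gradient norms %s", it + 1, norms)

        if adam_state is not None:
            adam_state, new_params = adam_step(adam_state, params, grads, optimizer)
        else:
            new_params = gd_step(params, grads, optimizer.lr)
        circuit.set_params(new_params)
        if config.w_mask is not None:
            circuit.W = circuit.W * config.w_mask

        Yf = _forward(circuit, I_full, solver_cfg)
        data_cost = float(full_cost.value(times, Yf[rec], circuit))
        if not np.isfinite(data_cost):
            raise RuntimeError(f"non-finite cost at iteration {it + 1}")
        data_trace.append(data_cost)
        total_trace.append(data_cost + spec.penalty(circuit))
        if (it + 1) % 100 == 0:
            log.info("iter %d full-data cost %.6g", it + 1, data_cost)
        if config.stop_cost is not None and data_cost <= config.stop_cost:
            break

    return circuit, CostTrace(np.asarray(total_trace), np.asarray(data_trace))


@dataclass
class SweepResult:
    lam: float
    circuit: GeneCircuit
    data_cost: float
    total_cost: float


def regularization_sweep(
    circuit: GeneCircuit,
    training_set: TrainingSet,
    lambda_sweep,
    config: TrainConfig,
    optimizer: AdamConfig | GDConfig | None = None,
) -> list[SweepResult]:
    """Re-train under each L1 strength in an ascending sweep.

    Each stage starts from the previous stage's parameters, so larger
    penalties progressively thin the network.
    """
    lams = [float(x) for x in lambda_sweep]
    if not lams:
        raise ValueError("lambda_sweep must be non-empty")
    if any(b < a for a, b in zip(lams, lams[1:])):
        raise ValueError("lambda_sweep must be ascending")
    results = []
    current = circuit
    for lam in lams:
        stage_cfg = replace(config, cost=replace(config.cost, lambda_l1=lam))
        current, trace = train(current, training_set, stage_cfg, optimizer)
        results.append(SweepResult(lam, current.copy(), trace.final(),
                                   float(trace.total[-1]) if len(trace) else np.nan))
    return results


def select_network(results: list[SweepResult], prune_eps: float,
                   factor: float = 2.0) -> SweepResult:
    """Pick the sparsest swept network whose data cost stays within
    ``factor`` of the least-regularised stage's cost."""
    ref = results[0].data_cost
    admissible = [r for r in results if r.data_cost <= factor * ref]
    if not admissible:
        admissible = [results[0]]
    return min(admissible, key=lambda r: int(np.sum(np.abs(r.circuit.W) > prune_eps)))


def prune(
    circuit: GeneCircuit,
    eps: float,
    training_set: TrainingSet,
    config: TrainConfig,
    optimizer: AdamConfig | GDConfig | None = None,
) -> tuple[GeneCircuit, GeneCircuit, CostTrace]:
    """Zero all weights with |W_ij| < eps, freeze them, re-fit the rest.

    Returns (pruned-but-untrained, retrained, retraining trace).  The
    retraining stage runs with the L1 penalty off.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    mask = (np.abs(circuit.W) >= eps).astype(float)
    pruned = circuit.copy()
    pruned.W = pruned.W * mask
    if not mask.any():
        warnings.warn("pruning removed every weight; the network is empty",
                      RuntimeWarning, stacklevel=2)
    retrain_cfg = replace(config, cost=replace(config.cost, lambda_l1=0.0),
                          w_mask=mask)
    retrained, trace = train(pruned, training_set, retrain_cfg, optimizer)
    return pruned, retrained, trace


def extract_topology(circuit: GeneCircuit, eps: float = 0.0) -> list[tuple]:
    """Signed edge list (source gene j, target gene i, sign, weight) for all
    |W_ij| > eps.  Positive weights are activations, negative repressions."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    edges = []
    N = circuit.n_nodes
    for i in range(N):
        for j in range(N):
            w = circuit.W[i, j]
            if abs(w) > eps:
                edges.append((j, i, "activation" if w > 0 else "repression", float(w)))
    return edges


def topology_to_tsv(edges: list[tuple], path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsign\tweight\n")
        for j, i, sign, w in edges:
            fh.write(f"{j}\t{i}\t{sign}\t{w!r}\n")


NOT_REACHED = -1


def iterations_to_cost(trace: CostTrace, c_target: float) -> int:
    """Smallest 1-based iteration whose full-data cost is <= c_target.

    Returns the sentinel ``NOT_REACHED`` (-1) if the trace never dips below
    the target — the N(C) scalability metric.
    """
    if len(trace) == 0:
        raise ValueError("trace is empty")
    hits = np.nonzero(trace.data <= c_target)[0]
    if len(hits) == 0:
        return NOT_REACHED
    return int(hits[0]) + 1
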