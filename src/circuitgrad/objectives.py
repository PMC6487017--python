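"""Scalar cost functions scoring a simulated circuit against a task.

Three data costs are available — endpoint squared error against per-case
target levels, squared deviation of the full readout trajectory from a
target cosine ``A_osc cos(w t)``, and binary cross-entropy — plus an L1
penalty on the interaction weights used to sparsify networks.  Each cost
object also supplies the analytic gradient of its value with respect to the
recorded trajectory states (and directly-entering parameters such as the
readout scale A), which is what the solver's adjoint sweep consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLAMP_EPS = 1e-7


# -- functional forms -------------------------------------------------------


def endpoint_mse(outputs, targets, A: float = 1.0) -> float:
    """Sum of squared errors of the rescaled endpoint readout, sum (A y - t)^2."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets must have matching length")
    return float(np.sum((A * outputs - targets) ** 2))


def trajectory_mse(readout, times, A_osc: float, omega: float) -> float:
    """Sum over recorded times of (y(t) - A_osc cos(omega t))^2."""
    readout = np.asarray(readout, dtype=float)
    times = np.asarray(times, dtype=float)
    target = A_osc * np.cos(omega * times)
    return float(np.sum((readout - target) ** 2))


def cross_entropy(outputs, targets, A: float = 1.0) -> float:
    """Binary cross-entropy of the rescaled readout against 0/1 targets.

    The rescaled output is clamped to [eps, 1 - eps] (eps = 1e-7) so the
    loss is total on all real outputs.
    """
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets must have matching length")
    if np.any((targets != 0) & (targets != 1)):
        raise ValueError("cross-entropy targets must be binary")
    p = np.clip(A * outputs, CLAMP_EPS, 1.0 - CLAMP_EPS)
    return float(-np.sum(targets * np.log(p) + (1 - targets) * np.log(1 - p)))


def l1_penalty(W, lambda_l1: float) -> float:
    """Sparsity penalty lambda * sum |W_ij|."""
    if lambda_l1 < 0:
        raise ValueError("lambda_l1 must be non-negative")
    return float(lambda_l1 * np.sum(np.abs(W)))


def l1_subgradient(W, lambda_l1: float) -> np.ndarray:
    """Subgradient lambda * sign(W), with sign(0) taken as 0."""
    return lambda_l1 * np.sign(W)


def optimal_scale(outputs, targets) -> float:
    """Closed-form A minimising sum (A y - t)^2 (least-squares ratio)."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    denom = float(np.sum(outputs**2))
    if denom == 0.0:
        return 1.0
    return float(np.sum(outputs * targets) / denom)


# -- cost objects consumed by the solver ------------------------------------


@dataclass
class EndpointCost:
    """Endpoint cost over a batch: readout A * y_out at the final record.

    ``kind`` selects squared error or cross-entropy.  ``state_grad`` seeds
    the adjoint only at the last recorded step and returns dC/dA so the
    scale can be trained jointly.
    """

    targets: np.ndarray
    kind: str = "endpoint_mse"  # endpoint_mse | cross_entropy

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float)
        if self.kind not in ("endpoint_mse", "cross_entropy"):
            raise ValueError(f"unknown endpoint cost kind {self.kind!r}")

    def _readout(self, Y, circuit):
        return Y[-1, :, circuit.output_node]

    def value(self, times, Y, circuit) -> float:
        y = self._readout(Y, circuit)
        if self.kind == "endpoint_mse":
            return endpoint_mse(y, self.targets, circuit.output_scale)
        return cross_entropy(y, self.targets, circuit.output_scale)

    def state_grad(self, times, Y, circuit):
        A = circuit.output_scale
        y = self._readout(Y, circuit)
        if self.kind == "endpoint_mse":
            resid = 2.0 * (A * y - self.targets)
        else:
            p = A * y
            inside = (p > CLAMP_EPS) & (p < 1.0 - CLAMP_EPS)
            pc = np.clip(p, CLAMP_EPS, 1.0 - CLAMP_EPS)
            resid = np.where(inside, (pc - self.targets) / (pc * (1.0 - pc)), 0.0)
        dY = np.zeros_like(Y)
        dY[-1, :, circuit.output_node] = A * resid
        return dY, {"A": float(np.sum(resid * y))}


@dataclass
class OscillatorCost:
    """Trajectory cost sum_t (y_out(t) - A_osc cos(omega t))^2.

    The target amplitude is fixed (the readout scale A is not applied);
    phase is left to the learnable initial conditions.
    """

    A_osc: float = 1.0
    omega: float = 1.0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    def value(self, times, Y, circuit) -> float:
        total = 0.0
        for m in range(Y.shape[1]):
            total += trajectory_mse(Y[:, m, circuit.output_node], times,
                                    self.A_osc, self.omega)
        return total

    def state_grad(self, times, Y, circuit):
        target = self.A_osc * np.cos(self.omega * np.asarray(times))
        dY = np.zeros_like(Y)
        out = circuit.output_node
        dY[:, :, out] = 2.0 * (Y[:, :, out] - target[:, None])
        return dY, {}


@dataclass
class CostSpec:
    """Declarative description of the training cost.

    kind: ``endpoint_mse`` | ``trajectory_mse`` | ``cross_entropy``;
    lambda_l1 scales the L1 weight penalty; learn_scale fits the readout
    scale A; A_osc / omega parameterise the trajectory target.
    """

    kind: str = "endpoint_mse"
    lambda_l1: float = 0.0
    learn_scale: bool = True
    A_osc: float = 1.0
    omega: float = 1.0
    l1_on_k: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("endpoint_mse", "trajectory_mse", "cross_entropy"):
            raise ValueError(f"unknown cost kind {self.kind!r}")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be non-negative")
        if self.kind == "trajectory_mse" and self.omega <= 0:
            raise ValueError("omega must be positive")

    def build(self, targets=None):
        """Instantiate the data-cost object for a batch of targets."""
        if self.kind == "trajectory_mse":
            return OscillatorCost(A_osc=self.A_osc, omega=self.omega)
        return EndpointCost(targets=np.asarray(targets, dtype=float), kind=self.kind)

    def penalty(self, circuit) -> float:
        pen = l1_penalty(circuit.W, self.lambda_l1)
        if self.l1_on_k:
            pen += l1_penalty(circuit.k, self.lambda_l1)
        return pen

    def penalty_grads(self, circuit) -> dict:
        out = {"W": l1_subgradient(circuit.W, self.lambda_l1)}
        if self.l1_on_k:
            out["k"] = l1_subgradient(circuit.k, self.lambda_l1)
        return out
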