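"""Gene-circuit ODE models and their parameter container.

A circuit of ``N`` transcription factors is parameterised by an ``N x N``
interaction matrix ``W`` (entry ``(i, j)`` is the effect of gene ``j`` on the
transcription of gene ``i``: positive = activation, negative = repression),
per-gene linear decay rates ``k``, and optionally a symmetric matrix ``gamma``
of dimer-mediated degradation rates or a Hill exponent for the
repressor-product variant.  Concentrations are dimensionless, normalised to
the maximal expression level.

Three right-hand-side variants are supported:

``additive``
    dy_i/dt = k_i (phi(sum_j W_ij y_j) + I_i - y_i)   (non-dimensional form)
    or, with ``k_on_decay_only``:
    dy_i/dt = phi(sum_j W_ij y_j) + I_i - k_i y_i

``dimer_decay``
    dy_i/dt = phi(sum_j W_ij y_j) + I_i - k_i y_i - sum_j Gamma_ij y_i y_j

``hill_product``
    dy_i/dt = prod_j 1 / (1 + (W_ij y_j)^n) + I_i - k_i y_i   (W_ij >= 0)

``phi`` is the logistic function, so production is always positive and
saturates at high input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

VARIANTS = ("additive", "dimer_decay", "hill_product")


def phi(x):
    """Saturating transcriptional nonlinearity (logistic).

    Strictly increasing, bounded in (0, 1), with phi(0) = 1/2; implemented
    in a numerically stable split form so large |x| does not overflow.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def phi_prime(x):
    """Derivative of :func:`phi`: phi(x) * (1 - phi(x))."""
    s = phi(x)
    return s * (1.0 - s)


@dataclass
class GeneCircuit:
    """All learnable and fixed parameters of one circuit.

    Parameters
    ----------
    n_nodes
        Number of genes N.
    W
        N x N interaction matrix.  For ``hill_product`` every entry is a
        repressor strength and must be non-negative.
    k
        Length-N vector of strictly positive decay rates (per unit time).
    y0
        Length-N vector of non-negative initial concentrations.
    gamma
        Optional N x N symmetric, non-negative matrix of dimer degradation
        rates (required by the ``dimer_decay`` variant).
    hill_n
        Hill exponent of the repressor-product variant (default 3).
    output_scale
        Positive readout rescaling factor A (the readout is A * y_output).
    variant
        One of ``additive``, ``dimer_decay``, ``hill_product``.
    k_on_decay_only
        For the additive variant only: if True, k multiplies the decay term
        alone instead of the whole bracket.
    input_nodes
        Indices of the genes that receive the external input I(t).
    output_node
        Index of the readout gene.
    learnable
        Per-parameter-group booleans.  ``W`` is always learnable; ``k``,
        ``y0``, ``A`` and ``gamma`` are optional.
    """

    n_nodes: int
    W: np.ndarray
    k: np.ndarray
    y0: np.ndarray
    gamma: np.ndarray | None = None
    hill_n: int = 3
    output_scale: float = 1.0
    variant: str = "additive"
    k_on_decay_only: bool = False
    input_nodes: tuple[int, ...] = (0,)
    output_node: int = -1
    learnable: dict = field(default_factory=lambda: {"W": True})

    def __post_init__(self):
        N = self.n_nodes
        self.W = np.asarray(self.W, dtype=float).reshape(N, N)
        self.k = np.asarray(self.k, dtype=float).reshape(N)
        self.y0 = np.asarray(self.y0, dtype=float).reshape(N)
        self.input_nodes = tuple(int(i) % N for i in np.atleast_1d(self.input_nodes))
        self.output_node = int(self.output_node) % N
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float).reshape(N, N)
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        self.learnable = {"W": True, **self.learnable}
        self.validate()

    def validate(self):
        if not (
            np.all(np.isfinite(self.W))
            and np.all(np.isfinite(self.k))
            and np.all(np.isfinite(self.y0))
        ):
            raise ValueError("circuit parameters must be finite")
        if np.any(self.k <= 0):
            raise ValueError("decay rates k must be strictly positive")
        if np.any(self.y0 < 0):
            raise ValueError("initial concentrations y0 must be non-negative")
        if self.output_scale <= 0:
            raise ValueError("output_scale must be positive")
        if self.variant == "hill_product":
            if self.hill_n < 1:
                raise ValueError("hill_n must be >= 1")
            if np.any(self.W < 0):
                raise ValueError("hill_product repressor strengths W must be >= 0")
        if self.variant == "dimer_decay":
            if self.gamma is None:
                raise ValueError("dimer_decay variant requires gamma")
            if not np.allclose(self.gamma, self.gamma.T):
                raise ValueError("gamma must be symmetric")
            if np.any(self.gamma < 0) or not np.all(np.isfinite(self.gamma)):
                raise ValueError("gamma must be non-negative and finite")

    # -- dynamics ---------------------------------------------------------

    def rhs(self, y: np.ndarray, I: np.ndarray) -> np.ndarray:
        """Right-hand side dy/dt for state ``y`` under input vector ``I``."""
        if self.variant == "additive":
            return rhs_additive(self, y, I)
        if self.variant == "dimer_decay":
            return rhs_dimer(self, y, I)
        return rhs_hill(self, y, I)

    # -- bookkeeping ------------------------------------------------------

    def copy(self) -> "GeneCircuit":
        return replace(
            self,
            W=self.W.copy(),
            k=self.k.copy(),
            y0=self.y0.copy(),
            gamma=None if self.gamma is None else self.gamma.copy(),
            learnable=dict(self.learnable),
        )

    def learnable_params(self) -> dict[str, np.ndarray | float]:
        """The current values of every learnable parameter group."""
        out: dict[str, np.ndarray | float] = {}
        if self.learnable.get("W", True):
            out["W"] = self.W
        if self.learnable.get("k", False):
            out["k"] = self.k
        if self.learnable.get("y0", False):
            out["y0"] = self.y0
        if self.learnable.get("A", False):
            out["A"] = self.output_scale
        if self.learnable.get("gamma", False) and self.gamma is not None:
            out["gamma"] = self.gamma
        return out

    def set_params(self, params: dict) -> None:
        """Write parameter-group values back, re-projecting constraints.

        Projections keep the update inside the model's admissible set:
        Hill repressor strengths and y0 are clipped at zero, gamma is
        re-symmetrised and clipped, k and A are floored at a small positive
        value.
        """
        if "W" in params:
            W = np.asarray(params["W"], dtype=float)
            if self.variant == "hill_product":
                W = np.maximum(W, 0.0)
            self.W = W
        if "k" in params:
            self.k = np.maximum(np.asarray(params["k"], dtype=float), 1e-3)
        if "y0" in params:
            self.y0 = np.maximum(np.asarray(params["y0"], dtype=float), 0.0)
        if "A" in params:
            self.output_scale = max(float(params["A"]), 1e-6)
        if "gamma" in params:
            g = np.asarray(params["gamma"], dtype=float)
            g = np.maximum(0.5 * (g + g.T), 0.0)
            self.gamma = g

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "n_nodes": self.n_nodes,
            "W": self.W.ravel().tolist(),
            "k": self.k.tolist(),
            "gamma": None if self.gamma is None else self.gamma.ravel().tolist(),
            "hill_n": self.hill_n,
            "y0": self.y0.tolist(),
            "output_scale": self.output_scale,
            "k_on_decay_only": self.k_on_decay_only,
            "input_nodes": list(self.input_nodes),
            "output_node": self.output_node,
            "learnable": {k: bool(v) for k, v in self.learnable.items()},
        }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "GeneCircuit":
        N = int(d["n_nodes"])
        gamma = d.get("gamma")
        return cls(
            n_nodes=N,
            W=np.array(d["W"], dtype=float).reshape(N, N),
            k=np.array(d["k"], dtype=float),
            y0=np.array(d["y0"], dtype=float),
            gamma=None if gamma is None else np.array(gamma, dtype=float).reshape(N, N),
            hill_n=int(d.get("hill_n", 3)),
            output_scale=float(d.get("output_scale", 1.0)),
            variant=d.get("variant", "additive"),
            k_on_decay_only=bool(d.get("k_on_decay_only", False)),
            input_nodes=tuple(d.get("input_nodes", (0,))),
            output_node=int(d.get("output_node", -1)),
            learnable=dict(d.get("learnable", {"W": True})),
        )

    @classmethod
    def from_json(cls, source) -> "GeneCircuit":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text) as fh:
            return cls.from_dict(json.load(fh))


def _check_state(circuit: GeneCircuit, y, I):
    y = np.asarray(y, dtype=float)
    I = np.asarray(I, dtype=float)
    if y.shape != (circuit.n_nodes,) or I.shape != (circuit.n_nodes,):
        raise ValueError(
            f"state and input must have shape ({circuit.n_nodes},); "
            f"got {y.shape} and {I.shape}"
        )
    return y, I


def rhs_additive(circuit: GeneCircuit, y, I) -> np.ndarray:
    """Additive transcriptional model.

    Canonical non-dimensional form k_i (phi(W y) + I - y)_i; with
    ``k_on_decay_only`` the decay-only form phi(W y) + I - k y.
    """
    y, I = _check_state(circuit, y, I)
    prod = phi(circuit.W @ y)
    if circuit.k_on_decay_only:
        return prod + I - circuit.k * y
    return circuit.k * (prod + I - y)


def rhs_dimer(circuit: GeneCircuit, y, I) -> np.ndarray:
    """Dimerisation-based decay: linear decay plus pairwise y_i y_j loss."""
    if circuit.gamma is None:
        raise ValueError("dimer_decay dynamics require gamma")
    y, I = _check_state(circuit, y, I)
    prod = phi(circuit.W @ y)
    dimer_loss = y * (circuit.gamma @ y)
    return prod + I - circuit.k * y - dimer_loss


def rhs_hill(circuit: GeneCircuit, y, I) -> np.ndarray:
    """Product of independent Hill repressors with exponent ``hill_n``."""
    if np.any(circuit.W < 0):
        raise ValueError("hill_product requires non-negative W")
    y, I = _check_state(circuit, y, I)
    X = circuit.W * y[np.newaxis, :]
    prod = np.prod(1.0 / (1.0 + X**circuit.hill_n), axis=1)
    return prod + I - circuit.k * y


def param_count(n_nodes: int, variant: str = "additive", learn_gamma: bool = False) -> int:
    """Number of interaction-weight parameters of a fully connected circuit.

    N^2 for the additive and Hill variants; the dimer variant adds the
    N(N+1)/2 free entries of the symmetric gamma matrix when it is learnable.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    n = n_nodes * n_nodes
    if variant == "dimer_decay" and learn_gamma:
        n += n_nodes * (n_nodes + 1) // 2
    return n


@dataclass
class InputSignal:
    """External drive applied to the circuit's input nodes.

    ``static`` holds one constant level; ``time_series`` a train of
    rectangular pulses (start, duration, amplitude) and/or arbitrary samples
    on the solver grid; ``zero`` no input.  Inputs are piecewise-constant on
    the step grid (left-continuous), so a pulse covers steps with
    start <= t < start + duration.
    """

    mode: str = "zero"  # static | time_series | zero
    level: float = 0.0
    pulses: Sequence[tuple[float, float, float]] = ()  # (start, duration, amplitude)
    samples: np.ndarray | None = None
    duration: float = 10.0

    def __post_init__(self):
        if self.mode not in ("static", "time_series", "zero"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "static" and self.level < 0:
            raise ValueError("input levels must be non-negative")
        for start, dur, amp in self.pulses:
            if dur <= 0 or amp < 0 or start < 0:
                raise ValueError("pulses need start >= 0, duration > 0, amplitude >= 0")

    @property
    def is_static(self) -> bool:
        return self.mode in ("static", "zero")

    def static_value(self) -> float:
        if self.mode == "static":
            return float(self.level)
        return 0.0

    def sample_on_grid(self, n_steps: int, dt: float) -> np.ndarray:
        """Input level applied during each Euler step [t_n, t_n + dt).

        Pulse edges are snapped to the nearest step boundary, so a pulse
        whose start and duration are grid multiples covers exactly
        duration/dt steps (left-continuous semantics).
        """
        if self.is_static:
            return np.full(n_steps, self.static_value())
        if self.samples is not None:
            s = np.asarray(self.samples, dtype=float)
            if s.shape != (n_steps,):
                raise ValueError(f"samples must have shape ({n_steps},), got {s.shape}")
            return s.copy()
        out = np.zeros(n_steps)
        for start, dur, amp in self.pulses:
            i0 = int(np.floor(start / dt + 0.5))
            i1 = int(np.floor((start + dur) / dt + 0.5))
            out[max(i0, 0):max(i1, 0)] += amp
        return out

    def integral(self, dt: float = 0.01) -> float:
        """Time integral of the drive over [0, duration]."""
        if self.mode == "zero":
            return 0.0
        if self.mode == "static":
            return self.level * self.duration
        if self.samples is None and self.pulses:
            return float(sum(dur * amp for _, dur, amp in self.pulses))
        n_steps = int(round(self.duration / dt))
        return float(self.sample_on_grid(n_steps, dt).sum() * dt)
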