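"""Parameter-update rules: classic gradient descent and Adam.

Both operate on dictionaries of parameter arrays (the learnable groups of a
circuit), so the same step function serves every model variant.  Adam keeps
bias-corrected first and second moment estimates per scalar parameter.  The
configured ``(b1, b2)`` are the moment decay rates themselves by default
(``parameterization="decay"``); the defaults (0.02, 0.001) give nearly
memoryless moments, so each update approaches lr * sign(g) with a
per-parameter adaptive scale — markedly better at escaping the plateaus of
circuit-design cost landscapes than the long-memory setting, in our
experience.  ``parameterization="decay_complement"`` instead maps them to
``beta = 1 - b``, recovering the conventional long-memory Adam
(0.98, 0.999).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ParamDict = dict[str, "np.ndarray | float"]


def gd_step(params: ParamDict, grads: ParamDict, lr: float) -> ParamDict:
    """One classic gradient-descent update, p <- p - lr * g."""
    out: ParamDict = {}
    for name, p in params.items():
        g = grads[name]
        if np.isscalar(p):
            out[name] = float(p) - lr * float(g)
        else:
            out[name] = np.asarray(p, dtype=float) - lr * np.asarray(g, dtype=float)
    return out


@dataclass
class AdamConfig:
    lr: float = 0.1
    b1: float = 0.02
    b2: float = 0.001
    eps: float = 1e-8
    parameterization: str = "decay"  # or "decay_complement"

    def __post_init__(self):
        if not (0 < self.b1 < 1 and 0 < self.b2 < 1):
            raise ValueError("b1 and b2 must lie in (0, 1)")
        if self.lr <= 0 or self.eps <= 0:
            raise ValueError("lr and eps must be positive")
        if self.parameterization not in ("decay_complement", "decay"):
            raise ValueError("parameterization must be decay_complement or decay")

    @property
    def betas(self) -> tuple[float, float]:
        if self.parameterization == "decay_complement":
            return 1.0 - self.b1, 1.0 - self.b2
        return self.b1, self.b2


@dataclass
class AdamState:
    """First/second moment accumulators and step counter."""

    m: ParamDict = field(default_factory=dict)
    v: ParamDict = field(default_factory=dict)
    t: int = 0

    @classmethod
    def for_params(cls, params: ParamDict) -> "AdamState":
        m: ParamDict = {}
        v: ParamDict = {}
        for name, p in params.items():
            if np.isscalar(p):
                m[name] = 0.0
                v[name] = 0.0
            else:
                m[name] = np.zeros_like(np.asarray(p, dtype=float))
                v[name] = np.zeros_like(np.asarray(p, dtype=float))
        return cls(m=m, v=v, t=0)


def adam_step(state: AdamState, params: ParamDict, grads: ParamDict,
              config: AdamConfig) -> tuple[AdamState, ParamDict]:
    """One Adam update with bias-corrected moments.

    m <- beta1 m + (1 - beta1) g,  v <- beta2 v + (1 - beta2) g^2,
    p <- p - lr * m-hat / (sqrt(v-hat) + eps).
    Mutates and returns ``state``; returns a fresh params dict.
    """
    beta1, beta2 = config.betas
    state.t += 1
    t = state.t
    bc1 = 1.0 - beta1**t
    bc2 = 1.0 - beta2**t
    out: ParamDict = {}
    for name, p in params.items():
        g = grads[name]
        if np.isscalar(p):
            m = beta1 * state.m[name] + (1 - beta1) * float(g)
            v = beta2 * state.v[name] + (1 - beta2) * float(g) ** 2
            state.m[name], state.v[name] = m, v
            out[name] = float(p) - config.lr * (m / bc1) / (np.sqrt(v / bc2) + config.eps)
        else:
            g = np.asarray(g, dtype=float)
            m = beta1 * state.m[name] + (1 - beta1) * g
            v = beta2 * state.v[name] + (1 - beta2) * g * g
            state.m[name], state.v[name] = m, v
            out[name] = np.asarray(p, dtype=float) - config.lr * (m / bc1) / (
                np.sqrt(v / bc2) + config.eps
            )
    return state, out
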