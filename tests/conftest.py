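import numpy as np
import pytest

import circuitgrad as cg


@pytest.fixture(autouse=True)
def _quiet_euler_warning():
    """The plain-Euler negative-dip diagnostic is expected in a few
    deliberately rough training runs; keep test output readable."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Euler state dipped",
                                category=RuntimeWarning)
        yield


def random_circuit(variant: str, n_nodes: int, seed: int,
                   learn_all: bool = True) -> cg.GeneCircuit:
    """A small random circuit of the given variant, safely inside the
    admissible parameter set (weights bounded away from constraint edges so
    finite-difference probes stay feasible)."""
    rng = np.random.default_rng(seed)
    if variant == "hill_product":
        W = 0.1 + np.abs(rng.normal(0.0, 0.5, (n_nodes, n_nodes)))
    else:
        W = rng.normal(0.0, 0.7, (n_nodes, n_nodes))
    gamma = None
    if variant == "dimer_decay":
        g = np.abs(rng.normal(0.0, 0.3, (n_nodes, n_nodes)))
        gamma = 0.5 * (g + g.T)
    c = cg.GeneCircuit(
        n_nodes=n_nodes,
        W=W,
        k=rng.uniform(0.5, 2.0, n_nodes),
        y0=rng.uniform(0.05, 0.5, n_nodes),
        gamma=gamma,
        variant=variant,
    )
    if learn_all:
        c.learnable.update({"k": True, "y0": True, "A": True,
                            "gamma": variant == "dimer_decay"})
    return c
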