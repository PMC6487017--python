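"""Model-layer tests: nonlinearity, the three ODE right-hand sides,
parameter counting, invariant enforcement and JSON round-tripping."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import circuitgrad as cg

from conftest import random_circuit


class TestPhi:
    def test_midpoint(self):
        assert cg.phi(0.0) == pytest.approx(0.5)

    def test_saturation_value(self):
        # high-precision logistic value at x = 10
        assert cg.phi(10.0) == pytest.approx(0.999954602, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-30, 30))
    def test_symmetry_and_bounds(self, x):
        # strict bounds hold wherever exp(-|x|) is resolvable in float64
        assert cg.phi(x) + cg.phi(-x) == pytest.approx(1.0)
        assert 0.0 < cg.phi(x) < 1.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-30, 30), st.floats(1e-3, 5.0))
    def test_strictly_increasing(self, x, dx):
        assert cg.phi(x + dx) > cg.phi(x)

    def test_extreme_arguments_do_not_overflow(self):
        assert cg.phi(-1000.0) == 0.0
        assert cg.phi(1000.0) == 1.0


def _simple(variant="additive", **kw):
    defaults = dict(
        n_nodes=2,
        W=np.zeros((2, 2)),
        k=np.ones(2),
        y0=np.full(2, 0.1),
        variant=variant,
    )
    defaults.update(kw)
    return cg.GeneCircuit(**defaults)


class TestAdditiveRHS:
    def test_fixed_point_at_half(self):
        # W = 0, I = 0, y = phi(0) = 0.5 is an exact fixed point
        c = _simple()
        out = cg.rhs_additive(c, np.full(2, 0.5), np.zeros(2))
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_input_balances_decay(self):
        c = _simple()
        out = cg.rhs_additive(c, np.ones(2), np.full(2, 0.5))
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_hand_computed_two_node(self):
        c = _simple(k=np.array([1.0, 2.0]), W=np.array([[0.0, 1.0], [-1.0, 0.0]]))
        y = np.array([0.5, 0.5])
        out = cg.rhs_additive(c, y, np.zeros(2))
        # node 0: 1 * (phi(0.5) - 0.5); node 1: 2 * (phi(-0.5) - 0.5)
        expected = np.array(
            [cg.phi(0.5) - 0.5, 2.0 * (cg.phi(-0.5) - 0.5)]
        )
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_decay_only_form(self):
        c = _simple(k=np.array([2.0, 3.0]), k_on_decay_only=True)
        y = np.array([0.2, 0.4])
        out = cg.rhs_additive(c, y, np.zeros(2))
        np.testing.assert_allclose(out, 0.5 - c.k * y, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        c = _simple()
        with pytest.raises(ValueError, match="shape"):
            cg.rhs_additive(c, np.zeros(3), np.zeros(3))


class TestDimerRHS:
    def test_zero_gamma_reduces_to_linear_decay_form(self):
        c = _simple("dimer_decay", gamma=np.zeros((2, 2)),
                    k=np.array([1.5, 0.7]), W=np.array([[0.3, -0.2], [1.0, 0.4]]))
        linear = _simple(k=c.k.copy(), W=c.W.copy(), k_on_decay_only=True)
        y = np.array([0.3, 0.8])
        I = np.array([0.1, 0.0])
        np.testing.assert_allclose(cg.rhs_dimer(c, y, I),
                                   cg.rhs_additive(linear, y, I), rtol=1e-14)

    def test_origin_produces_half(self):
        c = _simple("dimer_decay", gamma=np.zeros((2, 2)))
        np.testing.assert_allclose(cg.rhs_dimer(c, np.zeros(2), np.zeros(2)), 0.5)

    def test_dimer_term_hand_computed(self):
        gamma = np.array([[0.0, 0.3], [0.3, 0.0]])
        c = _simple("dimer_decay", gamma=gamma)
        y = np.array([1.0, 2.0])
        base = cg.rhs_dimer(_simple("dimer_decay", gamma=np.zeros((2, 2))),
                            y, np.zeros(2))
        out = cg.rhs_dimer(c, y, np.zeros(2))
        # dimer loss y_i * sum_j gamma_ij y_j: both partners lose 0.3*1*2 = 0.6
        np.testing.assert_allclose(out - base, [-0.6, -0.6], rtol=1e-12)

    def test_missing_gamma_is_configuration_error(self):
        with pytest.raises(ValueError, match="gamma"):
            _simple("dimer_decay", gamma=None)


class TestHillRHS:
    def test_no_repressors_full_production(self):
        c = _simple("hill_product", k=np.array([0.5, 2.0]))
        y = np.array([0.3, 0.4])
        I = np.array([0.2, 0.0])
        np.testing.assert_allclose(cg.rhs_hill(c, y, I), 1.0 + I - c.k * y,
                                   rtol=1e-12)

    def test_unit_repression_halves_production(self):
        W = np.array([[0.0, 2.0], [0.0, 0.0]])
        c = _simple("hill_product", W=W, hill_n=3)
        y = np.array([0.0, 0.5])  # W_01 * y_1 = 1 -> factor 1/(1+1) = 0.5
        out = cg.rhs_hill(c, y, np.zeros(2))
        assert out[0] == pytest.approx(0.5 - 0.0)

    def test_product_matches_explicit_loop(self):
        rng = np.random.default_rng(7)
        c = _simple("hill_product", n_nodes=3, W=np.abs(rng.normal(0, 1, (3, 3))),
                    k=np.ones(3), y0=np.full(3, 0.1))
        y = rng.uniform(0, 1, 3)
        out = cg.rhs_hill(c, y, np.zeros(3))
        expected = np.empty(3)
        for i in range(3):
            p = 1.0
            for j in range(3):
                p *= 1.0 / (1.0 + (c.W[i, j] * y[j]) ** 3)
            expected[i] = p - y[i]
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_monotone_decreasing_in_each_repressor(self):
        c = random_circuit("hill_product", 3, seed=5, learn_all=False)
        y = np.array([0.2, 0.4, 0.6])
        base = cg.rhs_hill(c, y, np.zeros(3))
        for j in range(3):
            up = y.copy()
            up[j] += 0.1
            bumped = cg.rhs_hill(c, up, np.zeros(3))
            for i in range(3):
                if i != j and c.W[i, j] > 0:
                    assert bumped[i] <= base[i]

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative|>= 0"):
            _simple("hill_product", W=np.array([[0.0, -0.1], [0.0, 0.0]]))


@pytest.mark.parametrize("variant", ["additive", "dimer_decay", "hill_product"])
def test_production_only_at_origin(variant):
    """With y = 0 and I >= 0 every component of the rate is non-negative."""
    c = random_circuit(variant, 3, seed=11, learn_all=False)
    out = c.rhs(np.zeros(3), np.array([0.0, 0.2, 0.0]))
    assert np.all(out >= 0)


class TestParamCount:
    @pytest.mark.parametrize("n,expected", [(9, 81), (1, 1), (3, 9)])
    def test_additive(self, n, expected):
        assert cg.param_count(n, "additive") == expected

    def test_dimer_with_learnable_gamma(self):
        assert cg.param_count(3, "dimer_decay", learn_gamma=True) == 9 + 6

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            cg.param_count(0)


class TestValidation:
    def test_nonpositive_decay_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            _simple(k=np.array([1.0, 0.0]))

    def test_negative_initial_state_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _simple(y0=np.array([-0.1, 0.1]))

    def test_asymmetric_gamma_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            _simple("dimer_decay", gamma=np.array([[0.0, 0.2], [0.1, 0.0]]))

    def test_nonfinite_weights_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            _simple(W=np.array([[np.inf, 0.0], [0.0, 0.0]]))


class TestSerialization:
    @pytest.mark.parametrize("variant", ["additive", "dimer_decay", "hill_product"])
    def test_round_trip_is_bit_exact(self, variant, tmp_path):
        c = random_circuit(variant, 3, seed=3)
        path = tmp_path / "circuit.json"
        c.to_json(path)
        back = cg.GeneCircuit.from_json(path)
        assert np.array_equal(back.W, c.W)
        assert np.array_equal(back.k, c.k)
        assert np.array_equal(back.y0, c.y0)
        if c.gamma is not None:
            assert np.array_equal(back.gamma, c.gamma)
        assert back.variant == c.variant
        assert back.output_scale == c.output_scale
        # serialising again reproduces the identical document
        assert back.to_json() == c.to_json()

    def test_flat_document_shape(self):
        c = random_circuit("additive", 2, seed=1)
        d = json.loads(c.to_json())
        assert len(d["W"]) == 4  # row-major flat
        assert set(d) >= {"variant", "n_nodes", "W", "k", "y0",
                          "output_scale", "input_nodes", "output_node"}
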