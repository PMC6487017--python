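"""Pipeline tests: initialisation statistics, batch training, the
regularisation sweep, pruning, topology extraction and the N(C) metric."""

import numpy as np
import pytest

import circuitgrad as cg


class TestInitialize:
    def test_reproducible_per_seed(self):
        a = cg.initialize(4, seed=7)
        b = cg.initialize(4, seed=7)
        assert np.array_equal(a.W, b.W)
        assert not np.array_equal(a.W, cg.initialize(4, seed=8).W)

    def test_printed_defaults(self):
        c = cg.initialize(5, seed=1)
        np.testing.assert_array_equal(c.k, np.ones(5))
        np.testing.assert_array_equal(c.y0, np.full(5, 0.1))

    def test_weight_scale(self):
        # sample sd of W entries over 10^4 draws ~ 0.1 within 3 standard errors
        draws = cg.initialize(100, seed=0).W.ravel()
        se = 0.1 / np.sqrt(2 * (len(draws) - 1))
        assert abs(draws.std(ddof=1) - 0.1) < 3 * se
        assert abs(draws.mean()) < 3 * 0.1 / np.sqrt(len(draws))

    def test_hill_weights_nonnegative(self):
        c = cg.initialize(4, seed=2, variant="hill_product")
        assert np.all(c.W >= 0)


class TestTrain:
    def test_zero_budget_returns_unchanged(self):
        task = cg.make_switch_task()
        c = cg.initialize(3, seed=0)
        out, trace = cg.train(c, task, cg.TrainConfig(n_iterations=0, seed=0))
        assert len(trace) == 0
        assert np.array_equal(out.W, c.W)

    def test_reproducible_end_to_end(self):
        task = cg.make_french_flag_task()
        cfg = cg.TrainConfig(n_iterations=25, seed=5)
        a, ta = cg.train(cg.initialize(3, seed=5), task, cfg)
        b, tb = cg.train(cg.initialize(3, seed=5), task, cfg)
        assert a.to_json() == b.to_json()
        assert np.array_equal(ta.data, tb.data)

    def test_learnable_scale_reaches_closed_form_optimum(self):
        """A single case whose target is twice the untrained output: the
        closed-form optimal rescaling A* = 2 zeroes the cost, and training
        the scale approaches that optimum."""
        task_probe = cg.make_switch_task(np.array([0.1, 0.9]), duration=5.0)
        c = cg.initialize(2, seed=3)
        sc = cg.SolverConfig(duration=5.0)
        _, Y = cg.simulate_batch(c, task_probe.signals()[:1], sc)
        y_out = float(Y[-1, 0, c.output_node])
        target = 2.0 * y_out
        cases = [(task_probe.cases[0][0], target)]
        task = cg.TrainingSet(cases, "endpoint", {"task": "scale_probe"})
        cfg = cg.TrainConfig(n_iterations=120, seed=3, solver=sc)
        trained, trace = cg.train(c, task, cfg)
        # the rescaled readout matches the target (the closed-form optimum
        # over A is cost 0); the jointly-trained weights keep the
        # short-memory optimizer jittering at the lr scale around it
        assert trace.data.min() < 1e-3
        assert trace.final() < 5e-3
        _, Yf = cg.simulate_batch(trained, task.signals(), sc)
        rescaled = trained.output_scale * float(Yf[-1, 0, trained.output_node])
        assert rescaled == pytest.approx(target, rel=0.1)

    def test_switch_cost_drops_tenfold(self):
        """Switch training shrinks the full-data cost at least tenfold on
        every seed (long-memory Adam, the fine-convergence setting)."""
        task = cg.make_switch_task()
        opt = cg.AdamConfig(parameterization="decay_complement")
        for seed in range(5):
            c = cg.initialize(3, seed=400 + seed)
            first = cg.train(c, task, cg.TrainConfig(n_iterations=1,
                                                     seed=400 + seed), opt)
            init_cost = first[1].data[0]
            cfg = cg.TrainConfig(n_iterations=2000, seed=400 + seed,
                                 stop_cost=init_cost / 20)
            _, trace = cg.train(c, task, cfg, opt)
            assert trace.final() < init_cost / 10

    def test_nonfinite_cost_aborts_with_iteration(self):
        import warnings

        task = cg.make_switch_task()
        c = cg.initialize(3, seed=0)
        c.k = np.full(3, 300.0)  # k > 2/dt makes the Euler map expansive
        with pytest.raises((RuntimeError, cg.SolverOverflowError)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cg.train(c, task, cg.TrainConfig(n_iterations=30, seed=0))


@pytest.fixture(scope="module")
def trained_stripe():
    task = cg.make_french_flag_task()
    c = cg.initialize(3, seed=5000)
    cfg = cg.TrainConfig(n_iterations=2500, seed=5000, stop_cost=0.05)
    trained, _ = cg.train(c, task, cfg)
    return task, trained


class TestSweepAndPrune:
    def test_zero_lambda_sweep_equals_plain_training(self, trained_stripe):
        task, trained = trained_stripe
        cfg = cg.TrainConfig(n_iterations=50, seed=5000)
        res = cg.regularization_sweep(trained, task, [0.0], cfg)
        _, trace = cg.train(trained, task, cfg)
        assert res[0].data_cost == pytest.approx(trace.final())

    def test_descending_sweep_rejected(self, trained_stripe):
        task, trained = trained_stripe
        with pytest.raises(ValueError, match="ascending"):
            cg.regularization_sweep(trained, task, [0.1, 0.01],
                                    cg.TrainConfig(n_iterations=5, seed=1))

    def test_sweep_trade_off(self, trained_stripe):
        """Ascending penalty: active-weight count non-increasing and the
        data cost at the strongest lambda is no better than unregularised."""
        task, trained = trained_stripe
        cfg = cg.TrainConfig(n_iterations=400, seed=5000)
        res = cg.regularization_sweep(trained, task, [0.0, 0.03, 0.3], cfg)
        counts = [int(np.sum(np.abs(r.circuit.W) > 0.1)) for r in res]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert res[-1].data_cost >= res[0].data_cost - 1e-9

    def test_prune_zero_eps_keeps_everything(self, trained_stripe):
        task, trained = trained_stripe
        pruned, _re, _tr = cg.prune(trained, 0.0, task,
                                    cg.TrainConfig(n_iterations=1, seed=1))
        assert np.array_equal(pruned.W, trained.W)

    def test_prune_infinite_eps_freezes_all_weights(self, trained_stripe):
        task, trained = trained_stripe
        with pytest.warns(RuntimeWarning, match="every weight"):
            pruned, retrained, _ = cg.prune(trained, np.inf, task,
                                            cg.TrainConfig(n_iterations=20, seed=1))
        assert np.all(pruned.W == 0)
        assert np.all(retrained.W == 0)  # frozen at zero during retraining

    def test_prune_retrain_recovers_cost(self, trained_stripe):
        task, trained = trained_stripe
        cfg = cg.TrainConfig(n_iterations=400, seed=5000)
        res = cg.regularization_sweep(trained, task, [0.03], cfg)
        pre = res[0].data_cost
        _p, _r, trace = cg.prune(res[0].circuit, 0.1, task, cfg)
        assert trace.final() <= 2.0 * pre


class TestTopology:
    def test_signed_edges(self):
        c = cg.GeneCircuit(n_nodes=2, W=np.array([[0.0, 1.0], [-1.0, 0.0]]),
                           k=np.ones(2), y0=np.zeros(2))
        edges = cg.extract_topology(c, 0.5)
        assert (1, 0, "activation", 1.0) in edges
        assert (0, 1, "repression", -1.0) in edges
        assert len(edges) == 2

    def test_threshold_above_max_gives_empty(self):
        c = cg.GeneCircuit(n_nodes=2, W=np.full((2, 2), 0.3), k=np.ones(2),
                           y0=np.zeros(2))
        assert cg.extract_topology(c, 0.5) == []

    def test_edge_count_matches_threshold_count(self):
        rng = np.random.default_rng(1)
        W = rng.normal(0, 1, (4, 4))
        c = cg.GeneCircuit(n_nodes=4, W=W, k=np.ones(4), y0=np.zeros(4))
        eps = 0.7
        assert len(cg.extract_topology(c, eps)) == int(np.sum(np.abs(W) > eps))

    def test_tsv_export(self, tmp_path):
        c = cg.GeneCircuit(n_nodes=2, W=np.array([[0.0, 1.0], [-1.0, 0.0]]),
                           k=np.ones(2), y0=np.zeros(2))
        path = tmp_path / "topo.tsv"
        cg.topology_to_tsv(cg.extract_topology(c, 0.5), path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "source\ttarget\tsign\tweight"
        assert len(lines) == 3


class TestIterationsToCost:
    def _trace(self, vals):
        arr = np.asarray(vals, dtype=float)
        return cg.CostTrace(arr, arr)

    def test_first_crossing(self):
        assert cg.iterations_to_cost(self._trace([1.0, 0.5, 0.3]), 0.4) == 3

    def test_immediate_crossing(self):
        assert cg.iterations_to_cost(self._trace([0.3, 0.6]), 0.4) == 1

    def test_never_reached_sentinel(self):
        trace = self._trace([1.0, 0.9, 0.8])
        assert cg.iterations_to_cost(trace, 0.4) == cg.NOT_REACHED

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            cg.iterations_to_cost(self._trace([]), 0.4)
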