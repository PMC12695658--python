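"""Gradients through the solver, checkpointing, truncation, optimizers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cablegrad import autodiff as ag
from cablegrad.losses import mae_loss
from cablegrad.mechanisms import ChannelSpec, SynapseSpec, \
    standard_hh_channels
from cablegrad.morphology import Section, build_cell_from_sections, \
    build_toy_cell
from cablegrad.params import ParameterView, from_unconstrained, \
    to_unconstrained
from cablegrad.solver import NetworkModel, StepCurrent, simulate
from cablegrad.training import (
    Adam,
    CheckpointPlan,
    OptimizerConfig,
    checkpointed_gradient,
    finite_difference_gradient,
    loss_gradient,
    polyak_step,
    smoothness_penalty,
    truncated_gradient,
)


class TestTransforms:
    def test_midpoint_maps_to_zero(self):
        assert float(ag.value_of(to_unconstrained(0.5, 0.0, 1.0))) == \
            pytest.approx(0.0, abs=1e-12)

    def test_logit_hand_value(self):
        t = float(ag.value_of(to_unconstrained(0.7310585786, 0.0, 1.0)))
        assert t == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(-10, 10), st.floats(-5, 5), st.floats(0.01, 10))
    def test_round_trip_over_random_bounds(self, t_center, lo, width):
        lo, hi = lo, lo + width
        theta = lo + width / (1 + np.exp(-t_center))
        back = float(ag.value_of(from_unconstrained(
            ag.value_of(to_unconstrained(theta, lo, hi)), lo, hi
        )))
        assert back == pytest.approx(theta, abs=1e-10)

    def test_unconstrained_always_maps_inside_bounds(self):
        for t in (-1e3, -5.0, 0.0, 5.0, 1e3):
            v = float(ag.value_of(from_unconstrained(t, 2.0, 3.0)))
            assert 2.0 <= v <= 3.0

    def test_value_on_bound_is_rejected(self):
        with pytest.raises(ValueError):
            to_unconstrained(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            ParameterView().add("x", "radius", [0], 1.0, (0.0, 1.0))


def passive_fit_problem(ncomp=1, amp=0.05):
    model = NetworkModel()
    model.add_cell(build_cell_from_sections(
        [Section("soma", 20.0, 10.0, ncomp)]
    ))
    model.insert_channel(0, ChannelSpec("leak", gbar=0.0003, e_rev=-54.3))
    model.stimulate(StepCurrent(0, 0, 0.0, 50.0, amp))
    model.record(0, 0)
    pv = ParameterView()
    pv.add("gl", "channel_gbar", np.arange(ncomp), 0.0003, (1e-5, 1e-2),
           channel="leak", group="leak")
    return model, pv


def hh_fit_problem():
    model = NetworkModel()
    model.add_cell(build_toy_cell("soma_two_dendrites"))
    for spec in standard_hh_channels().values():
        model.insert_channel(0, spec)
    tree = model.cells[0]
    model.stimulate(StepCurrent(0, tree.node_of("dend0", 1.0), 0.0, 10.0,
                                0.05))
    model.record(0, 0)
    model.record(0, tree.node_of("dend1", 1.0))
    comp = tree.compartment_index
    pv = ParameterView()
    pv.add("gna", "channel_gbar", comp, 0.12, (0.05, 1.1), channel="na",
           group="gna")
    pv.add("gk", "channel_gbar", comp, 0.036, (0.01, 0.3), channel="k",
           group="gk")
    pv.add("radius", "radius", comp,
           model.cells[0].radius[comp], (0.05, 15.0), group="geom")
    return model, pv


def trace_mae(target):
    def loss(tr):
        return mae_loss(tr.values, target)

    return loss


class TestGradientOracle:
    def test_constant_loss_has_zero_gradient(self):
        model, pv = passive_fit_problem()
        res = loss_gradient(model, lambda tr: 3.0, pv, t_max=2.0, dt=0.1)
        assert res.grads["gl"] == pytest.approx(0.0)

    def test_passive_terminal_voltage_gradient_matches_fd(self):
        model, pv = passive_fit_problem()

        def loss(tr):
            return tr.values[0, -1]

        res = loss_gradient(model, loss, pv, t_max=10.0, dt=0.025)
        fd = finite_difference_gradient(model, loss, pv, t_max=10.0,
                                        dt=0.025)
        assert res.grads["gl"] == pytest.approx(fd["gl"], rel=1e-3)

    def test_branched_hh_gradient_matches_fd_elementwise(self):
        model, pv = hh_fit_problem()
        target = np.asarray(simulate(model, t_max=5.0, dt=0.025).values) - 2.0
        loss = trace_mae(target)
        res = loss_gradient(model, loss, pv, t_max=5.0, dt=0.025)
        fd = finite_difference_gradient(model, loss, pv, t_max=5.0, dt=0.025)
        for name in res.grads:
            denom = np.maximum(np.abs(fd[name]), 1e-4 *
                               np.max(np.abs(fd[name])) + 1e-12)
            assert np.max(np.abs(res.grads[name] - fd[name]) / denom) < 1e-2

    def test_two_cell_synapse_gradient_matches_fd(self):
        model = NetworkModel()
        for _ in range(2):
            model.add_cell(build_cell_from_sections(
                [Section("soma", 20.0, 10.0, 1)]
            ))
        for spec in standard_hh_channels().values():
            model.insert_channel(0, spec)
        model.insert_channel(1, ChannelSpec("leak", gbar=0.0003,
                                            e_rev=-65.0))
        model.connect((0, 0), (1, 0), SynapseSpec(g_syn=2.0, e_syn=0.0,
                                                  k_minus=0.5))
        model.stimulate(StepCurrent(0, 0, 0.0, 20.0, 0.1))
        model.record(1, 0)
        pv = ParameterView()
        pv.add("gsyn", "g_syn", [0], 2.0, (0.01, 20.0), group="syn")
        pv.add("km", "k_minus", [0], 0.5, (0.01, 5.0), group="syn")

        def loss(tr):
            return ag.amean(tr.values)

        res = loss_gradient(model, loss, pv, t_max=15.0, dt=0.05)
        fd = finite_difference_gradient(model, loss, pv, t_max=15.0, dt=0.05)
        for name in res.grads:
            assert res.grads[name] == pytest.approx(fd[name], rel=1e-3)

    def test_fd_oracle_is_exact_on_quadratic_pass_through(self):
        # central differences are O(h^2): exact for quadratics
        pv = ParameterView()
        pv.add("x", "radius", [0], 1.0, (0.1, 5.0), group="x")
        u0 = pv.to_unconstrained()["x"]

        def quad(u):
            return float(3.0 * u["x"][0] ** 2 + 2 * u["x"][0])

        h = 1e-4
        up = {"x": u0 + h}
        um = {"x": u0 - h}
        fd = (quad(up) - quad(um)) / (2 * h)
        assert fd == pytest.approx(6.0 * u0[0] + 2.0, abs=1e-8)

    def test_fd_step_sweep_plateaus(self):
        model, pv = passive_fit_problem()

        def loss(tr):
            return tr.values[0, -1]

        vals = [
            finite_difference_gradient(model, loss, pv, t_max=5.0, dt=0.05,
                                       h=h)["gl"][0]
            for h in (1e-4, 1e-5, 1e-6)
        ]
        assert np.ptp(vals) / np.abs(np.mean(vals)) < 1e-4


class TestCheckpointing:
    def test_single_segment_plan_is_bitwise_full_storage(self):
        model, pv = passive_fit_problem()
        target = np.asarray(simulate(model, t_max=5.0, dt=0.05).values) + 1.0
        loss = trace_mae(target)
        full = loss_gradient(model, loss, pv, t_max=5.0, dt=0.05)
        one = loss_gradient(model, loss, pv, t_max=5.0, dt=0.05,
                            plan=CheckpointPlan([1]))
        assert np.array_equal(full.grads["gl"], one.grads["gl"])

    def test_two_level_plan_matches_full_storage_on_400_step_fit(self):
        model, pv = passive_fit_problem()
        target = np.asarray(simulate(model, t_max=20.0, dt=0.05).values) + 1.0
        loss = trace_mae(target)
        full = loss_gradient(model, loss, pv, t_max=20.0, dt=0.05)
        ck = checkpointed_gradient(model, loss, pv, t_max=20.0, dt=0.05,
                                   plan=CheckpointPlan([8, 5]))
        assert ck.grads["gl"] == pytest.approx(full.grads["gl"], rel=1e-8)
        assert ck.value == pytest.approx(full.value, rel=1e-12)

    @given(st.lists(st.integers(1, 6), min_size=1, max_size=3),
           st.integers(0, 5))
    @settings(max_examples=10)
    def test_random_plans_reproduce_the_gradient(self, segs, seed):
        model, pv = passive_fit_problem()
        rng = np.random.default_rng(seed)
        target = np.asarray(simulate(model, t_max=4.0, dt=0.1).values) \
            + rng.normal(0, 1)
        loss = trace_mae(target)
        full = loss_gradient(model, loss, pv, t_max=4.0, dt=0.1)
        ck = loss_gradient(model, loss, pv, t_max=4.0, dt=0.1,
                           plan=CheckpointPlan(segs))
        assert ck.grads["gl"] == pytest.approx(full.grads["gl"], rel=1e-8)

    def test_snapshot_budget_arithmetic(self):
        plan = CheckpointPlan([100, 100])
        assert plan.max_snapshots() == 200
        assert plan.levels == 2

    def test_on_hh_model_checkpointing_is_exact(self):
        model, pv = hh_fit_problem()
        target = np.asarray(simulate(model, t_max=5.0, dt=0.025).values) - 2.0
        loss = trace_mae(target)
        full = loss_gradient(model, loss, pv, t_max=5.0, dt=0.025)
        ck = loss_gradient(model, loss, pv, t_max=5.0, dt=0.025,
                           plan=CheckpointPlan([4, 4]))
        for name in full.grads:
            assert ck.grads[name] == pytest.approx(full.grads[name],
                                                   rel=1e-8, abs=1e-14)


class TestTruncation:
    def test_interval_beyond_duration_changes_nothing(self):
        model, pv = passive_fit_problem()
        target = np.asarray(simulate(model, t_max=5.0, dt=0.05).values) + 1.0
        loss = trace_mae(target)
        full = loss_gradient(model, loss, pv, t_max=5.0, dt=0.05)
        tr = truncated_gradient(model, loss, pv, t_max=5.0, dt=0.05,
                                truncation_interval=1e6)
        assert tr.grads["gl"] == pytest.approx(full.grads["gl"], rel=1e-12)

    def test_loss_on_first_segment_only_is_unaffected(self):
        model, pv = passive_fit_problem()
        n_first = 21  # samples in [0, 1] ms at dt=0.05

        def loss(tr):
            return ag.amean(tr.values[:, :n_first])

        full = loss_gradient(model, loss, pv, t_max=5.0, dt=0.05)
        tr = truncated_gradient(model, loss, pv, t_max=5.0, dt=0.05,
                                truncation_interval=1.0)
        assert tr.grads["gl"] == pytest.approx(full.grads["gl"], rel=1e-10)

    def test_forward_trace_is_unchanged_by_truncation(self):
        model, pv = passive_fit_problem()
        target = np.asarray(simulate(model, t_max=5.0, dt=0.05).values) + 1.0
        loss = trace_mae(target)
        full = loss_gradient(model, loss, pv, t_max=5.0, dt=0.05)
        tr = truncated_gradient(model, loss, pv, t_max=5.0, dt=0.05,
                                truncation_interval=1.0)
        assert np.array_equal(np.asarray(tr.trace.values),
                              np.asarray(full.trace.values))
        assert tr.value == full.value

    def test_two_segment_linear_recursion_severs_chain_rule(self):
        # hand-checkable analogue: x_{k+1} = a x_k on two steps with loss
        # x_2; truncating between the steps leaves only the last factor.
        # The solver analogue: gradient wrt leak of the final voltage with
        # truncation after every step must differ from the full gradient
        # and match a hand-assembled severed product.
        model, pv = passive_fit_problem()

        def loss(tr):
            return tr.values[0, -1]

        dt, t_max = 1.0, 2.0
        full = loss_gradient(model, loss, pv, t_max=t_max, dt=dt)
        sev = truncated_gradient(model, loss, pv, t_max=t_max, dt=dt,
                                 truncation_interval=dt)
        # severed chain rule by hand: d x2/d theta with x1 held constant
        u0 = pv.to_unconstrained()
        h = 1e-6

        def final_v(u, state0=None):
            tr_, st = simulate(model, pv, t_max=dt, dt=dt, unconstrained=u,
                               state0=state0, return_state=True)
            return tr_, st

        # forward to t=1 with nominal parameters, then differentiate only
        # the last step
        _, s1 = final_v(u0)
        up = {"gl": u0["gl"] + h}
        um = {"gl": u0["gl"] - h}
        vp = np.asarray(simulate(model, pv, t_max=dt, dt=dt,
                                 unconstrained=up,
                                 state0=s1.detached()).values)[0, -1]
        vm = np.asarray(simulate(model, pv, t_max=dt, dt=dt,
                                 unconstrained=um,
                                 state0=s1.detached()).values)[0, -1]
        hand = (vp - vm) / (2 * h)
        assert sev.grads["gl"][0] == pytest.approx(hand, rel=1e-4)
        assert not np.allclose(sev.grads["gl"], full.grads["gl"])


class TestPolyak:
    def test_unit_norm_gradient_moves_by_gamma(self):
        g = {"a": np.array([1.0])}
        upd = polyak_step(g, OptimizerConfig(gamma=0.3, beta=0.9))
        assert upd["a"] == pytest.approx([-0.3])

    def test_beta_one_is_normalized_gradient_descent(self):
        g = {"a": np.array([3.0, 4.0])}
        upd = polyak_step(g, OptimizerConfig(gamma=0.2, beta=1.0))
        assert np.linalg.norm(upd["a"]) == pytest.approx(0.2)

    def test_hand_value_beta_08(self):
        g = {"a": np.array([3.0, 4.0])}
        upd = polyak_step(g, OptimizerConfig(gamma=0.1, beta=0.8))
        assert upd["a"] == pytest.approx([-0.08278378, -0.11037837],
                                         abs=1e-7)

    def test_zero_norm_gradient_gives_zero_update(self):
        g = {"a": np.zeros(3)}
        upd = polyak_step(g, OptimizerConfig(gamma=0.1, beta=0.8))
        assert upd["a"] == pytest.approx(0.0)

    def test_per_group_normalization_is_independent(self):
        g = {"a": np.array([1.0]), "b": np.array([100.0])}
        cfg = OptimizerConfig(gamma=0.1, beta=1.0)
        upd = polyak_step(g, cfg, groups={"a": "ga", "b": "gb"})
        assert abs(upd["a"][0]) == pytest.approx(0.1)
        assert abs(upd["b"][0]) == pytest.approx(0.1)

    def test_momentum_accumulates(self):
        cfg = OptimizerConfig(gamma=0.1, beta=1.0, momentum=0.5)
        state = {}
        g = {"a": np.array([1.0])}
        u1 = polyak_step(g, cfg, momentum_state=state)
        u2 = polyak_step(g, cfg, momentum_state=state)
        assert u2["a"] == pytest.approx(u1["a"] * 1.5)

    def test_optimization_stays_in_bounds_over_long_runs(self):
        pv = ParameterView()
        pv.add("x", "radius", [0], 2.0, (1.0, 3.0), group="x")
        uncon = pv.to_unconstrained()
        rng = np.random.default_rng(0)
        cfg = OptimizerConfig(gamma=0.5, beta=0.8)
        for _ in range(500):
            g = {"x": rng.normal(size=1) * 10}
            upd = polyak_step(g, cfg)
            uncon = {"x": uncon["x"] + upd["x"]}
            pv.set_unconstrained(uncon)
            assert 1.0 < pv.entries["x"].value[0] < 3.0


class TestAdam:
    def test_descends_a_quadratic(self):
        opt = Adam(lr=0.1)
        u = {"x": np.array([5.0])}
        for _ in range(300):
            g = {"x": 2 * u["x"]}
            u = opt.step(u, g)
        assert abs(u["x"][0]) < 1e-2


class TestSmoothnessPenalty:
    def test_uniform_values_have_zero_penalty(self):
        tree = build_toy_cell("soma_two_dendrites")
        assert float(ag.value_of(smoothness_penalty(
            np.full(3, 0.7), tree, 0.001
        ))) == pytest.approx(0.0)

    def test_chain_hand_value(self):
        tree = build_cell_from_sections([
            Section("soma", 20.0, 5.0, 1),
            Section("b1", 30.0, 1.0, 1, parent="soma"),
            Section("b2", 30.0, 1.0, 1, parent="b1"),
        ])
        val = float(ag.value_of(smoothness_penalty(
            np.array([1.0, 2.0, 4.0]), tree, 0.001
        )))
        assert val == pytest.approx(0.001 * (1 + 4))

    def test_penalty_is_linear_in_lambda(self):
        tree = build_toy_cell("soma_two_dendrites")
        v = np.array([1.0, 3.0, 0.5])
        p1 = float(ag.value_of(smoothness_penalty(v, tree, 0.001)))
        p2 = float(ag.value_of(smoothness_penalty(v, tree, 0.002)))
        assert p2 == pytest.approx(2 * p1)


class TestGradientCostBound:
    def test_gradient_cost_is_independent_of_parameter_count(self):
        # same model, 1 vs 24 trainable parameters: the reverse sweep does
        # not replay extra simulations (FD would need 2 per parameter)
        import time

        model, pv_small = passive_fit_problem()
        model2, _ = passive_fit_problem()
        tree = model2.cells[0]
        pv_big = ParameterView()
        pv_big.add("gl", "channel_gbar", [0], 0.0003, (1e-5, 1e-2),
                   channel="leak", group="leak")
        pv_big.add("radius", "radius", [0], 10.0, (1.0, 20.0), group="g1")
        pv_big.add("length", "length", [0], 20.0, (5.0, 40.0), group="g2")
        pv_big.add("ra", "ra", [0], 100.0, (50.0, 500.0), group="g3")
        target = np.asarray(simulate(model, t_max=10.0, dt=0.05).values) + 1
        loss = trace_mae(target)

        def timed(m, pv):
            t0 = time.perf_counter()
            for _ in range(3):
                loss_gradient(m, loss, pv, t_max=10.0, dt=0.05)
            return time.perf_counter() - t0

        t_small = timed(model, pv_small)
        t_big = timed(model2, pv_big)
        assert t_big < 3.0 * t_small + 0.05
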