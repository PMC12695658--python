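"""Implicit-Euler cable solver: assembly, solves, stepping, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cablegrad import units
from cablegrad.mechanisms import ChannelSpec, standard_hh_channels
from cablegrad.morphology import Section, build_cell_from_sections, \
    build_toy_cell
from cablegrad.solver import (
    NetworkModel,
    NumericalDivergenceError,
    StepCurrent,
    n_steps_for,
    simulate,
    solve_tridiagonal_stone,
    solve_tridiagonal_thomas,
)

from conftest import make_random_tree_system

LEAK = dict(gbar=0.0003, e_rev=-65.0)
TAU_MS = 1.0 / 0.0003 * 1e-3  # Cm/g_leak for Cm = 1 uF/cm2


def single_compartment(radius=10.0, length=20.0):
    model = NetworkModel()
    model.add_cell(build_cell_from_sections(
        [Section("soma", length, radius, 1)]
    ))
    return model


class TestUnits:
    def test_half_axial_resistance_hand_value(self):
        # Ra=100 Ohm cm, l=100 um, a=1 um -> 50/pi MOhm = 15.915 MOhm
        r = units.half_axial_resistance_MOhm(100.0, 100.0, 1.0)
        assert r == pytest.approx(15.915, abs=1e-3)

    def test_membrane_time_constant_from_unit_table(self):
        # tau = Cm/g in this unit system must come out in ms
        area = 1234.5
        tau = units.capacitance_nF(area, 1.0) / \
            units.membrane_conductance_uS(0.0003, area)
        assert tau == pytest.approx(TAU_MS)


class TestTridiagonal:
    A3 = (np.array([0.0, 1, 1]), np.array([2.0, 2, 2]),
          np.array([1.0, 1, 0]), np.array([1.0, 0, 1]))

    def test_thomas_identity_system(self):
        x = solve_tridiagonal_thomas(np.zeros(4), np.ones(4), np.zeros(4),
                                     np.arange(4.0))
        assert x == pytest.approx(np.arange(4.0))

    def test_thomas_3x3_hand_case(self):
        # [[2,1,0],[1,2,1],[0,1,2]] x = [1,0,1]; A^{-1} row sums give
        # x = [1, -1, 1] (verified against the dense solve)
        lo, d, up, r = self.A3
        x = solve_tridiagonal_thomas(lo, d, up, r)
        assert x == pytest.approx([1.0, -1.0, 1.0])
        dense = np.diag(d) + np.diag(lo[1:], -1) + np.diag(up[:-1], 1)
        assert x == pytest.approx(np.linalg.solve(dense, r))

    @pytest.mark.parametrize("n", [1, 2, 3, 13, 50, 64, 100])
    def test_stone_agrees_with_thomas(self, n):
        rng = np.random.default_rng(n)
        d = rng.uniform(2, 4, n)
        lo = rng.uniform(-0.9, 0.9, n)
        up = rng.uniform(-0.9, 0.9, n)
        r = rng.normal(size=n)
        xs = solve_tridiagonal_stone(lo, d, up, r)
        xt = solve_tridiagonal_thomas(lo, d, up, r)
        assert xs == pytest.approx(xt, rel=1e-8, abs=1e-10)

    def test_stone_singleton_is_direct_division(self):
        assert solve_tridiagonal_stone(
            np.zeros(1), np.array([4.0]), np.zeros(1), np.array([2.0])
        ) == pytest.approx([0.5])

    def test_thomas_matches_dense_solve_on_dominant_system(self):
        rng = np.random.default_rng(5)
        n = 50
        d = rng.uniform(3, 5, n)
        lo = rng.uniform(-1, 1, n)
        up = rng.uniform(-1, 1, n)
        r = rng.normal(size=n)
        dense = np.diag(d) + np.diag(lo[1:], -1) + np.diag(up[:-1], 1)
        assert solve_tridiagonal_thomas(lo, d, up, r) == pytest.approx(
            np.linalg.solve(dense, r), rel=1e-10
        )

    def test_zero_pivot_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            solve_tridiagonal_thomas(np.zeros(2), np.zeros(2), np.zeros(2),
                                     np.ones(2))


class TestStepCounts:
    def test_200ms_at_25us_is_8000_steps(self):
        assert n_steps_for(200.0, 0.025) == 8000

    def test_zero_duration_trace_is_initial_condition_only(self,
                                                           passive_cell):
        tr = simulate(passive_cell, t_max=0.0, dt=0.025)
        assert tr.times.shape == (1,)
        assert np.asarray(tr.values).shape == (1, 1)

    def test_trace_has_steps_plus_one_samples(self, passive_cell):
        tr = simulate(passive_cell, t_max=1.0, dt=0.1)
        assert np.asarray(tr.values).shape[1] == 11

    def test_invalid_dt_rejected(self, passive_cell):
        with pytest.raises(ValueError):
            simulate(passive_cell, t_max=1.0, dt=0.0)


class TestPassiveDynamics:
    def test_equilibrium_is_a_fixed_point(self, passive_cell):
        tr = simulate(passive_cell, t_max=5.0, dt=0.1)
        assert np.asarray(tr.values) == pytest.approx(-65.0, abs=1e-9)

    def test_step_response_matches_rc_closed_form(self, passive_cell):
        passive_cell.stimulate(StepCurrent(0, 0, 0.0, 100.0, 0.01))
        dt = TAU_MS / 1000.0
        tr = simulate(passive_cell, t_max=3 * TAU_MS, dt=dt)
        area = 2 * np.pi * 10.0 * 20.0
        r_in = 1.0 / units.membrane_conductance_uS(0.0003, area)
        exact = -65.0 + 0.01 * r_in * (1 - np.exp(-tr.times / TAU_MS))
        err = np.max(np.abs(np.asarray(tr.values)[0] - exact))
        assert err / (0.01 * r_in) < 0.01

    def test_first_order_convergence_in_dt(self, passive_cell):
        passive_cell.stimulate(StepCurrent(0, 0, 0.0, 100.0, 0.01))
        area = 2 * np.pi * 10.0 * 20.0
        r_in = 1.0 / units.membrane_conductance_uS(0.0003, area)
        t_end = 2.0

        def error(dt):
            tr = simulate(passive_cell, t_max=t_end, dt=dt)
            exact = -65.0 + 0.01 * r_in * (1 - np.exp(-t_end / TAU_MS))
            return abs(float(np.asarray(tr.values)[0, -1]) - exact)

        dts = np.array([0.1, 0.05, 0.025, 0.0125])
        errs = np.array([error(dt) for dt in dts])
        order = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert 0.8 <= order <= 1.2

    def test_coupled_equal_compartments_stay_equal(self):
        model = NetworkModel()
        model.add_cell(build_cell_from_sections(
            [Section("cable", 40.0, 2.0, 2)]
        ))
        model.insert_channel(0, ChannelSpec("leak", **LEAK))
        model.record(0, 0)
        model.record(0, 1)
        tr = simulate(model, t_max=5.0, dt=0.05)
        v = np.asarray(tr.values)
        assert v[0] == pytest.approx(v[1], abs=1e-12)

    def test_implicit_euler_is_stable_at_large_dt(self, passive_cell):
        passive_cell.stimulate(StepCurrent(0, 0, 0.0, 500.0, 0.05))
        tr = simulate(passive_cell, t_max=500.0, dt=1.0)
        v = np.asarray(tr.values)
        assert np.all(np.isfinite(v)) and np.all(np.abs(v) < 500.0)

    def test_steady_state_attenuation_matches_cable_theory(self):
        # lambda = sqrt(a R_m / (2 Ra)); 200 compartments, analyze the
        # proximal portion where the semi-infinite exp(-x/lambda) holds
        n, seg = 200, 10.0
        a_um, gleak, ra = 1.0, 0.0003, 100.0
        lam_um = np.sqrt((a_um * 1e-4) * (1 / gleak) / (2 * ra)) * 1e4
        model = NetworkModel()
        model.add_cell(build_cell_from_sections(
            [Section("cable", n * seg, a_um, n)]
        ))
        model.insert_channel(0, ChannelSpec("leak", gbar=gleak, e_rev=-65.0))
        model.stimulate(StepCurrent(0, 0, 0.0, 1e6, 0.001))
        keep = [i for i in range(n) if (i * seg) <= 2.5 * lam_um]
        for i in keep:
            model.record(0, i)
        tr = simulate(model, t_max=60.0, dt=0.05)
        v = np.asarray(tr.values)[:, -1] + 65.0
        x = np.asarray(keep) * seg
        predicted = v[0] * np.exp(-(x - x[0]) / lam_um)
        assert np.max(np.abs(v - predicted) / v[0]) < 0.02


class TestTreeSolveOnModels:
    @given(st.integers(2, 30), st.integers(0, 1000))
    @settings(max_examples=40)
    def test_tree_solve_equals_dense_on_random_morphologies(self, n, seed):
        from cablegrad import autodiff as ag

        diag, off, rhs, parent, dense = make_random_tree_system(n, seed)
        x = ag.hines_solve(diag, off, rhs, parent)
        assert x == pytest.approx(np.linalg.solve(dense, rhs), rel=1e-10,
                                  abs=1e-12)

    def test_symmetric_y_gives_mirror_symmetric_voltages(self):
        model = NetworkModel()
        model.add_cell(build_toy_cell("soma_two_dendrites"))
        model.insert_channel(0, ChannelSpec("leak", **LEAK))
        tree = model.cells[0]
        tip0 = tree.node_of("dend0", 1.0)
        tip1 = tree.node_of("dend1", 1.0)
        model.stimulate(StepCurrent(0, tree.node_of("soma", 0.0),
                                    0.0, 10.0, 0.05))
        model.record(0, tip0)
        model.record(0, tip1)
        tr = simulate(model, t_max=10.0, dt=0.025)
        v = np.asarray(tr.values)
        assert v[0] == pytest.approx(v[1], abs=1e-12)


class TestActiveDynamics:
    def test_hh_soma_fires_under_step_current(self, hh_cell):
        hh_cell.stimulate(StepCurrent(0, 0, 0.0, 50.0, 0.1))
        tr = simulate(hh_cell, t_max=50.0, dt=0.025)
        v = np.asarray(tr.values)[0]
        assert v.max() > 0.0
        crossings = np.sum((v[1:] > 0) & (v[:-1] <= 0))
        assert crossings >= 1

    def test_hh_spike_timing_tracks_fine_scalar_reference(self, hh_cell):
        # independent scalar integration of the same equations at dt=1e-3
        hh_cell.stimulate(StepCurrent(0, 0, 0.0, 50.0, 0.1))
        tr = simulate(hh_cell, t_max=20.0, dt=0.025)
        v_sim = np.asarray(tr.values)[0]
        t_ref, v_ref = _scalar_hh_reference(
            i_nA=0.1, t_max=20.0, dt=0.001, area_um2=2 * np.pi * 10 * 20
        )
        t_spike_sim = tr.times[np.argmax(v_sim)]
        t_spike_ref = t_ref[np.argmax(v_ref)]
        assert v_ref.max() > 0.0
        assert abs(t_spike_sim - t_spike_ref) < 0.5  # ms

    def test_divergence_is_reported_with_site_and_time(self):
        model = single_compartment()
        # absurd negative conductance makes the system blow up
        model.insert_channel(0, ChannelSpec("leak", gbar=0.0003,
                                            e_rev=-65.0))
        model.record(0, 0)
        model.stimulate(StepCurrent(0, 0, 0.0, 10.0, float("nan")))
        with pytest.raises(NumericalDivergenceError, match="node 0"):
            simulate(model, t_max=1.0, dt=0.1)


class TestCalciumPool:
    def test_spiking_drives_transients_and_rest_decays(self, hh_cell):
        from cablegrad.mechanisms import CalciumPoolSpec

        hh_cell.calcium_pool = CalciumPoolSpec(channel="na", tau=20.0,
                                               scale=0.001)
        hh_cell.stimulate(StepCurrent(0, 0, 0.0, 50.0, 0.1))
        hh_cell.record(0, 0, "calcium")
        tr = simulate(hh_cell, t_max=50.0, dt=0.025)
        ca = np.asarray(tr.site("cell0.node0.ca"))
        assert ca[0] == pytest.approx(1e-4)
        assert ca.max() > 5 * ca[0]  # spikes load the pool

    def test_undriven_pool_relaxes_to_rest(self):
        from cablegrad.mechanisms import CalciumPoolSpec

        model = single_compartment()
        model.insert_channel(0, ChannelSpec("leak", gbar=0.0003,
                                            e_rev=-65.0))
        model.calcium_pool = CalciumPoolSpec(channel="leak", tau=5.0,
                                             scale=0.0)
        model.record(0, 0, "calcium")
        compiled = model.compile()
        state = compiled.initial_state()
        state.calcium[:] = 0.01
        tr = simulate(compiled, t_max=60.0, dt=0.1, state0=state)
        assert np.asarray(tr.values)[0, -1] == pytest.approx(1e-4, rel=0.01)

    def test_calcium_recording_requires_pool(self, hh_cell):
        from cablegrad.solver import SimulationError

        hh_cell.record(0, 0, "calcium")
        with pytest.raises(SimulationError, match="calcium"):
            hh_cell.compile()


class TestDeterminism:
    def test_repeated_runs_are_bit_identical(self, hh_cell):
        hh_cell.stimulate(StepCurrent(0, 0, 0.0, 20.0, 0.08))
        a = np.asarray(simulate(hh_cell, t_max=20.0, dt=0.025).values)
        b = np.asarray(simulate(hh_cell, t_max=20.0, dt=0.025).values)
        assert np.array_equal(a, b)


def _scalar_hh_reference(i_nA, t_max, dt, area_um2):
    """Plain scalar forward integration of the squid-axon equations."""
    from cablegrad import units as U

    def rates(v):
        am = 0.1 * (v + 40) / (1 - np.exp(-(v + 40) / 10))
        bm = 4 * np.exp(-(v + 65) / 18)
        ah = 0.07 * np.exp(-(v + 65) / 20)
        bh = 1 / (1 + np.exp(-(v + 35) / 10))
        an = 0.01 * (v + 55) / (1 - np.exp(-(v + 55) / 10))
        bn = 0.125 * np.exp(-(v + 65) / 80)
        return am, bm, ah, bh, an, bn

    c = U.capacitance_nF(area_um2, 1.0)
    gna = U.membrane_conductance_uS(0.12, area_um2)
    gk = U.membrane_conductance_uS(0.036, area_um2)
    gl = U.membrane_conductance_uS(0.0003, area_um2)
    v = -65.0
    am, bm, ah, bh, an, bn = rates(v)
    m, h, n = am / (am + bm), ah / (ah + bh), an / (an + bn)
    ts = np.arange(0.0, t_max + dt, dt)
    vs = np.empty_like(ts)
    vs[0] = v
    for k in range(1, len(ts)):
        am, bm, ah, bh, an, bn = rates(v)
        m += dt * (am * (1 - m) - bm * m)
        h += dt * (ah * (1 - h) - bh * h)
        n += dt * (an * (1 - n) - bn * n)
        i_ion = (gna * m**3 * h * (v - 50.0) + gk * n**4 * (v + 77.0)
                 + gl * (v + 54.3))
        v += dt * (i_nA - i_ion) / c
        vs[k] = v
    return ts, vs
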