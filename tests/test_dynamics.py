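"""Membrane dynamics: closed forms, oracles, conservation, determinism."""

import numpy as np
import pytest
from scipy.linalg import expm

from wormcircuit.connectome import Connectome, Neuron
from wormcircuit.dynamics import (
    SimulationError,
    _Assembled,
    linearized_simulate,
    resting_state,
    simulate,
)
from wormcircuit.model import NA_TO_INTERNAL, StimulusPlan, default_params
from wormcircuit.synthetic import ToySpec, make_toy_connectome


def _net(n, gap=None, chem=None, inhibitory=()):
    neurons = [
        Neuron(f"N{i}", f"N{i}", "inter", i in inhibitory, i) for i in range(n)
    ]
    return Connectome(
        neurons,
        np.zeros((n, n)) if gap is None else np.asarray(gap, float),
        np.zeros((n, n)) if chem is None else np.asarray(chem, float),
    )


def lti_closed_form(conn, params, i_ext_na, t):
    """Matrix-exponential solution of the activation-frozen network.

    Independent of the integrator: builds the LTI system (A, b) from the
    stated right-hand side and evaluates V(t) = V* + expm(At)(V0 - V*).
    """
    p = params
    rest = resting_state(conn, p)
    s = rest.activations
    gg = p.gap_unit_conductance * conn.gap
    gs = p.syn_unit_conductance * conn.chem
    e_rev = np.where(conn.inhibitory_mask, p.syn_reversal_inh, p.syn_reversal_exc)
    g_diag = p.leak_conductance + gg.sum(axis=1) + gs.T @ s
    a = (-np.diag(g_diag) + gg) / p.capacitance
    b = (
        p.leak_conductance * p.leak_reversal
        + gs.T @ (s * e_rev)
        + np.asarray(i_ext_na) * NA_TO_INTERNAL
    ) / p.capacitance
    v_star = np.linalg.solve(a, -b)
    out = np.empty((conn.n, len(t)))
    for k, tk in enumerate(t):
        out[:, k] = v_star + expm(a * tk) @ (rest.voltages - v_star)
    return out


class TestRestingState:
    def test_isolated_neuron_at_leak_reversal(self, single_neuron, params_fast):
        rs = resting_state(single_neuron, params_fast)
        assert rs.voltages[0] == pytest.approx(params_fast.leak_reversal)

    def test_gap_pair_symmetric_rest(self, params_fast):
        conn = _net(2, gap=[[0, 3], [3, 0]])
        rs = resting_state(conn, params_fast)
        assert np.allclose(rs.voltages, params_fast.leak_reversal)

    def test_equilibrium_of_nonlinear_rhs(self, params_fast):
        """Resting state zeroes the full nonlinear right-hand side.

        Oracle: evaluate the stated RHS directly (not via the integrator)
        at the returned state.
        """
        conn = _net(3, chem=[[0, 2, 0], [0, 0, 4], [1, 0, 0]], inhibitory=(1,))
        rs = resting_state(conn, params_fast)
        asm = _Assembled(conn, params_fast)
        dv = asm.dv(rs.voltages, rs.activations, np.zeros(3))
        ds = asm.ds(rs.voltages, rs.activations, rs.thresholds)
        assert np.abs(dv).max() < 1e-9
        assert np.abs(ds).max() < 1e-12

    def test_matches_independent_root_finder(self, params_fast):
        """Equilibrium agrees with a generic nonlinear root-finder."""
        from scipy.optimize import fsolve

        conn = _net(3, chem=[[0, 5, 0], [0, 0, 3], [0, 0, 0]])
        rs = resting_state(conn, params_fast)
        asm = _Assembled(conn, params_fast)

        def rhs(x):
            v, s = x[:3], x[3:]
            return np.concatenate(
                [asm.dv(v, s, np.zeros(3)), asm.ds(v, s, rs.thresholds)]
            )

        x0 = np.concatenate([rs.voltages + 1.0, rs.activations + 0.01])
        sol = fsolve(rhs, x0, full_output=False)
        assert np.allclose(sol[:3], rs.voltages, atol=1e-6)


class TestSingleNeuronClosedForm:
    def test_step_response_matches_exponential(self, single_neuron):
        p = default_params(duration=2.0)
        current_na = 2e-4
        tr = simulate(single_neuron, p, StimulusPlan({"A": current_na}))
        tau = p.capacitance / p.leak_conductance
        delta = current_na * NA_TO_INTERNAL / p.leak_conductance
        expected = p.leak_reversal + delta * (1 - np.exp(-tr.time / tau))
        scale = max(abs(delta), 1.0)
        assert np.abs(tr.voltage[0] - expected).max() / scale < 1e-3

    def test_time_constant_recovered(self, single_neuron):
        p = default_params(duration=2.0)
        tr = simulate(single_neuron, p, StimulusPlan({"A": 1e-4}))
        v = tr.voltage[0] - p.leak_reversal
        v_inf = v[-1]
        tau_true = p.capacitance / p.leak_conductance
        k = int(np.argmin(np.abs(v - v_inf * (1 - np.exp(-1)))))
        assert tr.time[k] == pytest.approx(tau_true, rel=1e-3, abs=p.dt)


class TestSimulate:
    def test_zero_stimulus_stays_at_rest(self, conn3, params_fast):
        tr = simulate(conn3, params_fast)
        rs = resting_state(conn3, params_fast)
        drift = np.abs(tr.voltage - rs.voltages[:, None]).max()
        assert drift < 1e-9

    def test_determinism_bit_identical(self, conn3, params_fast):
        s = StimulusPlan({"A": 1e-4})
        t1 = simulate(conn3, params_fast, s)
        t2 = simulate(conn3, params_fast, s)
        assert np.array_equal(t1.voltage, t2.voltage)
        assert np.array_equal(t1.activation, t2.activation)

    def test_activations_bounded(self, conn3, params_fast):
        tr = simulate(conn3, params_fast, StimulusPlan({"A": 5e-4}))
        assert tr.activation.min() >= 0.0 and tr.activation.max() <= 1.0

    def test_gap_current_conservation(self, params_fast):
        """Pairwise antisymmetry: total gap-junctional current is zero."""
        gap = np.array([[0, 2, 1], [2, 0, 4], [1, 4, 0]], float)
        conn = _net(3, gap=gap)
        p = params_fast
        tr = simulate(conn, p, StimulusPlan({"N0": 3e-4}))
        gg = p.gap_unit_conductance * gap
        for k in range(0, tr.voltage.shape[1], 200):
            v = tr.voltage[:, k]
            i_gap = (gg * (v[:, None] - v[None, :])).sum()
            assert abs(i_gap) < 1e-8 * max(1.0, np.abs(v).max())

    def test_grid_convergence_halving_dt(self, fixture_toy):
        """Halving dt changes the motor trace only marginally (non-stiff)."""
        fx = fixture_toy
        p1 = fx.params.with_overrides(duration=4.0)
        p2 = p1.with_overrides(dt=p1.dt / 2)
        s = fx.stimulus()
        t1 = simulate(fx.connectome, p1, s)
        t2 = simulate(fx.connectome, p2, s)
        v1 = t1.trace(t1.names[-1])
        v2 = t2.trace(t2.names[-1])[::2]
        span = v1.max() - v1.min()
        assert np.abs(v1 - v2).max() <= max(1e-6, 1e-4 * max(span, 1.0))

    def test_bilateral_symmetry(self):
        conn = make_toy_connectome(
            ToySpec(1, 1, 1, 1, 1, gap_weight=2, chem_weight=3, bilateral=True)
        )
        p = default_params(duration=2.0)
        inj = {nm: 2e-4 for nm in conn.names if nm.startswith("SEN")}
        tr = simulate(conn, p, StimulusPlan(inj))
        for nm in conn.names:
            if nm.endswith("L"):
                mirror = nm[:-1] + "R"
                assert np.array_equal(tr.trace(nm), tr.trace(mirror))

    def test_stimulus_on_ablated_neuron_warned_and_dropped(self, conn3, params_fast):
        with pytest.warns(UserWarning, match="ablated"):
            tr = simulate(
                conn3, params_fast, StimulusPlan({"A": 1e-3}), ablations={"A"}
            )
        # neuron A isolated at leak equilibrium, uninfluenced by its stimulus
        assert np.allclose(tr.trace("A"), params_fast.leak_reversal)

    def test_coarse_dt_rejected(self, params_fast):
        conn = _net(2, gap=[[0, 50], [50, 0]])
        with pytest.raises(SimulationError, match="dt"):
            simulate(conn, params_fast.with_overrides(dt=0.5))

    def test_ablation_starts_from_ablated_equilibrium(self, params_fast):
        conn = _net(3, chem=[[0, 3, 0], [0, 0, 3], [0, 0, 0]])
        tr = simulate(conn, params_fast, ablations={"N0"})
        rest_abl = resting_state(
            __import__("wormcircuit").ablate(conn, {"N0"}), params_fast
        )
        assert np.abs(tr.voltage[:, 0] - rest_abl.voltages).max() < 1e-12
        assert np.abs(tr.voltage - rest_abl.voltages[:, None]).max() < 1e-9


class TestLinearizedOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_matrix_exponential_random_small_nets(self, seed):
        """linearized_simulate equals the expm closed form on <=4-neuron nets."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        gap = rng.integers(0, 3, (n, n)).astype(float)
        gap = np.triu(gap, 1)
        gap = gap + gap.T
        chem = rng.integers(0, 3, (n, n)).astype(float)
        np.fill_diagonal(chem, 0)
        inhibitory = tuple(np.flatnonzero(rng.random(n) < 0.3))
        conn = _net(n, gap=gap, chem=chem, inhibitory=inhibitory)
        p = default_params(duration=1.0)
        i_na = np.zeros(n)
        i_na[0] = 2e-4
        tr = linearized_simulate(conn, p, StimulusPlan({"N0": i_na[0]}))
        sample = slice(0, len(tr.time), 100)
        expected = lti_closed_form(conn, p, i_na, tr.time[sample])
        err = np.abs(tr.voltage[:, sample] - expected).max()
        assert err < 1e-6 * max(1.0, np.abs(expected).max())

    def test_zero_input_constant(self, conn3, params_fast):
        tr = linearized_simulate(conn3, params_fast)
        assert np.abs(tr.voltage - tr.voltage[:, :1]).max() < 1e-9

    def test_coincides_with_simulate_without_chemical_synapses(self, params_fast):
        conn = _net(3, gap=[[0, 2, 0], [2, 0, 1], [0, 1, 0]])
        s = StimulusPlan({"N0": 1e-4})
        v_full = simulate(conn, params_fast, s).voltage
        v_lin = linearized_simulate(conn, params_fast, s).voltage
        assert np.allclose(v_full, v_lin, atol=1e-12)
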