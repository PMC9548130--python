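"""Network membrane-voltage dynamics.

Each neuron is a single leaky compartment coupled to the rest of the network
by ohmic gap junctions and graded chemical synapses:

    C dV_i/dt = -G_leak (V_i - E_cell)
                - sum_j G_gap  gap_ij  (V_i - V_j)
                - sum_j G_syn  chem_ji s_j (V_i - E_rev(j))
                + I_ext,i(t)

    ds_i/dt   = a_r phi(V_i) (1 - s_i) - a_d s_i,
    phi(V)    = 1 / (1 + exp(-beta (V - V_th,i)))

where ``gap``/``chem`` are contact-count matrices, s_j is the graded release
variable of presynaptic neuron j, and E_rev(j) is the excitatory or
inhibitory reversal potential according to j's transmitter sign.  The
per-neuron half-activation voltage V_th,i anchors the release sigmoid at the
network's zero-input equilibrium, which makes the resting state an exact
fixed point of the full nonlinear system.

Integration is a fixed-step explicit 4th-order Runge-Kutta scheme: the
system is non-stiff at millisecond steps for these parameter scales, and a
fixed step yields deterministic, uniformly sampled traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .connectome import Connectome, ablate
from .model import NA_TO_INTERNAL, ModelParams, StimulusPlan
from .traces import TraceSet

__all__ = [
    "NetworkState",
    "SimulationError",
    "resting_state",
    "simulate",
    "linearized_simulate",
]


class SimulationError(RuntimeError):
    """Integration failure: divergence, non-finite state, or bad step size."""


@dataclass
class NetworkState:
    voltages: np.ndarray     # mV, (N,)
    activations: np.ndarray  # dimensionless in [0, 1], (N,)
    thresholds: np.ndarray   # mV, (N,)


# ---------------------------------------------------------------------------
# assembled coefficient arrays


class _Assembled:
    """Connectome + params compiled into the arrays the RHS needs."""

    def __init__(self, conn: Connectome, p: ModelParams):
        self.p = p
        self.gap_g = p.gap_unit_conductance * conn.gap        # pS, symmetric
        self.chem_g = p.syn_unit_conductance * conn.chem      # pS, pre->post
        self.gap_degree = self.gap_g.sum(axis=1)              # pS
        self.e_rev = np.where(
            conn.inhibitory_mask, p.syn_reversal_inh, p.syn_reversal_exc
        )                                                     # mV, presynaptic
        self.n = conn.n

    def dv(self, v: np.ndarray, s: np.ndarray, i_ext: np.ndarray) -> np.ndarray:
        p = self.p
        leak = p.leak_conductance * (v - p.leak_reversal)
        gap = self.gap_degree * v - self.gap_g @ v
        g_in = self.chem_g.T @ s                  # total synaptic conductance
        drive = self.chem_g.T @ (s * self.e_rev)  # conductance-weighted E_rev
        syn = g_in * v - drive
        return (-leak - gap - syn + i_ext) / p.capacitance

    def ds(self, v: np.ndarray, s: np.ndarray, v_th: np.ndarray) -> np.ndarray:
        p = self.p
        phi = 1.0 / (1.0 + np.exp(-p.sigmoid_gain * (v - v_th)))
        return p.syn_rise * phi * (1.0 - s) - p.syn_decay * s

    def max_rate(self) -> float:
        """Upper bound on the fastest voltage eigenrate (1/s).

        Activations cannot exceed a_r/(a_r + a_d) (ds/dt < 0 above it for
        any release level), which bounds the total synaptic conductance.
        """
        p = self.p
        s_max = p.syn_rise / (p.syn_rise + p.syn_decay)
        total = (
            p.leak_conductance
            + 2.0 * self.gap_degree
            + s_max * self.chem_g.sum(axis=0)
        )
        return float(total.max() / p.capacitance)


# ---------------------------------------------------------------------------
# resting state


def resting_state(conn: Connectome, params: ModelParams) -> NetworkState:
    """Zero-input network equilibrium, used as initial condition.

    Under the half-activation ansatz phi(V_eq) = 1/2 the release variables
    equilibrate at s_eq = a_r / (a_r + 2 a_d) for every neuron, which turns
    the voltage fixed-point equations into a linear system.  Setting
    V_th = V_eq then closes the ansatz, so the returned state is an exact
    equilibrium of the full nonlinear dynamics.
    """
    p = params
    asm = _Assembled(conn, p)
    s_eq = p.syn_rise / (p.syn_rise + 2.0 * p.syn_decay)
    g_in = asm.chem_g.sum(axis=0) * s_eq
    a = (
        np.diag(p.leak_conductance + asm.gap_degree + g_in)
        - asm.gap_g
    )
    b = p.leak_conductance * p.leak_reversal + s_eq * (asm.chem_g.T @ asm.e_rev)
    try:
        v_eq = np.linalg.solve(a, np.broadcast_to(b, (conn.n,)))
    except np.linalg.LinAlgError as exc:
        raise SimulationError(
            "singular equilibrium system; review conductance parameters"
        ) from exc
    s = np.full(conn.n, s_eq)
    return NetworkState(voltages=v_eq, activations=s, thresholds=v_eq.copy())


# ---------------------------------------------------------------------------
# integration


def _current_vector(
    conn: Connectome, params: ModelParams, stimulus: StimulusPlan
) -> tuple[np.ndarray, float, float]:
    """Injected-current vector in internal units plus the [t_on, t_off) window."""
    i_ext = np.zeros(conn.n)
    dropped = [nm for nm in stimulus.injections if nm in conn.ablated]
    if dropped:
        warnings.warn(
            f"stimulus on ablated neurons dropped: {sorted(dropped)}",
            stacklevel=3,
        )
    for name, current_na in stimulus.injections.items():
        if name in conn.ablated:
            continue
        i_ext[conn.index_of(name)] = (
            current_na * NA_TO_INTERNAL * params.current_scale
        )
    t_on, t_off = stimulus.window(params.duration)
    return i_ext, t_on, t_off


def _check_step(asm: _Assembled, dt: float) -> None:
    # explicit RK4 real-axis stability limit is ~2.79/|lambda|
    if dt * max(asm.max_rate(), asm.p.syn_rise + asm.p.syn_decay) > 2.5:
        raise SimulationError(
            f"dt={dt} s too coarse for the fastest time scale "
            f"(~{1.0 / asm.max_rate():.2e} s); use a smaller dt"
        )


def _integrate(
    asm: _Assembled,
    v0: np.ndarray,
    s0: np.ndarray,
    v_th: np.ndarray,
    i_ext: np.ndarray,
    t_on: float,
    t_off: float,
    params: ModelParams,
    names: list[str],
    freeze_s: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dt = params.dt
    n_steps = int(round(params.duration / dt))
    time = np.arange(n_steps + 1) * dt
    volts = np.empty((len(v0), n_steps + 1))
    acts = np.empty_like(volts)
    v, s = v0.copy(), s0.copy()
    volts[:, 0], acts[:, 0] = v, s
    zero = np.zeros_like(i_ext)

    # the injected current is held constant across each step, sampled at the
    # step start: grid-aligned on/off switches then introduce no substep
    # inconsistency and the scheme keeps its order within each regime
    def rhs(i_t, v, s):
        dv = asm.dv(v, s, i_t)
        ds = zero if freeze_s else asm.ds(v, s, v_th)
        return dv, ds

    for k in range(n_steps):
        t = time[k]
        i_t = i_ext if (t_on - 1e-9) <= t < (t_off - 1e-9) else zero
        k1v, k1s = rhs(i_t, v, s)
        k2v, k2s = rhs(i_t, v + dt / 2 * k1v, s + dt / 2 * k1s)
        k3v, k3s = rhs(i_t, v + dt / 2 * k2v, s + dt / 2 * k2s)
        k4v, k4s = rhs(i_t, v + dt * k3v, s + dt * k3s)
        v = v + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
        s = s + dt / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
        if not freeze_s:
            np.clip(s, 0.0, 1.0, out=s)
        if not np.isfinite(v).all():
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise SimulationError(
                f"non-finite voltage for neuron {names[bad]!r} at "
                f"t={time[k + 1]:.4f} s; reduce dt or review parameters"
            )
        volts[:, k + 1], acts[:, k + 1] = v, s
    return time, volts, acts


def simulate(
    conn: Connectome,
    params: ModelParams,
    stimulus: StimulusPlan | None = None,
    ablations: Iterable[str] = (),
    protocol_id: str = "",
    keep_activations: bool = True,
) -> TraceSet:
    """Integrate the full nonlinear network under a stimulation protocol.

    Ablations are applied structurally before computing the initial
    condition, so the run starts from the *ablated* network's resting state
    and the traces carry no transient artifact of a stale equilibrium.
    """
    stimulus = stimulus or StimulusPlan()
    net = ablate(conn, ablations) if ablations else conn
    rest = resting_state(net, params)
    asm = _Assembled(net, params)
    _check_step(asm, params.dt)
    i_ext, t_on, t_off = _current_vector(net, params, stimulus)
    time, volts, acts = _integrate(
        asm,
        rest.voltages,
        rest.activations,
        rest.thresholds,
        i_ext,
        t_on,
        t_off,
        params,
        net.names,
        freeze_s=False,
    )
    return TraceSet(
        time=time,
        voltage=volts,
        activation=acts if keep_activations else None,
        names=net.names,
        protocol_id=protocol_id,
        params_fingerprint=params.fingerprint(),
        ablated=tuple(sorted(net.ablated)),
    )


def linearized_simulate(
    conn: Connectome,
    params: ModelParams,
    stimulus: StimulusPlan | None = None,
    protocol_id: str = "",
) -> TraceSet:
    """Simulate with activations frozen at their resting values.

    With s fixed the voltage equations are linear time-invariant, so small
    networks admit a matrix-exponential closed form; this mode exists to
    cross-check the integrator against that solution.
    """
    stimulus = stimulus or StimulusPlan()
    rest = resting_state(conn, params)
    asm = _Assembled(conn, params)
    _check_step(asm, params.dt)
    i_ext, t_on, t_off = _current_vector(conn, params, stimulus)
    time, volts, acts = _integrate(
        asm,
        rest.voltages,
        rest.activations,
        rest.thresholds,
        i_ext,
        t_on,
        t_off,
        params,
        conn.names,
        freeze_s=True,
    )
    return TraceSet(
        time=time,
        voltage=volts,
        activation=acts,
        names=conn.names,
        protocol_id=protocol_id or "linearized",
        params_fingerprint=params.fingerprint(),
        ablated=tuple(sorted(conn.ablated)),
    )
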