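"""Download-free fixtures: toy connectomes and surrogate oscillatory traces.

The toy connectome mirrors the four-layer sensorimotor topology of the
reflexive-aversion circuit: a sensor pair couples by gap junctions to a
relay-interneuron pair, which chemically synapses onto a command-interneuron
set, which drives a motor layer of mixed excitatory and inhibitory classes
(the inhibitory motor class stands in for the GABAergic VD/DD neurons).
Optional recurrent weights (command mutual excitation, motor-to-command
feedback, inhibitory-to-excitatory motor cross-inhibition) let a tuned toy
sustain network oscillations; they default to zero, giving the purely
feedforward chain.  An optional bystander pair couples to the sensors but
has no path to the motors, providing a guaranteed negative control for
ablation screens.

The shipped oscillator fixture (``oscillator_fixture``) is one such toy with
weights, stimulus currents, and parameter overrides tuned once and frozen as
package data, because sustained oscillation depends sensitively on the
operating point and screens need a stable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .connectome import Connectome, Neuron
from .model import ModelParams, StimulusPlan, default_params
from .traces import TraceSet

__all__ = [
    "ToySpec",
    "SurrogateSpec",
    "make_toy_connectome",
    "make_surrogate_traces",
    "make_two_pool_oscillator",
    "oscillator_fixture",
    "OscillatorFixture",
]

# layer prefix -> (category, inhibitory)
_LAYERS = {
    "SEN": ("sensory", False),
    "INT": ("inter", False),
    "CMD": ("inter", False),
    "MEX": ("motor", False),
    "MIN": ("motor", True),
    "BYS": ("inter", False),
}


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the generated four-layer toy connectome.

    Counts are per side when ``bilateral`` (each layer then doubles with
    mirror wiring and L/R name suffixes).  Weights are synaptic contact
    counts.  The recurrence weights default to zero (feedforward chain).
    """

    n_sensor: int = 1
    n_inter: int = 1
    n_command: int = 1
    n_motor_exc: int = 1
    n_motor_inh: int = 0
    gap_weight: float = 1.0
    chem_weight: float = 1.0
    bilateral: bool = False
    seed: int = 0
    bystander: bool = False
    command_recurrent: float = 0.0   # CMD <-> CMD mutual excitation
    motor_feedback: float = 0.0      # MEX -> CMD excitatory feedback
    cross_inhibition: float = 0.0    # MIN -> MEX inhibition
    motor_drive_exc: float | None = None  # CMD -> MEX weight; None = chem_weight
    relay_weight: float | None = None     # INT -> CMD weight; None = chem_weight
    inhibitory_inter: bool = False        # relay interneurons GABAergic

    def __post_init__(self) -> None:
        for f in ("n_sensor", "n_inter", "n_command", "n_motor_exc",
                  "n_motor_inh"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        for f in ("gap_weight", "chem_weight", "command_recurrent",
                  "motor_feedback", "cross_inhibition"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def _layer_names(prefix: str, count: int, bilateral: bool) -> list[str]:
    if bilateral:
        return [
            f"{prefix}{i + 1:02d}{side}"
            for i in range(count)
            for side in ("L", "R")
        ]
    return [f"{prefix}{i + 1:02d}" for i in range(count)]


def _same_side(a: str, b: str, bilateral: bool) -> bool:
    return (not bilateral) or a[-1] == b[-1]


def make_toy_connectome(spec: ToySpec) -> Connectome:
    """Deterministic four-layer toy connectome for a given spec."""
    layers = {
        "SEN": _layer_names("SEN", spec.n_sensor, spec.bilateral),
        "INT": _layer_names("INT", spec.n_inter, spec.bilateral),
        "CMD": _layer_names("CMD", spec.n_command, spec.bilateral),
        "MEX": _layer_names("MEX", spec.n_motor_exc, spec.bilateral),
        "MIN": _layer_names("MIN", spec.n_motor_inh, spec.bilateral),
        "BYS": _layer_names("BYS", 1, spec.bilateral) if spec.bystander else [],
    }
    neurons: list[Neuron] = []
    for prefix, names in layers.items():
        category, inhibitory = _LAYERS[prefix]
        if prefix == "INT" and spec.inhibitory_inter:
            inhibitory = True
        for nm in names:
            neurons.append(
                Neuron(
                    name=nm,
                    class_label=prefix,
                    category=category,
                    inhibitory=inhibitory,
                    index=len(neurons),
                )
            )
    n = len(neurons)
    idx = {nr.name: nr.index for nr in neurons}
    gap = np.zeros((n, n))
    chem = np.zeros((n, n))

    def add_gap(a: str, b: str, w: float) -> None:
        if w > 0:
            gap[idx[a], idx[b]] += w
            gap[idx[b], idx[a]] += w

    def add_chem(a: str, b: str, w: float) -> None:
        if w > 0:
            chem[idx[a], idx[b]] += w

    def connect(src: str, dst: str, w: float, kind: str) -> None:
        for a in layers[src]:
            for b in layers[dst]:
                if a != b and _same_side(a, b, spec.bilateral):
                    (add_gap if kind == "gap" else add_chem)(a, b, w)

    mex_drive = (
        spec.chem_weight if spec.motor_drive_exc is None else spec.motor_drive_exc
    )
    relay = spec.chem_weight if spec.relay_weight is None else spec.relay_weight
    connect("SEN", "INT", spec.gap_weight, "gap")
    connect("INT", "CMD", relay, "chem")
    connect("CMD", "MEX", mex_drive, "chem")
    connect("CMD", "MIN", spec.chem_weight, "chem")
    connect("CMD", "CMD", spec.command_recurrent, "chem")
    connect("MEX", "CMD", spec.motor_feedback, "chem")
    connect("MIN", "MEX", spec.cross_inhibition, "chem")
    if spec.bystander:
        # chemical (directed) so the bystanders receive sensor drive but
        # exert no influence back: an exactly-null ablation control
        connect("SEN", "BYS", spec.chem_weight, "chem")
    return Connectome(
        neurons=neurons, gap=gap, chem=chem,
        version_tag=f"toy(seed={spec.seed})",
    )


# ---------------------------------------------------------------------------
# surrogate traces


@dataclass(frozen=True)
class SurrogateSpec:
    """Sinusoidal surrogate traces with known period, phase, and noise."""

    period: float = 2.5          # s
    phase_map: dict = field(default_factory=dict)  # neuron -> phase (rad)
    amplitude: float = 10.0      # mV
    noise_sd: float = 0.0        # mV
    duration: float = 12.0       # s
    dt: float = 0.01             # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 2 * self.dt:
            raise ValueError("period must exceed 2*dt")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_surrogate_traces(spec: SurrogateSpec) -> TraceSet:
    """amplitude * sin(2 pi t / period + phase) + seeded Gaussian noise."""
    names = list(spec.phase_map) or ["OSC01"]
    phases = np.array([spec.phase_map.get(nm, 0.0) for nm in names])
    n_steps = int(round(spec.duration / spec.dt))
    t = np.arange(n_steps + 1) * spec.dt
    clean = spec.amplitude * np.sin(
        2.0 * np.pi * t[None, :] / spec.period + phases[:, None]
    )
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=clean.shape)
    return TraceSet(
        time=t,
        voltage=clean + noise,
        names=names,
        protocol_id=f"surrogate(seed={spec.seed})",
    )


# ---------------------------------------------------------------------------
# frozen oscillator fixture


def make_two_pool_oscillator(
    gap_weight: float,
    relay_weight: float,
    ring_drive: float,
    ring_inhibition: float,
    ring_feedback: float,
    ring_shortcut: float,
    cross_coupling: float,
    readout_weight: float,
) -> Connectome:
    """Four-layer toy whose command circuit is two anti-phase ring oscillators.

    Architecture (one instance per pool A/B):

    * sensor pair SEN01/02 -- gap junctions --> inhibitory relay pair INT01/02
      (and a BYS bystander pair with no path to the motors);
    * each relay inhibits both pool commands CMD01 (pool A) and CMD02 (pool B);
    * each pool is a three-stage ring:
      CMD -> RI (inhibitory) -> RE (excitatory) -> CMD, with an optional weak
      CMD -> RE shortcut.  With the release sigmoid anchored at rest, the
      ring's zero-input equilibrium is a weakly unstable focus, so the ring
      oscillates whenever the command sits near its resting operating point;
    * each pool's RE excites the other pool's RI (competitive cross-coupling),
      locking the two rings half a period apart;
    * motor readouts: excitatory MEX01/02 are driven by pool A's command,
      GABAergic MIN01/02 by pool B's command.  Because both readout stages
      are identical single excitatory synapses, the anti-phase pool locking
      appears as an exact half-period shift between the motor classes.

    The stimulation logic is a cancellation gate.  Sensor input saturates the
    inhibitory relays and hyperpolarizes the commands below the ring's
    operating window (sensor alone: silent).  Command current alone drives
    the commands above the window into saturation (commands alone: silent).
    Together, the relay inhibition and the injected current cancel, parking
    the commands inside the window where the rings oscillate.  Ablating the
    relay layer removes the inhibition and the same command current
    overshoots the window, abolishing the oscillation; ablating the
    bystanders changes nothing.
    """
    rows = [
        ("SEN01", "SEN", "sensory", False), ("SEN02", "SEN", "sensory", False),
        ("INT01", "INT", "inter", True), ("INT02", "INT", "inter", True),
        ("BYS01", "BYS", "inter", False), ("BYS02", "BYS", "inter", False),
        ("CMD01", "CMD", "inter", False), ("CMD02", "CMD", "inter", False),
        ("RIA01", "RIA", "inter", True), ("RIB01", "RIB", "inter", True),
        ("REA01", "REA", "inter", False), ("REB01", "REB", "inter", False),
        ("MEX01", "MEX", "motor", False), ("MEX02", "MEX", "motor", False),
        ("MIN01", "MIN", "motor", True), ("MIN02", "MIN", "motor", True),
    ]
    neurons = [
        Neuron(nm, cls, cat, inh, i) for i, (nm, cls, cat, inh) in enumerate(rows)
    ]
    n = len(neurons)
    idx = {nr.name: nr.index for nr in neurons}
    gap = np.zeros((n, n))
    chem = np.zeros((n, n))

    def g(a: str, b: str, w: float) -> None:
        gap[idx[a], idx[b]] += w
        gap[idx[b], idx[a]] += w

    def c(a: str, b: str, w: float) -> None:
        chem[idx[a], idx[b]] += w

    for s in ("SEN01", "SEN02"):
        for t in ("INT01", "INT02"):
            g(s, t, gap_weight)
        for t in ("BYS01", "BYS02"):
            # directed chemical drive: bystanders listen to the sensors but
            # influence nothing, so their ablation is an exact null control
            c(s, t, gap_weight)
    for relay in ("INT01", "INT02"):
        c(relay, "CMD01", relay_weight / 2.0)
        c(relay, "CMD02", relay_weight / 2.0)
    for cmd, ri, re in (("CMD01", "RIA01", "REA01"), ("CMD02", "RIB01", "REB01")):
        c(cmd, ri, ring_drive)
        c(ri, re, ring_inhibition)
        c(re, cmd, ring_feedback)
        if ring_shortcut > 0:
            c(cmd, re, ring_shortcut)
    c("REA01", "RIB01", cross_coupling)
    c("REB01", "RIA01", cross_coupling)
    for m in ("MEX01", "MEX02"):
        c("CMD01", m, readout_weight)
    for m in ("MIN01", "MIN02"):
        c("CMD02", m, readout_weight)
    return Connectome(neurons, gap, chem, version_tag="two-pool-oscillator")


@dataclass(frozen=True)
class OscillatorFixture:
    """The shipped tuned toy: connectome, protocol currents, params.

    ``command_asymmetry`` is a deterministic bias on the second pool's
    injected current; it seeds the anti-phase mode the same way the
    reference circuit's left/right interneuron asymmetry does.  The
    ``window_start`` is the fixture's post-transient analysis onset: the
    toy's gating transient rings down more slowly than the reference
    network's, so its canonical window opens at half the protocol duration.
    """

    connectome: Connectome
    params: ModelParams
    sensor_current: float     # nA, per sensor neuron
    command_current: float    # nA, per command neuron
    command_asymmetry: float  # fractional bias on the second pool
    window_start: float       # s, analysis window onset
    readout_classes: tuple[str, ...] = ("MEX", "MIN")

    def stimulus_map(
        self, sensors: bool = True, commands: bool = True
    ) -> dict[str, float]:
        inj: dict[str, float] = {}
        if sensors:
            inj["SEN01"] = inj["SEN02"] = self.sensor_current
        if commands:
            inj["CMD01"] = self.command_current
            inj["CMD02"] = self.command_current * (1.0 + self.command_asymmetry)
        return inj

    def stimulus(self, sensors: bool = True, commands: bool = True) -> StimulusPlan:
        return StimulusPlan(injections=self.stimulus_map(sensors, commands))

    @property
    def analysis(self):
        from .oscillation import AnalysisConfig

        return AnalysisConfig(window_start=self.window_start)

    def protocol(
        self,
        sensors: bool = True,
        commands: bool = True,
        ablations: tuple[str, ...] = (),
        protocol_id: str = "toy",
    ):
        from .protocols import ProtocolSpec

        return ProtocolSpec(
            protocol_id=protocol_id,
            injections=self.stimulus_map(sensors, commands),
            ablations=ablations,
            duration=self.params.duration,
            readout_classes=self.readout_classes,
        )


def oscillator_fixture() -> OscillatorFixture:
    """Load the frozen oscillator toy shipped as package data."""
    ref = resources.files("wormcircuit.data").joinpath("toy_oscillator.json")
    with ref.open() as fh:
        doc = json.load(fh)
    conn = make_two_pool_oscillator(**doc["weights"])
    params = default_params(**doc.get("param_overrides", {}))
    return OscillatorFixture(
        connectome=conn,
        params=params,
        sensor_current=float(doc["sensor_current_na"]),
        command_current=float(doc["command_current_na"]),
        command_asymmetry=float(doc["command_asymmetry"]),
        window_start=float(doc["analysis_window_start_s"]),
    )
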