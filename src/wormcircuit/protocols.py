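"""Named stimulation protocols and the in silico ablation screen.

The registry (shipped as YAML data, user-extensible) encodes the stimulation
experiments used to dissect the reflexive-aversion circuit: sensory neurons
driven at 5.0 nA, optionally with the AVA/AVD/AVE command interneurons (CIs)
co-stimulated at 0.9 nA each, with or without ablations of candidate relay
interneurons.  Currents are per neuron: a class entry applies its current to
every member.

The screen runs a base protocol once intact and once per candidate ablation
and reports which candidates' removal flips the circuit verdict away from
``oscillatory`` — the binary present/lost reading used to call circuit
membership.  Amplitude deltas are retained for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .connectome import Connectome, NeuronGroup, ablate, resolve_group
from .dynamics import simulate
from .model import ModelParams, StimulusPlan
from .oscillation import (
    AnalysisConfig,
    OscillationReport,
    Verdict,
    build_report,
)
from .traces import TraceSet

__all__ = [
    "ProtocolSpec",
    "ScreenResult",
    "named_protocol",
    "available_protocols",
    "run_protocol",
    "ablation_screen",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """One named in silico experiment.

    ``injections`` maps group names (class labels, aliases, or explicit
    neuron names) to per-neuron currents in nA; groups are resolved against
    the connectome at run time.
    """

    protocol_id: str
    injections: Mapping[str, float] = field(default_factory=dict)
    ablations: tuple[str, ...] = ()           # group names
    duration: float = 12.0
    readout_classes: tuple[str, ...] = ("VA", "DA", "VD", "DD", "AS")
    t_on: float = 0.0
    t_off: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "injections", dict(self.injections))
        if self.duration < 12.0:
            raise ValueError("protocol duration must be >= 12 s")

    def resolve_stimulus(self, conn: Connectome) -> StimulusPlan:
        inj: dict[str, float] = {}
        for group, current in self.injections.items():
            for name in resolve_group(conn, group).members:
                inj[name] = inj.get(name, 0.0) + current
        return StimulusPlan(injections=inj, t_on=self.t_on, t_off=self.t_off)

    def resolve_ablations(self, conn: Connectome) -> tuple[str, ...]:
        names: list[str] = []
        for group in self.ablations:
            names.extend(resolve_group(conn, group).members)
        return tuple(dict.fromkeys(names))


def _load_registry(path: str | Path | None = None) -> dict:
    if path is None:
        ref = resources.files("wormcircuit.data").joinpath("protocols.yaml")
        with ref.open() as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def available_protocols(registry_path: str | Path | None = None) -> list[str]:
    return sorted(_load_registry(registry_path)["protocols"])


def named_protocol(
    protocol_id: str, registry_path: str | Path | None = None
) -> ProtocolSpec:
    """Look up a protocol in the registry (packaged YAML by default)."""
    doc = _load_registry(registry_path)
    protocols = doc["protocols"]
    if protocol_id not in protocols:
        raise KeyError(
            f"unknown protocol {protocol_id!r}; registry has: "
            f"{', '.join(sorted(protocols))}"
        )
    entry = dict(protocols[protocol_id])
    if "base" in entry:
        base = dict(protocols[entry.pop("base")])
        base.update(entry)
        entry = base
    return ProtocolSpec(
        protocol_id=protocol_id,
        injections=entry.get("stimulus", {}),
        ablations=tuple(entry.get("ablations", ())),
        duration=float(entry.get("duration", doc.get("duration", 12.0))),
        readout_classes=tuple(
            entry.get(
                "readout_classes",
                doc.get("readout_classes", ("VA", "DA", "VD", "DD", "AS")),
            )
        ),
    )


def run_protocol(
    conn: Connectome,
    params: ModelParams,
    spec: ProtocolSpec,
    analysis: AnalysisConfig | None = None,
) -> tuple[TraceSet, OscillationReport]:
    """Simulate a protocol and build its oscillation report.

    Pure function of (connectome, params, spec): repeated runs give
    identical traces and reports.
    """
    if params.duration < spec.duration:
        params = params.with_overrides(duration=spec.duration)
    ablations = spec.resolve_ablations(conn)
    stimulus = spec.resolve_stimulus(conn)
    traces = simulate(
        conn, params, stimulus, ablations, protocol_id=spec.protocol_id
    )
    groups = [resolve_group(conn, g) for g in spec.readout_classes]
    report = build_report(traces, groups, analysis)
    return traces, report


@dataclass
class ScreenResult:
    baseline: OscillationReport
    per_ablation: dict[str, OscillationReport]
    circuit_members: list[str]
    traces: dict[str, TraceSet] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        def row(label: str, rep: OscillationReport) -> dict:
            amps = [m.amplitude for m in rep.per_neuron]
            return {
                "ablation": label,
                "verdict": rep.circuit_verdict.value,
                "oscillating_fraction": (
                    sum(m.oscillating for m in rep.per_neuron)
                    / len(rep.per_neuron)
                    if rep.per_neuron
                    else 0.0
                ),
                "max_amplitude_mv": max(amps) if amps else 0.0,
                "circuit_member": label in self.circuit_members,
            }

        rows = [row("(none)", self.baseline)]
        rows += [row(lbl, rep) for lbl, rep in self.per_ablation.items()]
        df = pd.DataFrame(rows)
        base_amp = df.loc[0, "max_amplitude_mv"]
        df["amplitude_delta_mv"] = df["max_amplitude_mv"] - base_amp
        return df


def ablation_screen(
    conn: Connectome,
    params: ModelParams,
    base: ProtocolSpec,
    candidates: Sequence[str],
    analysis: AnalysisConfig | None = None,
    keep_traces: bool = False,
) -> ScreenResult:
    """Ablate each candidate group in turn and test for oscillation loss.

    ``circuit_members`` are the candidates whose ablation drops the verdict
    from ``oscillatory``; cost is one simulation per candidate plus the
    baseline.
    """
    traces0, baseline = run_protocol(conn, params, base, analysis)
    per_ablation: dict[str, OscillationReport] = {}
    all_traces: dict[str, TraceSet] = {"(none)": traces0}
    members: list[str] = []
    for label in candidates:
        spec = ProtocolSpec(
            protocol_id=f"{base.protocol_id}_minus_{label}",
            injections=base.injections,
            ablations=base.ablations + (label,),
            duration=base.duration,
            readout_classes=base.readout_classes,
            t_on=base.t_on,
            t_off=base.t_off,
        )
        tr, rep = run_protocol(conn, params, spec, analysis)
        per_ablation[label] = rep
        all_traces[label] = tr
        if (
            baseline.circuit_verdict == Verdict.oscillatory
            and rep.circuit_verdict != Verdict.oscillatory
        ):
            members.append(label)
    return ScreenResult(
        baseline=baseline,
        per_ablation=per_ablation,
        circuit_members=members,
        traces=all_traces if keep_traces else {},
    )
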