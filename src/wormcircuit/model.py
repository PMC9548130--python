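"""Biophysical constants, integration settings, and stimulation plans."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["ModelParams", "StimulusPlan", "default_params", "load_params"]

#: fA per nA — the internal current unit consistent with pF/pS/mV/s.
NA_TO_INTERNAL = 1.0e6


@dataclass(frozen=True)
class ModelParams:
    """Constants of the membrane/synapse model plus integration settings.

    Units: capacitance pF, conductances pS, voltages mV, rates 1/s, time s.
    ``current_scale`` is a dimensionless calibration multiplier applied to
    every injected current after nA conversion.
    """

    capacitance: float = 1.0
    leak_conductance: float = 10.0
    leak_reversal: float = -35.0
    gap_unit_conductance: float = 100.0
    syn_unit_conductance: float = 100.0
    syn_reversal_exc: float = 0.0
    syn_reversal_inh: float = -45.0
    sigmoid_gain: float = 0.125
    syn_rise: float = 1.0
    syn_decay: float = 5.0
    current_scale: float = 1.0
    dt: float = 0.001
    duration: float = 12.0

    def __post_init__(self) -> None:
        positive = (
            "capacitance",
            "leak_conductance",
            "gap_unit_conductance",
            "syn_unit_conductance",
            "sigmoid_gain",
            "syn_rise",
            "syn_decay",
            "current_scale",
            "dt",
            "duration",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (
            self.syn_reversal_inh < self.leak_reversal < self.syn_reversal_exc
        ):
            warnings.warn(
                "expected ordering syn_reversal_inh < leak_reversal < "
                "syn_reversal_exc is violated",
                stacklevel=2,
            )

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def fingerprint(self) -> str:
        """Stable short hash of all parameter values."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class StimulusPlan:
    """Per-neuron injected currents (nA) held on [t_on, t_off).

    Default timing is the whole run (t_off=None reads as the simulation
    duration), matching continuous stimulation protocols.
    """

    injections: Mapping[str, float] = field(default_factory=dict)
    t_on: float = 0.0
    t_off: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "injections", dict(self.injections))
        for name, cur in self.injections.items():
            if not _finite(cur):
                raise ValueError(f"non-finite current for {name!r}")
        if self.t_off is not None and not self.t_on < self.t_off:
            raise ValueError("require t_on < t_off")

    def window(self, duration: float) -> tuple[float, float]:
        t_off = duration if self.t_off is None else self.t_off
        if t_off > duration + 1e-12:
            raise ValueError(f"t_off={t_off} exceeds duration={duration}")
        return self.t_on, t_off


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def default_params(**overrides) -> ModelParams:
    """Packaged defaults (data/defaults.yaml), optionally overridden."""
    with resources.files("wormcircuit.data").joinpath("defaults.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    doc.update(overrides)
    return ModelParams(**doc)


def load_params(path: str | Path, **overrides) -> ModelParams:
    """Load a YAML or JSON params file; missing fields fall back to defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - set(ModelParams.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    doc.update(overrides)
    return default_params(**doc)
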