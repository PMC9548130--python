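"""Oscillation readouts over motor-neuron voltage traces.

Turns a :class:`~wormcircuit.traces.TraceSet` into the quantities used to
judge whether a stimulation protocol drives the backward-locomotion program:
per-neuron peak voltage, oscillation presence, period, pairwise in-phase /
anti-phase relations, and a per-circuit verdict.

The analysis window defaults to the post-transient part of the run
(3 s onward): stimulated networks typically show strong onset activity,
a dip, and only then sustained oscillation, so period and phase are read
after the transient while the maximum voltage deliberately uses the full
run, where the onset peak lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .connectome import NeuronGroup
from .traces import TraceSet

__all__ = [
    "AnalysisConfig",
    "OscillationMetrics",
    "PhaseRelation",
    "OscillationReport",
    "Verdict",
    "PhaseClass",
    "max_voltage",
    "estimate_period",
    "classify_phase",
    "build_report",
]


class Verdict(str, Enum):
    oscillatory = "oscillatory"
    weak = "weak"
    silent = "silent"


class PhaseClass(str, Enum):
    in_phase = "in_phase"
    anti_phase = "anti_phase"
    undetermined = "undetermined"


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the oscillation analytics.

    amplitude_threshold separates genuine oscillation from numerically tiny
    ripple (mV, peak-to-trough); prominence_frac filters peaks by prominence
    relative to the window's peak-to-trough range; phase_threshold is the
    |correlation| needed for an in/anti-phase call; majority is the fraction
    of readout neurons that must oscillate for an oscillatory verdict.
    """

    window_start: float = 3.0
    window_end: float | None = None  # None = end of trace
    amplitude_threshold: float = 0.5  # mV
    min_peaks: int = 2
    prominence_frac: float = 0.10
    phase_threshold: float = 0.5
    majority: float = 0.5
    smooth_window: float | None = None  # s; None = auto (dt-scaled)


@dataclass(frozen=True)
class OscillationMetrics:
    neuron: str
    max_voltage: float        # mV, full run
    oscillating: bool
    amplitude: float          # mV peak-to-trough in the analysis window
    period: float | None      # s
    n_peaks: int


@dataclass(frozen=True)
class PhaseRelation:
    neuron_a: str
    neuron_b: str
    relation: PhaseClass
    correlation: float


@dataclass
class OscillationReport:
    per_neuron: list[OscillationMetrics]
    per_class: dict[str, dict]
    phase_pairs: list[PhaseRelation]
    circuit_verdict: Verdict

    def metrics(self, neuron: str) -> OscillationMetrics:
        for m in self.per_neuron:
            if m.neuron == neuron:
                return m
        raise KeyError(neuron)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "neuron": m.neuron,
                    "max_voltage_mv": m.max_voltage,
                    "oscillating": m.oscillating,
                    "amplitude_mv": m.amplitude,
                    "period_s": m.period,
                    "n_peaks": m.n_peaks,
                }
                for m in self.per_neuron
            ]
        )

    def to_dict(self) -> dict:
        return {
            "per_neuron": self.to_frame().to_dict(orient="records"),
            "per_class": self.per_class,
            "phase_pairs": [
                {
                    "neuron_a": p.neuron_a,
                    "neuron_b": p.neuron_b,
                    "relation": p.relation.value,
                    "correlation": p.correlation,
                }
                for p in self.phase_pairs
            ],
            "circuit_verdict": self.circuit_verdict.value,
        }


# ---------------------------------------------------------------------------
# per-trace primitives


def max_voltage(trace: np.ndarray) -> float:
    """Maximum membrane voltage over the full simulated interval (mV).

    The transient is deliberately included: stimulation-onset peaks are part
    of the readout.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if not np.isfinite(trace).all():
        raise ValueError("non-finite samples in trace")
    return float(trace.max())


def _window_slice(
    time: np.ndarray, t_start: float, t_end: float | None
) -> slice:
    t_end = time[-1] if t_end is None else t_end
    if t_end <= t_start:
        raise ValueError(f"empty analysis window [{t_start}, {t_end}]")
    i0 = int(np.searchsorted(time, t_start - 1e-12))
    i1 = int(np.searchsorted(time, t_end + 1e-12))
    if i1 - i0 < 2:
        raise ValueError("analysis window contains fewer than 2 samples")
    return slice(i0, i1)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Zero-phase boxcar smoothing (edge-padded); width in samples."""
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]


def _find_peaks(
    y: np.ndarray, prominence_frac: float, min_peaks: int
) -> np.ndarray:
    span = float(y.max() - y.min())
    if span == 0.0:
        return np.array([], dtype=int)
    peaks, _ = sp_signal.find_peaks(y, prominence=prominence_frac * span)
    return peaks


def estimate_period(
    trace: np.ndarray,
    time: np.ndarray,
    window: tuple[float, float | None] = (3.0, None),
    config: AnalysisConfig | None = None,
) -> float | None:
    """Dominant oscillation period in the window (s), or None.

    Pipeline: detrend (subtract windowed mean), light zero-phase boxcar
    smoothing (which suppresses sample-level peak jitter under noise without
    shifting peak positions), prominence-filtered peak detection; fewer than
    two surviving peaks means no oscillation.  Returns the mean inter-peak
    interval.  The estimate is invariant to constant offsets and to positive
    rescaling of the trace.
    """
    cfg = config or AnalysisConfig()
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)
    sl = _window_slice(time, window[0], window[1])
    y = trace[sl] - trace[sl].mean()
    t = time[sl]
    dt = float(t[1] - t[0])
    if cfg.smooth_window is None:
        width = max(1, int(round(0.02 * len(y))))  # ~2% of window
    else:
        width = max(1, int(round(cfg.smooth_window / dt)))
    peaks = _find_peaks(_smooth(y, width), cfg.prominence_frac, cfg.min_peaks)
    if len(peaks) < max(2, cfg.min_peaks):
        return None
    # earliest-time tie-break is find_peaks' behavior for plateaus already
    rough = float((t[peaks[-1]] - t[peaks[0]]) / (len(peaks) - 1))
    # second pass: smoothing matched to the rough period suppresses peak-time
    # jitter without flattening the cycles themselves
    width2 = max(width, int(round(rough / dt / 8.0)))
    ys = _smooth(y, width2)
    peaks = _find_peaks(ys, cfg.prominence_frac, cfg.min_peaks)
    if len(peaks) < max(2, cfg.min_peaks):
        return rough

    def series_slope(events: np.ndarray) -> tuple[float, float] | None:
        """Mean spacing of one event series by least squares, with weight."""
        m = len(events)
        if m < 2:
            return None
        if m == 2:
            return float(t[events[1]] - t[events[0]]), 1.0
        slope = float(np.polyfit(np.arange(m), t[events], 1)[0])
        return slope, float(m**3 - m)  # inverse variance of the LS slope

    # troughs are a second, independent once-per-cycle event series for any
    # periodic waveform shape; pooling them tightens the interval estimate
    troughs = _find_peaks(-ys, cfg.prominence_frac, cfg.min_peaks)
    estimates = [series_slope(peaks)]
    if len(troughs) >= 2:
        estimates.append(series_slope(troughs))
    pairs = [e for e in estimates if e is not None]
    total = sum(wt for _, wt in pairs)
    return float(sum(sl_ * wt for sl_, wt in pairs) / total)


def classify_phase(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    time: np.ndarray,
    window: tuple[float, float | None] = (3.0, None),
    config: AnalysisConfig | None = None,
    neuron_a: str = "a",
    neuron_b: str = "b",
) -> PhaseRelation:
    """Zero-lag correlation of detrended windowed traces, thresholded.

    correlation >= +threshold -> in_phase; <= -threshold -> anti_phase;
    otherwise (including quadrature and zero-variance traces) undetermined.
    Symmetric in its arguments.
    """
    cfg = config or AnalysisConfig()
    time = np.asarray(time, dtype=float)
    sl = _window_slice(time, window[0], window[1])
    a = np.asarray(trace_a, dtype=float)[sl]
    b = np.asarray(trace_b, dtype=float)[sl]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return PhaseRelation(neuron_a, neuron_b, PhaseClass.undetermined, 0.0)
    r = float((a @ b) / denom)
    if r >= cfg.phase_threshold:
        rel = PhaseClass.in_phase
    elif r <= -cfg.phase_threshold:
        rel = PhaseClass.anti_phase
    else:
        rel = PhaseClass.undetermined
    return PhaseRelation(neuron_a, neuron_b, rel, r)


# ---------------------------------------------------------------------------
# per-trace-set report


def _neuron_metrics(
    traces: TraceSet, name: str, cfg: AnalysisConfig
) -> OscillationMetrics:
    v = traces.trace(name)
    window = (cfg.window_start, cfg.window_end)
    sl = _window_slice(traces.time, *window)
    vw = v[sl]
    amplitude = float(vw.max() - vw.min())
    period = estimate_period(v, traces.time, window, cfg)
    # count surviving peaks the same way estimate_period does
    y = vw - vw.mean()
    width = max(1, int(round(0.02 * len(y))))
    peaks = _find_peaks(_smooth(y, width), cfg.prominence_frac, cfg.min_peaks)
    oscillating = (
        amplitude >= cfg.amplitude_threshold
        and len(peaks) >= cfg.min_peaks
        and period is not None
    )
    return OscillationMetrics(
        neuron=name,
        max_voltage=max_voltage(v),
        oscillating=oscillating,
        amplitude=amplitude,
        period=period if oscillating else period,
        n_peaks=int(len(peaks)),
    )


def build_report(
    traces: TraceSet,
    classes: Sequence[NeuronGroup],
    config: AnalysisConfig | None = None,
) -> OscillationReport:
    """Full oscillation report over the given readout classes.

    Computes per-neuron metrics in the post-transient window, per-class
    oscillating fractions and median periods, all intra- and inter-class
    phase pairs among oscillating neurons, and the circuit verdict:
    ``oscillatory`` when at least the configured majority of readout neurons
    oscillate; otherwise ``weak`` when any neuron's windowed amplitude
    reaches the amplitude threshold, else ``silent``.
    """
    cfg = config or AnalysisConfig()
    for grp in classes:
        missing = [m for m in grp.members if m not in traces.names]
        if missing:
            raise ValueError(
                f"group {grp.group_name!r} members absent from traces: {missing}"
            )
    window = (cfg.window_start, cfg.window_end)
    all_names: list[str] = []
    for grp in classes:
        for m in grp.members:
            if m not in all_names:
                all_names.append(m)
    per_neuron = [_neuron_metrics(traces, nm, cfg) for nm in all_names]
    by_name = {m.neuron: m for m in per_neuron}

    per_class: dict[str, dict] = {}
    for grp in classes:
        ms = [by_name[m] for m in grp.members]
        periods = [m.period for m in ms if m.oscillating and m.period]
        per_class[grp.group_name] = {
            "oscillating_fraction": (
                sum(m.oscillating for m in ms) / len(ms) if ms else 0.0
            ),
            "median_period": float(np.median(periods)) if periods else None,
        }

    oscillating = [m.neuron for m in per_neuron if m.oscillating]
    phase_pairs = [
        classify_phase(
            traces.trace(a),
            traces.trace(b),
            traces.time,
            window,
            cfg,
            neuron_a=a,
            neuron_b=b,
        )
        for i, a in enumerate(oscillating)
        for b in oscillating[i + 1 :]
    ]

    frac = len(oscillating) / len(per_neuron) if per_neuron else 0.0
    if per_neuron and frac >= cfg.majority and len(oscillating) > 0:
        verdict = Verdict.oscillatory
    elif any(m.amplitude >= cfg.amplitude_threshold for m in per_neuron):
        verdict = Verdict.weak
    else:
        verdict = Verdict.silent
    return OscillationReport(
        per_neuron=per_neuron,
        per_class=per_class,
        phase_pairs=phase_pairs,
        circuit_verdict=verdict,
    )
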