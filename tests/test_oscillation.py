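"""Oscillation analytics: period recovery, phase calls, report logic."""

import numpy as np
import pytest

from wormcircuit.connectome import NeuronGroup
from wormcircuit.oscillation import (
    AnalysisConfig,
    PhaseClass,
    Verdict,
    build_report,
    classify_phase,
    estimate_period,
    max_voltage,
)
from wormcircuit.synthetic import SurrogateSpec, make_surrogate_traces
from wormcircuit.traces import TraceSet


def _time(duration=12.0, dt=0.01):
    return np.arange(int(round(duration / dt)) + 1) * dt


def acf_first_peak_period(y, dt):
    """Independent oracle: lag of the first local autocorrelation maximum.

    Uses the unbiased ACF (dividing each lag by its overlap count) so the
    finite-window triangular taper does not drag the peak to shorter lags.
    """
    y = y - y.mean()
    n = len(y)
    acf = np.correlate(y, y, mode="full")[n - 1:] / np.arange(n, 0, -1)
    # first local max after the zero-lag lobe has decayed through zero
    below = np.flatnonzero(acf < 0)
    if len(below) == 0:
        return None
    # the zero crossing sits near a quarter period, so the one-period peak
    # lies within a few multiples of it; capping the search there keeps the
    # noisier long-lag estimates (near two periods) out
    start = below[0]
    k = start + int(np.argmax(acf[start : min(6 * start, n // 2)]))
    return k * dt


class TestMaxVoltage:
    def test_constant_trace(self):
        assert max_voltage(np.full(100, -35.0)) == -35.0

    def test_unit_sinusoid(self):
        t = _time()
        assert max_voltage(np.sin(2 * np.pi * t / 2.5)) == pytest.approx(1.0, abs=1e-3)

    def test_transient_included(self):
        t = _time()
        v = np.where(t < 1.0, 40.0, 0.0)
        assert max_voltage(v) == 40.0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            max_voltage(np.array([0.0, np.nan]))

    def test_rejects_empty(self):
        with pytest.raises(ValueError, match="empty"):
            max_voltage(np.array([]))


class TestEstimatePeriod:
    def test_pure_sinusoid_recovered_within_dt(self):
        t = _time()
        v = 10 * np.sin(2 * np.pi * t / 2.5)
        assert estimate_period(v, t) == pytest.approx(2.5, abs=0.01)

    def test_monotone_decay_gives_none(self):
        t = _time()
        assert estimate_period(-35 + 5 * np.exp(-t), t) is None

    def test_constant_gives_none(self):
        t = _time()
        assert estimate_period(np.full_like(t, -35.0), t) is None

    def test_noisy_sinusoid_within_2pct_and_agrees_with_acf_oracle(self):
        t = _time()
        rng = np.random.default_rng(7)
        clean = 10 * np.sin(2 * np.pi * t / 2.5)
        v = clean + rng.normal(0, 0.5, t.shape)  # 5% amplitude noise
        est = estimate_period(v, t)
        assert est == pytest.approx(2.5, rel=0.02)
        sl = t >= 3.0
        oracle = acf_first_peak_period(v[sl], t[1] - t[0])
        assert est == pytest.approx(oracle, rel=0.02)

    def test_offset_and_positive_rescale_invariance(self):
        t = _time()
        rng = np.random.default_rng(3)
        v = 5 * np.sin(2 * np.pi * t / 2.0) + rng.normal(0, 0.2, t.shape)
        base = estimate_period(v, t)
        assert estimate_period(v + 120.0, t) == pytest.approx(base)
        assert estimate_period(3.7 * v, t) == pytest.approx(base)

    def test_empty_window_rejected(self):
        t = _time()
        with pytest.raises(ValueError, match="window"):
            estimate_period(np.sin(t), t, window=(5.0, 5.0))


class TestClassifyPhase:
    def setup_method(self):
        self.t = _time()
        self.s = np.sin(2 * np.pi * self.t / 2.5)

    def test_in_phase(self):
        rel = classify_phase(self.s, 2 * self.s, self.t)
        assert rel.relation == PhaseClass.in_phase
        assert rel.correlation == pytest.approx(1.0, abs=1e-6)

    def test_anti_phase(self):
        rel = classify_phase(self.s, -self.s, self.t)
        assert rel.relation == PhaseClass.anti_phase
        assert rel.correlation == pytest.approx(-1.0, abs=1e-6)

    def test_quadrature_undetermined(self):
        c = np.cos(2 * np.pi * self.t / 2.5)
        rel = classify_phase(self.s, c, self.t)
        assert rel.relation == PhaseClass.undetermined
        assert abs(rel.correlation) < 0.5

    def test_zero_variance_undetermined_with_zero_correlation(self):
        rel = classify_phase(self.s, np.zeros_like(self.s), self.t)
        assert rel.relation == PhaseClass.undetermined
        assert rel.correlation == 0.0

    def test_symmetry(self):
        a = self.s + 0.1 * np.cos(2 * np.pi * self.t / 1.3)
        b = -self.s
        r1 = classify_phase(a, b, self.t)
        r2 = classify_phase(b, a, self.t)
        assert r1.relation == r2.relation
        assert r1.correlation == pytest.approx(r2.correlation)


def _surrogate_traceset():
    spec = SurrogateSpec(
        period=2.5,
        phase_map={
            "VA01": 0.0, "VA02": 0.0, "DA01": 0.0, "AS01": 0.0,
            "VD01": np.pi, "DD01": np.pi,
        },
        amplitude=10.0,
        noise_sd=0.0,
    )
    return make_surrogate_traces(spec)


class TestBuildReport:
    def _classes(self):
        return [
            NeuronGroup("VA", ("VA01", "VA02")),
            NeuronGroup("DA", ("DA01",)),
            NeuronGroup("AS", ("AS01",)),
            NeuronGroup("VD", ("VD01",)),
            NeuronGroup("DD", ("DD01",)),
        ]

    def test_constructed_truth_verdict_and_phases(self):
        report = build_report(_surrogate_traceset(), self._classes())
        assert report.circuit_verdict == Verdict.oscillatory
        rel = {
            frozenset((p.neuron_a, p.neuron_b)): p.relation
            for p in report.phase_pairs
        }
        assert rel[frozenset(("VA01", "DA01"))] == PhaseClass.in_phase
        assert rel[frozenset(("VA01", "VD01"))] == PhaseClass.anti_phase
        assert rel[frozenset(("VD01", "DD01"))] == PhaseClass.in_phase
        assert report.per_class["VA"]["median_period"] == pytest.approx(2.5, rel=0.01)

    def test_all_constant_traces_silent(self):
        t = _time()
        traces = TraceSet(
            time=t,
            voltage=np.full((3, len(t)), -35.0),
            names=["VA01", "DA01", "VD01"],
        )
        groups = [NeuronGroup("VA", ("VA01",)), NeuronGroup("DA", ("DA01",)),
                  NeuronGroup("VD", ("VD01",))]
        report = build_report(traces, groups)
        assert report.circuit_verdict == Verdict.silent
        assert all(m.period is None for m in report.per_neuron)

    def test_oscillating_implies_period_and_peaks(self):
        report = build_report(_surrogate_traceset(), self._classes())
        for m in report.per_neuron:
            if m.oscillating:
                assert m.period is not None and m.n_peaks >= 2
            assert m.amplitude >= 0

    def test_verdict_monotone_under_trace_zeroing(self):
        traces = _surrogate_traceset()
        report_full = build_report(traces, self._classes())
        zeroed = traces.voltage.copy()
        zeroed[0] = 0.0  # silence VA01
        traces2 = TraceSet(time=traces.time, voltage=zeroed, names=traces.names)
        report_less = build_report(traces2, self._classes())
        order = {Verdict.silent: 0, Verdict.weak: 1, Verdict.oscillatory: 2}
        assert order[report_less.circuit_verdict] <= order[report_full.circuit_verdict]

    def test_missing_class_member_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            build_report(_surrogate_traceset(), [NeuronGroup("VB", ("VB01",))])
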