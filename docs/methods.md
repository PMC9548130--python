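# Methods

## Model

Every neuron is a single isopotential compartment with a leak current,
ohmic gap-junction coupling, and graded (non-spiking) chemical transmission:

```
C dV_i/dt = -G_leak (V_i - E_cell)
            - Σ_j G_gap  gap_ij  (V_i - V_j)
            - Σ_j G_syn  chem_ji s_j (V_i - E_rev(j))
            + I_ext,i(t)

ds_i/dt   = a_r φ(V_i) (1 - s_i) - a_d s_i
φ(V)      = 1 / (1 + exp(-β (V - V_th,i)))
```

`gap` and `chem` are synaptic contact-count matrices from the wiring
diagram (`gap` symmetric, `chem` directed pre→post); `s_j ∈ [0, 1]` is the
presynaptic release variable; `E_rev(j)` is the excitatory or inhibitory
reversal potential according to presynaptic neuron j's transmitter sign.
This is the standard model family for *C. elegans* whole-network
simulation: the nervous system is electrotonically compact and
communicates predominantly by graded potentials, so single-compartment
units with graded synapses are the appropriate level of description.
Spiking currents, channel noise, multicompartment morphology, and
plasticity are deliberately out of scope.

### Units

Capacitance is in pF, conductances in pS, voltages in mV, time in s.
These are mutually consistent when currents are expressed in fA
(pS·mV = fA, and fA/pF = mV/s), so injected currents given in nA are
converted by 1e6. A dimensionless `current_scale` parameter multiplies all
injected currents; it exists because published protocol currents for this
model family are nominal labels whose effective scale depends on the
simulator build being matched, and calibration should not require code
changes. The single-neuron closed form (steady state `E_cell + I/G_leak`,
time constant `C/G_leak`) is tested to 0.1%, which pins the unit
conventions.

### Parameters

Defaults (`wormcircuit/data/defaults.yaml`) are nominal values for this
model family, all overridable per run:

| parameter | default | meaning |
|---|---|---|
| capacitance | 1 pF | membrane capacitance per neuron |
| leak_conductance | 10 pS | membrane leak |
| leak_reversal | −35 mV | leak/resting potential E_cell |
| gap_unit_conductance | 100 pS | per gap-junction contact |
| syn_unit_conductance | 100 pS | per chemical-synapse contact |
| syn_reversal_exc / inh | 0 / −45 mV | reversal by presynaptic sign |
| sigmoid_gain β | 0.125 mV⁻¹ | release-sigmoid steepness |
| syn_rise a_r / syn_decay a_d | 1 / 5 s⁻¹ | activation kinetics |
| dt | 1 ms | integration step |
| duration | 12 s | protocol length |

None of these are measured constants; reproducing a specific published
simulator's printed voltages requires calibrating them against that
simulator (see Limitations).

### Resting state and thresholds

The release sigmoid of each neuron is anchored at the network's zero-input
equilibrium: under the half-activation ansatz φ = 1/2, every `s_i`
equilibrates at `a_r / (a_r + 2 a_d)`, which makes the voltage fixed-point
equations linear; the solve gives `V_eq`, and setting `V_th,i = V_eq,i`
closes the ansatz. The returned resting state is therefore an *exact*
equilibrium of the full nonlinear system, used as the initial condition of
every run. Simulations of ablated networks start from the *ablated*
network's resting state so ablation screens carry no relaxation artifact
from a stale equilibrium. The equilibrium solve is a dense linear system;
it is strictly diagonally dominant (leak on the diagonal) and cannot be
singular for positive conductances.

### Integration

Fixed-step explicit 4th-order Runge–Kutta. The system is non-stiff at
millisecond steps for these parameter scales (fastest eigenrate is bounded
by the largest total conductance over the capacitance, with the chemical
contribution bounded by `s ≤ a_r/(a_r+a_d)`); a pre-run check rejects
steps beyond the RK4 stability margin and suggests a smaller `dt`.
Injected currents are held constant across each step (sampled at the step
start), so grid-aligned stimulus on/off switches introduce no substep
inconsistency. A fixed step gives bit-deterministic, uniformly sampled
traces — identical inputs produce identical `TraceSet`s. The integrator is
cross-checked against (i) the single-neuron closed form and (ii) a
matrix-exponential solution of the activation-frozen (linear
time-invariant) system on ≤4-neuron networks, via `linearized_simulate`.

### Ablation

In silico ablation zeroes every gap and chemical weight into and out of
the ablated neurons while keeping them in the state vector, isolated at
their leak equilibrium. Indices and trace-row order are therefore stable
across a screen, and ablation is idempotent.

## Oscillation analytics

Motor-program readouts per neuron: maximum voltage over the *full* run
(onset transients are part of the readout), peak-to-trough amplitude and
period in a post-transient analysis window (default 3 s → end of run), and
an oscillating flag requiring amplitude ≥ 0.5 mV and ≥ 2 prominence-filtered
peaks (prominence ≥ 10% of the windowed range; plateau ties resolve to the
earliest sample). The period estimator detrends, applies zero-phase boxcar
smoothing (first pass ~2% of the window, second pass matched to one eighth
of the first-pass period estimate — wide enough to suppress sample-level
peak jitter, narrow enough not to flatten cycles), and returns the mean
inter-peak interval as the least-squares slope of peak time against peak
index, pooled with the analogous trough series (each series is spaced by
exactly one period for any waveform shape, and pooling roughly doubles the
events). On seeded sinusoidal surrogates at SNR 10 this recovers the true
period with ≤ 2% error.

Pairwise phase relations are the zero-lag Pearson correlation of the
detrended windowed traces: ≥ +0.5 is in-phase, ≤ −0.5 anti-phase,
otherwise undetermined (a quadrature pair is deliberately undetermined;
zero-variance traces return correlation 0). The circuit verdict is
`oscillatory` when at least half the readout neurons oscillate,
otherwise `weak` if any windowed amplitude reaches the 0.5 mV threshold,
else `silent`. The screen calls circuit membership on the verdict enum —
the binary present/lost reading — while amplitude deltas are retained for
inspection. All thresholds live in `AnalysisConfig`.

## Protocols and the screen

The protocol registry (YAML shipped as package data, user-replaceable)
encodes the named stimulation experiments: each sensory class at 5.0 nA
per neuron, the command interneurons (alias `CI` = AVA + AVD + AVE) at
0.9 nA per neuron, with or without ablation of the candidate relay
interneurons AUA, RMG, AIB, AVB, SMB. Currents apply per neuron (each
member of a stimulated class receives the stated current), stimulation
runs for the whole protocol (t_on = 0, t_off = duration), and protocols
last at least 12 s. The ablation screen runs the base protocol once intact
and once per candidate; candidates whose removal drops the verdict from
`oscillatory` are the predicted circuit members.

## Synthetic data

`make_toy_connectome` generates the four-layer sensorimotor topology —
sensor pair → relay-interneuron pair (gap junctions from the sensors) →
command set (chemical) → motor classes with mixed excitatory/GABAergic
neurons — with optional bilateral mirroring, recurrent weights, and a
bystander pair that receives sensory input but influences nothing (an
exactly-null ablation control). `make_surrogate_traces` generates seeded
sinusoids with known period, per-neuron phase, and Gaussian noise. All
generators are deterministic under a fixed seed.

### The oscillator fixture

Sustained network oscillation in this model family depends sensitively on
the operating point, so the screen's ground-truth toy is tuned once and
frozen as data (`data/toy_oscillator.json`) rather than regenerated.
Two properties of the rest-anchored model shaped its architecture:

1. At rest every release sigmoid sits at φ = 1/2 — its maximum gain — so
   any sustained positive input moves sigmoids toward saturation and
   *lowers* loop gain. A circuit whose oscillation is switched on by
   adding current therefore cannot work by gain increase; the fixture
   instead uses a *cancellation gate*: the relay interneurons are
   inhibitory, sensor drive alone hyperpolarizes the commands below their
   operating window, command current alone saturates them above it, and
   only the combination parks them inside the window where the command
   circuit's intrinsic instability lives. Ablating the relays removes the
   inhibition, the same command current overshoots, and the oscillation is
   lost — the screen's positive result. The fixture's inhibitory reversal
   is set to −60 mV (a physiological GABA value) because with the default
   −45 mV the heavily inhibited commands equilibrate close to the reversal
   and the gate loses its driving force.
2. The minimal oscillator here is a three-stage ring (command → inhibitory
   stage → excitatory stage → command) whose stages each contribute ~60°
   of phase at onset, so no single ring offers a voltage pair near 180°
   apart. The fixture therefore runs *two* identical rings ("phase
   pools"), cross-coupled competitively (each ring's excitatory node
   drives the other's inhibitor), which locks them half a period apart.
   The excitatory motor neurons read pool A's command and the GABAergic
   motor neurons read pool B's through identical single synapses, so the
   anti-phase relation between the motor classes is exact by symmetry
   rather than by lag tuning, mirroring the anti-phase VA/DA/AS vs VD/DD
   pattern of backward locomotion. A deterministic 10% bias on the second
   pool's injected current seeds the anti-phase mode (the analog of the
   left/right interneuron asymmetry seen in the reference circuit).

Fixture overrides (part of the frozen data, not package defaults):
β = 0.9 mV⁻¹, a_r = 0.5 s⁻¹, a_d = 2.5 s⁻¹, E_inh = −60 mV, 24 s
protocols. The gate's settling transient decays with a ~7 s time constant,
slower than stimulated runs of the reference network settle, so the
fixture's canonical analysis window opens at 12 s. The screen's verdicts
and the ~3.8 s motor period are stable under halving of `dt`.

What the fixture does and does not show: it demonstrates that the
pipeline — resting-state solve, integration, oscillation scoring, phase
classification, and verdict-flip screening — correctly identifies a relay
layer whose removal abolishes a stimulation-gated network oscillation,
with a structurally guaranteed negative control. It is a dynamical analog
of the sensor → relay → command → motor circuit, not a biophysical replica:
its relay synapse signs, weights, and currents were chosen for a clean
bistable gate, and no attempt is made to match the reference connectome's
specific voltages.

## Problem sizes

Default test and analysis runs use the 16-neuron fixture (24 s at 1 ms
steps), ≤4-neuron oracle networks (1 s), and 100 surrogate trials of four
12 s traces at 10 ms sampling; these sizes give sub-minute analyses while
leaving the estimator and screen behavior fully exercised. The simulator
itself is dense-matrix over the neuron count and handles the full
~300-neuron wiring at the same protocol lengths in seconds per run.

## Limitations

* The reference wiring dataset is an input, not part of the package
  (`version_tag` records which wiring a result used). The printed
  headline voltages of the motivating study (VA01 at 0.014 mV under
  sensor-only drive, 39.2 mV under co-stimulation, ~2.5 s periods) depend
  on that dataset *and* on the reference simulator's unprinted constants
  and input scaling; reproducing them requires supplying the wiring at
  `data/reference_connectome/` and calibrating `defaults.yaml` (including
  `current_scale`) against that simulator. The corresponding test stays
  red until then.
* Phase classification is a sign call, not a phase-lag estimate in
  radians; quadrature relationships are reported as undetermined by
  design.
* The behavioral indices are exact ratios; no inferential statistics are
  provided.
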