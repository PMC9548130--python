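# Default biophysical constants and integration settings.
#
# Model family: single-compartment leaky units, ohmic gap junctions, graded
# chemical synapses with first-order activation kinetics and a sigmoidal
# release function.  None of these constants are measured quantities here;
# they are nominal values for this model family and are meant to be
# overridden when calibrating against a specific reference simulator.
#
# Unit convention: capacitance pF, conductances pS, voltages mV, time s.
# With these, the internally consistent current unit is fA; injected currents
# given in nA are converted by 1e6 and then multiplied by current_scale
# (a calibration knob, dimensionless, default 1).

capacitance: 1.0          # pF per neuron
leak_conductance: 10.0    # pS
leak_reversal: -35.0      # mV (E_cell)
gap_unit_conductance: 100.0   # pS per contact
syn_unit_conductance: 100.0   # pS per contact
syn_reversal_exc: 0.0     # mV
syn_reversal_inh: -45.0   # mV
sigmoid_gain: 0.125       # 1/mV (beta)
syn_rise: 1.0             # 1/s (a_r)
syn_decay: 5.0            # 1/s (a_d)
current_scale: 1.0        # dimensionless multiplier on injected currents
dt: 0.001                 # s
duration: 12.0            # s
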