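{
  "comment": "Frozen two-pool oscillator toy. Weights are synaptic contact counts; tuned once so that sensor+command co-stimulation parks the commands in the rings' oscillatory window while either input alone (or relay ablation) leaves the network at a stable fixed point. See docs/methods.md.",
  "weights": {
    "gap_weight": 2.0,
    "relay_weight": 36.0,
    "ring_drive": 1.2,
    "ring_inhibition": 4.0,
    "ring_feedback": 6.0,
    "ring_shortcut": 0.2,
    "cross_coupling": 1.1,
    "readout_weight": 0.7
  },
  "sensor_current_na": 0.001,
  "command_current_na": 0.003,
  "command_asymmetry": 0.1,
  "analysis_window_start_s": 12.0,
  "param_overrides": {
    "sigmoid_gain": 0.9,
    "syn_rise": 0.5,
    "syn_decay": 2.5,
    "syn_reversal_inh": -60.0,
    "duration": 24.0
  }
}
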