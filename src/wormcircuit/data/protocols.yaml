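# Named in silico stimulation protocols.
#
# Stimulus entries map a neuron group (class label, alias, or explicit
# neuron name) to a per-neuron injected current in nA.  "CI" is the
# command-interneuron alias (AVA + AVD + AVE).  Ablation entries are group
# names resolved the same way.  Readout classes are the backward-locomotion
# motor-neuron classes.
#
# Users may point the CLI/API at their own registry file with the same
# layout to add protocols without code changes.

duration: 12.0
readout_classes: [VA, DA, VD, DD, AS]

protocols:
  awb_only:
    stimulus: {AWB: 5.0}
  awb_ci:
    stimulus: {AWB: 5.0, CI: 0.9}
  awc_ci:
    stimulus: {AWC: 5.0, CI: 0.9}
  asi_ci:
    stimulus: {ASI: 5.0, CI: 0.9}
  ase_ci:
    stimulus: {ASE: 5.0, CI: 0.9}
  ash_ci:
    stimulus: {ASH: 5.0, CI: 0.9}
  awb_ci_minus_AUA:
    base: awb_ci
    ablations: [AUA]
  awb_ci_minus_RMG:
    base: awb_ci
    ablations: [RMG]
  awb_ci_minus_AIB:
    base: awb_ci
    ablations: [AIB]
  awb_ci_minus_AVB:
    base: awb_ci
    ablations: [AVB]
  awb_ci_minus_SMB:
    base: awb_ci
    ablations: [SMB]
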