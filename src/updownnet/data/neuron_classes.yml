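# Electrophysiological class parameters for the two-variable neuron models.
# Voltage-equation constants (alpha, beta, gamma, v_peak) are shared by all
# classes; (a, b, c, d) select the firing pattern.  AdEx constants give the
# exponential voltage equation a fixed point and nullcline shape close to the
# quadratic model (E_L is tied to the reset voltage c).
common:
  alpha: 0.04
  beta: 5.0
  gamma: 140.0
  v_peak: 30.0
classes:
  RS:  {a: 0.02, b: 0.20, c: -65.0, d: 8.0, synaptic: excitatory}
  CH:  {a: 0.02, b: 0.20, c: -50.0, d: 2.0, synaptic: excitatory}
  FS:  {a: 0.10, b: 0.20, c: -65.0, d: 2.0, synaptic: inhibitory}
  LTS: {a: 0.02, b: 0.25, c: -65.0, d: 2.0, synaptic: inhibitory}
adex:
  gL: 1.0
  DeltaT: 30.0
  vT: -65.0
  offset: -46.0
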