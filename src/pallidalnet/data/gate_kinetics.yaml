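# Calibrated gate kinetics for the single-compartment GP neuron.
#
# One record per gate: Boltzmann steady state (v_half mV, slope mV; slope < 0
# opens with hyperpolarization) and sigmoidal voltage-dependent time constant
# tau(V) = tau_min + (tau_max - tau_min) / (1 + exp((V - v_tau)/k_tau)) in ms.
# Values were seeded from published rodent GPe-neuron kinetics and then
# calibrated (see docs/methods.md) so that the neuron population reproduces
# the target isolated-cell surface — autonomous pacemaking near 23.6 Hz in
# the large majority of heterogeneous cells, depolarization-driven firing up
# to ~200 Hz, sag and rebound under hyperpolarization, slowed pacemaking
# (~15.8 Hz) when both HCN conductances are zeroed — and degrades gracefully
# (rather than silencing) under GABAergic conductance load, which the
# network-level competition dynamics require.
# A user holding a different kinetics set can point the config at their file.

NaF:
  m: {v_half: -39.0, slope: 5.0, tau_min: 0.028, tau_max: 0.028}
  h: {v_half: -48.0, slope: -2.8, tau_min: 0.25, tau_max: 4.0, v_tau: -43.0, k_tau: 10.0}
  s: {v_half: -40.0, slope: -5.4, tau_min: 10.0, tau_max: 1000.0, v_tau: -40.0, k_tau: 10.0}
NaP:
  m: {v_half: -59.3, slope: 5.7, tau_min: 0.03, tau_max: 0.15, v_tau: -42.6, k_tau: 10.0}
  h: {v_half: -57.0, slope: -10.0, tau_min: 30.0, tau_max: 60.0, v_tau: -50.0, k_tau: 8.0}
  s: {v_half: -10.0, slope: -4.9, tau_min: 10000.0, tau_max: 10000.0}
Kv2:
  m: {v_half: -33.2, slope: 9.1, tau_min: 0.1, tau_max: 3.0, v_tau: -33.0, k_tau: 10.0}
  h: {v_half: -20.0, slope: -10.0, tau_min: 3400.0, tau_max: 3400.0}
Kv3:
  m: {v_half: -26.0, slope: 7.8, tau_min: 0.1, tau_max: 14.0, v_tau: -26.0, k_tau: 12.0}
  h: {v_half: -20.0, slope: -10.0, tau_min: 7.0, tau_max: 33.0, v_tau: -25.0, k_tau: 10.0}
Kv4_fast:
  m: {v_half: -49.0, slope: 12.5, tau_min: 0.25, tau_max: 7.0, v_tau: -49.0, k_tau: 29.0}
  h: {v_half: -83.0, slope: -10.0, tau_min: 7.0, tau_max: 21.0, v_tau: -65.0, k_tau: 10.0}
Kv4_slow:
  m: {v_half: -49.0, slope: 12.5, tau_min: 0.25, tau_max: 7.0, v_tau: -49.0, k_tau: 29.0}
  h: {v_half: -83.0, slope: -10.0, tau_min: 50.0, tau_max: 120.0, v_tau: -65.0, k_tau: 10.0}
KCNQ:
  m: {v_half: -61.0, slope: 19.5, tau_min: 6.7, tau_max: 100.0, v_tau: -61.0, k_tau: 35.0}
HVA:
  m: {v_half: 0.0, slope: 5.0, tau_min: 0.75, tau_max: 0.75}
HCN_fast:
  m: {v_half: -88.0, slope: -4.5, tau_min: 25.0, tau_max: 3000.0, v_tau: -61.0, k_tau: 1.5}
HCN_slow:
  m: {v_half: -106.0, slope: -6.4, tau_min: 2500.0, tau_max: 2500.0}
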