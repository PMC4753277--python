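lif:
  tau_m: 10.0      # ms
  e_leak: -70.0    # mV
  r_in: 160.0      # MOhm
  c_m: 62.5        # pF = tau_m / r_in
  v_thresh: -37.0  # mV
  v_peak: 20.0     # mV (spike display amplitude; no effect on dynamics)
  v_reset: -80.0   # mV
kernel:
  tau_rise: 1.4    # ms
  tau_decay: 3.0   # ms (fast, basket-cell-type input; 5.0 for Martinotti-type)
  g_peak: 1.0      # nS
  e_rev: 0.0       # mV
  t_onset: 10.0    # ms
sim:
  dt: 0.1          # ms, forward Euler
  duration: 100.0  # ms
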