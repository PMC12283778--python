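# Tissue model presets for the synthetic generator.
#
# potato: calibrated to the summary conductivities measured in russet tuber
# tissue with parallel-plate ramps: non-electroporated bulk 0.13 S/m (1 µs
# pulses) and 0.04 S/m (10 µs pulses); electroporated plateaus 0.55 and
# 0.67 S/m.  The transition field (500 V/cm) and half-width (150 V/cm) place
# the conductivity rise between ~350 and ~650 V/cm, bracketing the observed
# onset (between 250 and 750 V/cm depending on pulse width).
#
# cardiac: SYNTHETIC placeholder preset (no cardiac conductivities were
# measured on this bench); bulk values scaled up to a ~0.2 S/m baseline to
# emulate the higher conductivity of myocardium.  Qualitative use only.
potato:
  sigma_bulk_by_pw: {1.0: 0.13, 10.0: 0.04}
  sigma_max_by_pw: {1.0: 0.55, 10.0: 0.67}
  e_th_v_per_cm: 500.0
  transition_width_v_per_cm: 150.0
  tau_mem_us: 1.0
  cap_transient_frac: 0.10
  cap_transient_tau_us: 0.2
  noise_rel: 0.01
  mode: phenomenological

potato_mechanistic:
  sigma_bulk_by_pw: {1.0: 0.13, 10.0: 0.04}
  sigma_max_by_pw: {1.0: 0.55, 10.0: 0.67}
  e_th_v_per_cm: 500.0
  transition_width_v_per_cm: 150.0
  tau_mem_us: 1.0
  cap_transient_frac: 0.10
  cap_transient_tau_us: 0.2
  noise_rel: 0.01
  mode: mechanistic

cardiac:
  comment: synthetic placeholder values, not bench measurements
  sigma_bulk_by_pw: {1.0: 0.45, 10.0: 0.20}
  sigma_max_by_pw: {1.0: 0.70, 10.0: 0.80}
  e_th_v_per_cm: 500.0
  transition_width_v_per_cm: 150.0
  tau_mem_us: 1.0
  cap_transient_frac: 0.10
  cap_transient_tau_us: 0.2
  noise_rel: 0.01
  mode: phenomenological
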