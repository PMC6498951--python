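# Resting ventilation run: 12 breaths/min, 0.5 L tidal volume.
# Omitted fields take the standard physiological defaults.
morphometry:
  trachea_radius_m: 1.0e-2
  homothety_ratio: 0.7937
  acinar_generations: 6
ventilation:
  A: 1.0     # trachea velocity amplitude, m/s
  T: 5.0     # breathing period, s
blood:
  P_aO2: 40.0
  P_aCO2: 47.0
mechanics:
  R: 2.0e+5  # Pa s m^-3
  C: 5.0e-7  # m^3 Pa^-1
solver:
  nodes_per_branch: 8
  steps_per_cycle: 120
  periodicity_tol: 1.0e-5
calibrate: true
target_rest_RER: 0.8
rest_demand: 1.32e-4   # mol/s
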