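# Calibrated default configuration for the intermittent-hypoxia chamber twin.
# Units are explicit in key names: _l litres, _lpm L/min, _s seconds, _bar bar,
# _pct O2 percentage points; unlabelled O2 quantities are mole fractions.
plant:
  antechamber_volume_l: 0.05
  antechamber_mixing_factor: 1.0
  cage_volume_l: 12.4
  cage_mixing_factor: 0.2068
  flow_cap_lpm: 50.0
  n2_pressure_bar: 2.0
  air_pressure_bar: 1.2
  n2_valve_max_flow_lpm: 45.0
  air_onoff_max_flow_lpm: 40.0
  air_small_max_flow_lpm: 8.8165
  initial_o2_pct: 21.0
  dt_s: 0.01
sensors:
  antechamber_time_constant_s: 0.5
  cage_time_constant_s: 4.249
  noise_sd: 0.0005
  adc_bits: 10
  adc_range: 0.25
  sample_period_s: 0.1
controller:
  kp: 0.2336
  ki: 0.0008
  kd: 0.0
  integral_limit: 20.0
  gating_band_pct: 0.2
  gating_hysteresis_pct: 0.05
  min_command: 0.03
  air_onoff_threshold: 0.5
  mix_trim_gain: 0.0005
protocol:
  level_1_pct: 5.7
  duration_1_s: 90.0
  level_2_pct: 21.0
  duration_2_s: 90.0
  session_hours: 8.0
  n_days: 21
  session_start_hour: 7.0
calibration:
  parameters:
    plant.cage_mixing_factor: [0.05, 0.6]
    plant.air_small_max_flow_lpm: [0.5, 10.0]
    sensors.cage_time_constant_s: [0.2, 8.0]
    controller.kp: [0.05, 1.0]
    controller.ki: [0.0, 0.05]
    controller.min_command: [0.03, 0.3]
  target_time_to_target_s: 4.5
  target_settle_time_s: 27.0
  target_undershoot_duration_s: 12.0
  target_undershoot_nadir_pct: 2.0
  weight_time_to_target: 1.0
  weight_settle_time: 1.0
  weight_undershoot_duration: 1.0
  weight_undershoot_nadir: 1.0
  metrics_band_pct: 0.5
  sim_duration_s: 60.0
  n_starts: 8
  max_evals_per_start: 200
stats:
  baseline_ca1: 10.0
  baseline_ca3: 10.0
  baseline_dg: 20.0
  ih_effect_multiplier: 1.3
  n_ih: 8
  n_ctrl: 7
  dispersion: 10.0
  frame_um: 280.0
  thickness_um: 35.0
  n_sections: 4
  alpha: 0.05
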